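study_id,study_name,design,intervention,events,size,cluster_adjusted,alloc_concealment,blinding,followup,confounders
1,Nansel (2002),RCT,1,70,89,0,U,Y,N,
1,Nansel (2002),RCT,2,76,85,0,U,Y,N,
2,Kendrick (2005),RCT,1,348.44,436.80,1,Y,U,Y,
2,Kendrick (2005),RCT,2,310.93,376.78,1,Y,U,Y,
3,Nansel (2008),NRCT,1,29,38,0,Y,U,N,
3,Nansel (2008),NRCT,2,60,69,0,Y,U,N,
4,Clamp (1998),RCT,1,50,69,0,Y,N,Y,
4,Clamp (1998),RCT,3,52,64,0,Y,N,Y,
5,McDonald (2005),RCT,1,10,41,0,U,N,N,
5,McDonald (2005),RCT,3,23,54,0,U,N,N,
6,Kendrick (1999),NRCT,1,214.26,323.61,1,U,Y,N,
6,Kendrick (1999),NRCT,4,223.15,323.61,1,U,Y,N,
7,Watson (2005),RCT,1,328,718,0,U,N,Y,
7,Watson (2005),RCT,5,408,742,0,U,N,Y,
8,Phelan (2010),RCT,1,78,147,0,,N,N,Y
8,Phelan (2010),RCT,6,131,146,0,,N,N,Y
9,Posner (2004),RCT,2,25,47,0,U,Y,Y,
9,Posner (2004),RCT,3,28,49,0,U,Y,Y,
10,Sznajder (2003),RCT,2,45,50,0,N,N,Y,
10,Sznajder (2003),RCT,5,44,47,0,N,N,Y,
11,Gielen (2002),RCT,3,12.85,47.44,1,Y,N,Y,
11,Gielen (2002),RCT,4,10.87,47.44,1,Y,N,Y,
12,King (2001),RCT,4,158,482,0,Y,Y,N,
12,King (2001),RCT,7,166,469,0,Y,Y,N,
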