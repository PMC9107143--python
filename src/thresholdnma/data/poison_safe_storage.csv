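study_id,study_name,design,intervention,events,size,cluster_adjusted,alloc_concealment,blinding,followup,confounders
1,Kelly (1987),RCT,1,43,54,0,U,Y,N,
1,Kelly (1987),RCT,2,49,55,0,U,Y,N,
2,Nansel (2002),RCT,1,65,89,0,Y,U,Y,
2,Nansel (2002),RCT,2,66,85,0,Y,U,Y,
3,McDonald (2005),RCT,1,3,57,0,Y,U,N,
3,McDonald (2005),RCT,2,6,61,0,Y,U,N,
4,Gielen (2007),RCT,1,44,62,0,Y,N,Y,
4,Gielen (2007),RCT,2,57,73,0,Y,N,Y,
5,Nansel (2008),NRCT,1,59,73,0,U,N,N,
5,Nansel (2008),NRCT,2,117,144,0,U,N,N,
6,Woolf (1992),clusterRCT,1,60,151,0,U,Y,N,
6,Woolf (1992),clusterRCT,3,89,150,0,U,Y,N,
7,Clamp (1998),RCT,1,49,82,0,U,N,Y,
7,Clamp (1998),RCT,3,59,83,0,U,N,Y,
8,Kendrick (1999),clusterNRCT,1,317,367,0,,N,N,Y
8,Kendrick (1999),clusterNRCT,4,322,363,0,,N,N,Y
9,Swart (2008),NRCT,1,46.86,57.96,1,U,Y,Y,
9,Swart (2008),NRCT,4,50.87,58.27,1,U,Y,Y,
10,Hendrickson (2002),RCT,1,14,40,0,N,N,Y,
10,Hendrickson (2002),RCT,4,34,38,0,N,N,Y,
11,Watson (2005),clusterRCT,1,327,669,0,Y,N,Y,
11,Watson (2005),clusterRCT,5,368,693,0,Y,N,Y,
12,Posner (2004),RCT,2,22,47,0,Y,Y,N,
12,Posner (2004),RCT,3,34,49,0,Y,Y,N,
13,Sznajder (2003),RCT,2,32,41,0,Y,N,Y,
13,Sznajder (2003),RCT,5,40,48,0,Y,N,Y,
14,Dershewitz (1977),RCT,3,1,101,0,U,Y,N,
14,Dershewitz (1977),RCT,7,0,104,0,U,Y,N,
15,King (2001),RCT,4,261,469,0,Y,Y,Y,
15,King (2001),RCT,6,273,482,0,Y,Y,Y,
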