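# Methods

## Model

The package fits the standard arm-based random-effects NMA for binary
outcomes. With studies `i = 1..N`, interventions coded `1..K` (1 = usual
care, the reference), and `t(i, a)` the intervention on arm `a`:

- Likelihood: `r_ia ~ Binomial(n_ia, p_ia)`, `logit(p_ia) = mu_i + delta_ia`,
  with `delta = 0` on the study's baseline arm (its lowest-coded arm).
- Random effects: the vector of a study's non-baseline `delta`s is
  multivariate normal with means `d_1t - d_1b`, variances `tau^2` and
  pairwise covariances `tau^2 / 2` (the standard exchangeable multi-arm
  construction). Two-arm studies reduce to `delta ~ N(d_1k - d_1c, tau^2)`.
- Priors: `mu_i, d_1k ~ N(0, 100^2)` and `tau ~ Uniform(0, 5)`, the vague
  choices conventional for this model family; both scales are exposed in
  `NMAConfig` (`prior_sd_effects`, `tau_upper`).

Counts are carried as floats end to end. Cluster-randomised studies enter
with design-effect–adjusted effective counts (`DEFF = 1 + (m - 1) ICC`,
both cells divided by DEFF, preserving the observed proportion); the two
packaged networks carry the adjusted figures exactly as published, because
the underlying ICCs and cluster sizes are not public. Real-valued counts
pose no problem for MCMC because the binomial normalising constant is
parameter-free and cancels from every acceptance ratio (its log-gamma
generalisation exists but is never needed).

Studies with a zero cell (all of Dershewitz 1977 in the poison network)
receive the Haldane–Anscombe continuity correction — 0.5 added to each cell
of the 2×2 table, i.e. `events + 0.5`, `size + 1` — applied to *all* arms of
the affected study, before any log-odds-ratio or likelihood evaluation.
The packaged CSV stores the uncorrected published counts; correction happens
at preparation time.

A labelling note on the poison network: the source tables are internally
inconsistent about which of codes 3/4/5 include equipment fitting versus
home-safety inspection. The numeric codes (which are what every computation
uses) are taken from the study-comparison table, which is consistent with
all per-study results; the text labels follow that table and should be read
with this caveat.

## Sampling

The posterior is explored with an adaptive Metropolis-within-Gibbs sampler
(numba-compiled), one chain per seed, default 4 chains × 30 000 iterations
(10 000 burn-in, thinning 4 → 20 000 retained draws). Per sweep:

1. random-walk updates of each `mu_i`, each non-baseline `delta`, and each
   `d_k`;
2. *translation moves* proposing a joint shift of `d_k` and the random
   effects of every study involving `k` — the exchangeable prior is invariant
   under the shift, so only the likelihood and the `d_k` prior enter the
   ratio. These break the strong `d`–`delta` posterior correlation of the
   hierarchy;
3. a Gibbs draw of `tau`: conditional on the random-effect residuals,
   `1/tau^2` is Gamma((M−1)/2, W/2) truncated by the prior bound (`M` =
   number of random-effect dimensions, `W` = summed quadratic forms), drawn
   directly; a random walk is used as fallback when `M < 2`;
4. non-centred (interweaving) `tau` moves that rescale all residuals along
   with `tau`, accepted on the likelihood ratio alone. The posterior is
   ridge-shaped in (`tau`, shrinkage), and alternating the centred Gibbs
   draw with these non-centred moves is what makes `tau` mix well; several
   per sweep, one long-range.

Proposal scales adapt toward 0.44 acceptance in diminishing batches during
burn-in only, so the post-burn-in kernel is fixed and valid. Chains start
from empirical-logit values with overdispersed jitter (non-baseline
dimensions only). Split-chain R-hat and bulk ESS (ArviZ) are recorded for
every `d_k` and `tau`; fits warn — and the CLI exits with a dedicated code —
when any R-hat exceeds 1.05. On the packaged networks all R-hat ≈ 1.00 and
`tau` ESS is in the thousands.

Node-splitting refits the model with a separate direct-effect parameter for
the two-arm studies observing the chosen contrast; the consistency
parameters are then informed only by the remaining evidence, and the
two-sided tail probability of the direct-minus-indirect difference is the
inconsistency p-value. A contrast is splittable when direct studies exist
and the graph without them still connects the two interventions.

## Threshold analysis

The decision rule is "highest expected effect": `k* = argmax_k E[d_1k]`
(ties break to the lowest code, with a warning). For data points `y_j` with
contrast rows `X` and likelihood variances `V`, the first-order influence of
an additive bias adjustment on the posterior means is

    U = Sigma_post X' V^{-1}

- `Sigma_post`: covariance of the `K−1` free basic parameters estimated from
  the MCMC draws (so it is the fully marginal posterior covariance,
  including heterogeneity uncertainty);
- study level: `y_j` = a study's delta-method log OR, `V_jj = v_j + tau_hat^2`;
- contrast level: `y_j` = fixed-effect inverse-variance pool of the direct
  studies on that contrast, `V_jj = v_pool + tau_hat^2 / m_j`;
- `tau_hat` = posterior median of `tau` (plug-in; the choice is localised in
  `influence_matrix`).

For each data point and each rival `a ≠ k*`, the candidate bias equalising
the two is `eps = (d_hat[k*] − d_hat[a]) / (u_aj − u_k*j)`; the smallest
positive and largest negative candidates are the thresholds, the rival
attaining them the new optimum, and `(y_j + eps−, y_j + eps+)` the
decision-invariant interval (`NT` = unbounded side, stored as ±inf and
exported as the string `NT`). Robustness compares the data point's 95%
interval with its invariant interval: delta-method confidence intervals at
study level, posterior credible intervals of the contrast at contrast level
(the combined quantity the decision actually uses — hence visibly wider in
heterogeneous networks, as for the single-study contrast 4v6).

When one study is a contrast's only direct evidence, the study- and
contrast-level rows are algebraically identical (same variance, same design
row), which the tests assert exactly.

`brute_force_decision_flip` is the independent oracle: it refits the full
model on a grid of bias adjustments (shifting the perturbed study's
non-baseline log-odds) and reports the first grid point at which `argmax`
changes. The linear thresholds track the oracle within max(0.1, 10%) in the
regime the method is designed for — closely competing top interventions,
hence small thresholds (|eps| ≲ 0.35), in networks where `tau` is reasonably
identified. Outside that regime the linearisation is conservative in a
predictable direction: a large injected bias inflates the refitted `tau`
and its own delta-method variance, both of which dampen the data point's
influence, so true flip points sit ~20–40% beyond the linear threshold.
Reported thresholds of that magnitude should be read as order-of-magnitude
statements (which is how they are used: "robust" calls depend on small
thresholds, where the approximation is sharp).

## Synthetic data

`simulate_network` inverts the fitted model exactly: baselines
`mu_i ~ N(-0.5, 0.5^2)` by default (mid-range uptake proportions comparable
to the packaged studies), study effects drawn from a single consistent
`d_true` with between-study SD `tau_true` (correlated construction for
multi-arm designs), binomial counts, optional per-study additive log-OR
biases. Designs are two-arm by default (as in both packaged networks), a
spanning star plus random pairs unless an explicit contrast list is given;
`poison_like_scenario` reproduces the poison network's exact 15-study
topology including its two bridge edges (3–7, 4–6). What the generator does
*not* emulate: raw cluster-randomised data (only DEFF-adjusted summaries),
non-randomised designs with systematic bias, and outcome correlation between
arms — so passing recovery tests demonstrate correctness of the machinery
under the model's own assumptions, not robustness to real-world violations
of them.

Default study sizes in the test-suite experiments (e.g. K = 3–4, 12–20
studies, 200–500 households per arm, `tau` 0.1–0.25) were chosen to mirror
the scale of the packaged networks while keeping the full suite fast.

## Known limitations

- The published analysis this package replicates inherited cluster- and
  NRCT-variance adjustments from the original systematic reviews whose
  parameters (ICCs, bias-model weights) were never published. The packaged
  networks carry exactly the published counts; consequently one cluster
  non-RCT (poison study 8, Kendrick 1999) is analysed here with its
  unadjusted delta-method variance and comes out *non-robust* (and
  small-thresholded) where the original analysis, with an inflated variance,
  judged it robust. The robustness *sets* otherwise agree, and every printed
  threshold value replicates within tolerance.
- Thresholds are one-data-point-at-a-time; joint biases across studies are
  out of scope.
- Node-splitting requires two-arm direct studies.
- The rank credible intervals are knife-edge functions of tail
  probabilities; with probability-best near 0.97–0.99 the upper rank bound
  can differ from a published value by one integer for MCMC-trivial reasons.
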