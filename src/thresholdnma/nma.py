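"""Bayesian random-effects network meta-analysis for arm-level binary data.

Fits the standard binomial-logit hierarchical model: study baselines ``mu_i``,
exchangeable study-specific effects ``delta_i ~ N(d_1k - d_1c, tau^2)`` (with
the usual correlated construction for multi-arm trials) and vague priors —
Normal(0, 100^2) on baselines and basic parameters, Uniform(0, 5) on the
between-study SD ``tau``.  Basic parameters ``d_1k`` are log odds ratios of
intervention ``k`` versus the network reference (code 1).

Also provides intervention rankings (probability best, median rank), pairwise
random-effects meta-analysis of the direct evidence for one contrast, and
node-splitting consistency checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import networkx as nx
import numpy as np
import pandas as pd

from . import _sampler
from .data_model import (
    Arm,
    Intervention,
    Network,
    NetworkValidationError,
    Study,
    apply_continuity_correction,
)

__all__ = [
    "NMAConfig",
    "NMAResult",
    "PairwiseResult",
    "NodeSplitResult",
    "ConvergenceWarning",
    "NotSplittableError",
    "fit_nma",
    "relative_effects",
    "rank_interventions",
    "fit_pairwise",
    "node_split",
]


class ConvergenceWarning(UserWarning):
    """An MCMC convergence diagnostic exceeded its threshold."""


class NotSplittableError(ValueError):
    """Contrast has no independent direct and indirect evidence paths."""


@dataclass(frozen=True)
class NMAConfig:
    """Sampler and prior settings.

    ``iterations`` is the total number of MCMC iterations per chain including
    ``burn_in``; every ``thin``-th post-burn-in draw is kept.
    """

    prior_sd_effects: float = 100.0
    tau_upper: float = 5.0
    chains: int = 4
    iterations: int = 30_000
    burn_in: int = 10_000
    thin: int = 4
    seed: int = 2024
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for convergence diagnostics")
        if not 0 < self.burn_in < self.iterations:
            raise ValueError("need 0 < burn_in < iterations")
        if self.tau_upper <= 0 or self.prior_sd_effects <= 0:
            raise ValueError("prior scales must be positive")

    def with_seed(self, seed: int) -> "NMAConfig":
        return replace(self, seed=int(seed) % 2**31)


@dataclass
class NMAResult:
    """Posterior draws from :func:`fit_nma`.

    ``d`` has shape (chains, draws, K) and includes the reference column
    (identically zero); ``mu`` is (chains, draws, n_studies); ``tau`` is
    (chains, draws).  ``d_direct`` is present only for node-split fits.
    """

    network: Network
    config: NMAConfig
    d: np.ndarray
    tau: np.ndarray
    mu: np.ndarray
    d_direct: np.ndarray | None = None
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def codes(self) -> list[int]:
        return [i.code for i in sorted(self.network.interventions, key=lambda x: x.code)]

    @property
    def d_flat(self) -> np.ndarray:
        """(total draws, K) basic-parameter draws, chains concatenated."""
        return self.d.reshape(-1, self.d.shape[-1])

    @property
    def d_means(self) -> np.ndarray:
        """Posterior mean of each basic parameter (reference entry 0)."""
        return self.d_flat.mean(axis=0)

    @property
    def tau_flat(self) -> np.ndarray:
        return self.tau.reshape(-1)

    @property
    def tau_median(self) -> float:
        return float(np.median(self.tau_flat))

    def d_posterior_cov(self) -> np.ndarray:
        """Posterior covariance of the K-1 free basic parameters."""
        return np.cov(self.d_flat[:, 1:], rowvar=False)

    def contrast_draws(self, c: int, k: int) -> np.ndarray:
        """Draws of d_ck = d_1k - d_1c (log OR of k vs c)."""
        codes = self.codes
        return self.d_flat[:, codes.index(k)] - self.d_flat[:, codes.index(c)]

    def or_summary(self, c: int, k: int) -> tuple[float, float, float]:
        """(median, 2.5%, 97.5%) of the odds ratio of k versus c."""
        draws = np.exp(self.contrast_draws(c, k))
        lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
        return float(med), float(lo), float(hi)

    def max_rhat(self) -> float:
        return float(self.diagnostics["rhat"].max())


@dataclass(frozen=True)
class PairwiseResult:
    """Random-effects pairwise meta-analysis of one contrast's direct studies."""

    contrast: tuple[int, int]
    n_studies: int
    or_median: float
    or_ci: tuple[float, float]
    log_or_draws: np.ndarray


@dataclass(frozen=True)
class NodeSplitResult:
    contrast: tuple[int, int]
    direct: tuple[float, float, float]  # median, 2.5%, 97.5% on log-OR scale
    indirect: tuple[float, float, float]
    p_value: float


# ---------------------------------------------------------------------------


def _build_arrays(network: Network):
    """Flatten the network to the sampler's arm arrays (baseline arm first)."""
    codes = sorted(i.code for i in network.interventions)
    code_to_idx = {c: i for i, c in enumerate(codes)}
    arm_r, arm_n, arm_study, arm_treat = [], [], [], []
    study_start = [0]
    for s in network.studies:
        for code in s.treatments:  # ascending: lowest code is the baseline arm
            a = s.arm_for(code)
            arm_r.append(a.events)
            arm_n.append(a.size)
            arm_study.append(len(study_start) - 1)
            arm_treat.append(code_to_idx[code])
        study_start.append(len(arm_r))
    return (
        np.asarray(arm_r, dtype=np.float64),
        np.asarray(arm_n, dtype=np.float64),
        np.asarray(arm_study, dtype=np.int64),
        np.asarray(arm_treat, dtype=np.int64),
        np.asarray(study_start, dtype=np.int64),
    )


def _initial_values(arm_r, arm_n, study_start):
    """Empirical-logit starting values for baselines and random effects."""
    logit = np.log((arm_r + 0.5) / (arm_n - arm_r + 0.5))
    n_studies = len(study_start) - 1
    mu0 = np.array([logit[study_start[i]] for i in range(n_studies)])
    delta0 = np.zeros_like(arm_r)
    for i in range(n_studies):
        a0 = study_start[i]
        for a in range(a0 + 1, study_start[i + 1]):
            delta0[a] = logit[a] - logit[a0]
    return mu0, delta0


def _compute_diagnostics(d, tau, ddir, codes) -> pd.DataFrame:
    """Split-chain R-hat and bulk ESS per monitored parameter (via arviz)."""
    rows = {}
    for j, code in enumerate(codes[1:], start=1):
        rows[f"d[{code}]"] = d[:, :, j]
    rows["tau"] = tau
    if ddir is not None:
        rows["d_direct"] = ddir
    recs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, draws in rows.items():
            recs.append(
                {
                    "parameter": name,
                    "rhat": float(az.rhat(draws.astype(np.float64))),
                    "ess_bulk": float(az.ess(draws.astype(np.float64))),
                }
            )
    return pd.DataFrame(recs).set_index("parameter")


def fit_nma(
    network: Network,
    config: NMAConfig | None = None,
    _direct_contrast: tuple[int, int] | None = None,
) -> NMAResult:
    """Fit the random-effects binomial-logit NMA and return posterior draws.

    Zero-cell studies are continuity-corrected internally.  Warns with
    :class:`ConvergenceWarning` if any split-chain R-hat on ``d`` or ``tau``
    exceeds ``config.rhat_threshold``.

    ``_direct_contrast`` is internal plumbing for :func:`node_split`: flagged
    two-arm studies observing exactly that contrast get their own direct-effect
    parameter instead of the consistency mean.
    """
    config = config or NMAConfig()
    net = apply_continuity_correction(network)
    arm_r, arm_n, arm_study, arm_treat, study_start = _build_arrays(net)
    n_studies = len(net.studies)
    K = net.n_interventions

    direct_flag = np.zeros(n_studies, dtype=np.uint8)
    if _direct_contrast is not None:
        c, k = sorted(_direct_contrast)
        for i, s in enumerate(net.studies):
            if set(s.treatments) == {c, k}:
                direct_flag[i] = 1

    mu0, delta0 = _initial_values(arm_r, arm_n, study_start)
    nonbase = np.ones(len(arm_r), dtype=bool)
    nonbase[study_start[:-1]] = False  # baseline-arm deltas are pinned at 0
    n_keep = (config.iterations - config.burn_in) // config.thin

    rng = np.random.default_rng(config.seed)
    d_out = np.empty((config.chains, n_keep, K))
    tau_out = np.empty((config.chains, n_keep))
    mu_out = np.empty((config.chains, n_keep, n_studies))
    ddir_out = np.empty((config.chains, n_keep))
    for c_idx in range(config.chains):
        chain_seed = int(rng.integers(0, 2**31 - 1))
        d0 = np.zeros(K)
        d0[1:] = rng.normal(0.0, 0.25, K - 1)  # overdispersed starts
        dd, tt, mm, ddd = _sampler.run_chain(
            chain_seed,
            config.iterations,
            config.burn_in,
            config.thin,
            arm_r,
            arm_n,
            arm_study,
            arm_treat,
            study_start,
            direct_flag,
            config.prior_sd_effects,
            config.tau_upper,
            mu0 + rng.normal(0.0, 0.2, n_studies),
            delta0 + rng.normal(0.0, 0.2, len(arm_r)) * nonbase,
            d0,
            float(rng.uniform(0.1, 1.0)),
            0.0,
        )
        d_out[c_idx], tau_out[c_idx], mu_out[c_idx], ddir_out[c_idx] = dd, tt, mm, ddd

    has_direct = bool(direct_flag.any())
    codes = sorted(i.code for i in net.interventions)
    diagnostics = _compute_diagnostics(d_out, tau_out, ddir_out if has_direct else None, codes)
    bad = diagnostics[diagnostics["rhat"] > config.rhat_threshold]
    if len(bad):
        warnings.warn(
            "MCMC may not have converged; split-chain R-hat above "
            f"{config.rhat_threshold} for: {', '.join(bad.index)} "
            f"(max {bad['rhat'].max():.3f}). Increase iterations.",
            ConvergenceWarning,
            stacklevel=2,
        )
    return NMAResult(
        network=network,
        config=config,
        d=d_out,
        tau=tau_out,
        mu=mu_out,
        d_direct=ddir_out if has_direct else None,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------


def relative_effects(result: NMAResult) -> pd.DataFrame:
    """K x K table of odds ratios: entry (c, k) = median (CrI) of OR of k vs c.

    Returned as a DataFrame with MultiIndex columns (code, {"or","low","high"})
    and one row per comparator code; the diagonal is exactly 1.
    """
    codes = result.codes
    data = {}
    for k in codes:
        med = np.empty(len(codes))
        lo = np.empty(len(codes))
        hi = np.empty(len(codes))
        for i, c in enumerate(codes):
            if c == k:
                med[i] = lo[i] = hi[i] = 1.0
            else:
                med[i], lo[i], hi[i] = result.or_summary(c, k)
        data[(k, "or")] = med
        data[(k, "low")] = lo
        data[(k, "high")] = hi
    df = pd.DataFrame(data, index=pd.Index(codes, name="comparator"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["intervention", "stat"])
    return df


def rank_interventions(result: NMAResult, higher_is_better: bool = True) -> pd.DataFrame:
    """Rank summary per intervention: median rank, 95% CrI, probability best.

    Per posterior draw interventions are ranked by their basic parameter
    (rank 1 = best; for uptake outcomes larger log-odds is better).
    """
    d = result.d_flat
    if not higher_is_better:
        d = -d
    order = np.argsort(-d, axis=1, kind="stable")
    ranks = np.empty_like(order)
    m, K = d.shape
    ranks[np.arange(m)[:, None], order] = np.arange(1, K + 1)[None, :]
    codes = result.codes
    lo, med, hi = np.percentile(ranks, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "label": [result.network.label(c) for c in codes],
            "median_rank": np.round(med).astype(int),
            "rank_low": np.floor(lo).astype(int),
            "rank_high": np.ceil(hi).astype(int),
            "probability_best": (ranks == 1).mean(axis=0),
        },
        index=pd.Index(codes, name="intervention"),
    )


def _two_treatment_subnetwork(network: Network, contrast: tuple[int, int]) -> Network | None:
    """Direct studies only, relabelled to a 2-intervention network (c -> 1, k -> 2)."""
    c, k = sorted(contrast)
    direct = network.direct_studies((c, k))
    if not direct:
        return None
    relabel = {c: 1, k: 2}
    studies = []
    for s in direct:
        arms = tuple(
            Arm(relabel[a.intervention], a.events, a.size)
            for a in s.arms
            if a.intervention in relabel
        )
        studies.append(replace(s, arms=arms))
    interventions = (
        Intervention(1, network.label(c)),
        Intervention(2, network.label(k)),
    )
    return Network(interventions=interventions, studies=tuple(studies))


def fit_pairwise(
    network: Network, contrast: tuple[int, int], config: NMAConfig | None = None
) -> PairwiseResult | None:
    """Random-effects pairwise meta-analysis of the direct evidence for a contrast.

    Same likelihood and priors as :func:`fit_nma`, restricted to the studies
    directly comparing the pair.  Returns ``None`` when there is no direct
    evidence (the "NA" cells of a league table).
    """
    c, k = sorted(contrast)
    sub = _two_treatment_subnetwork(network, (c, k))
    if sub is None:
        return None
    res = fit_nma(sub, config or NMAConfig())
    draws = res.contrast_draws(1, 2)
    med, lo, hi = res.or_summary(1, 2)
    return PairwiseResult(
        contrast=(c, k),
        n_studies=len(sub.studies),
        or_median=med,
        or_ci=(lo, hi),
        log_or_draws=draws,
    )


def is_splittable(network: Network, contrast: tuple[int, int]) -> bool:
    """True when a contrast has direct evidence plus an independent indirect path."""
    c, k = sorted(contrast)
    direct = network.direct_studies((c, k))
    if not direct:
        return False
    rest = [s for s in network.studies if s not in direct]
    g = nx.Graph()
    g.add_nodes_from([c, k])
    for s in rest:
        t = s.treatments
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                g.add_edge(t[i], t[j])
    return nx.has_path(g, c, k)


def node_split(
    network: Network, contrast: tuple[int, int], config: NMAConfig | None = None
) -> NodeSplitResult:
    """Node-splitting consistency check for one contrast in a closed loop.

    Refits the NMA with a separate direct-effect parameter for the studies
    observing the contrast; the consistency parameters ``d`` are then informed
    by the remaining (indirect) evidence only.  The two-sided tail probability
    of the direct-minus-indirect difference crossing zero is reported as the
    inconsistency p-value.
    """
    c, k = sorted(contrast)
    if not is_splittable(network, (c, k)):
        raise NotSplittableError(
            f"contrast {c} vs {k} has no closed loop of direct and indirect evidence"
        )
    for s in network.direct_studies((c, k)):
        if len(s.arms) != 2:
            raise NotSplittableError(
                f"node-splitting supports two-arm direct studies only (study {s.study_id})"
            )
    res = fit_nma(network, config or NMAConfig(), _direct_contrast=(c, k))
    assert res.d_direct is not None
    direct = res.d_direct.reshape(-1)
    indirect = res.contrast_draws(c, k)
    diff = direct - indirect
    p_gt = float((diff > 0).mean())
    p = 2.0 * min(p_gt, 1.0 - p_gt)
    def _summ(x):
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        return float(med), float(lo), float(hi)
    return NodeSplitResult(contrast=(c, k), direct=_summ(direct), indirect=_summ(indirect), p_value=p)
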