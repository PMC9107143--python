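"""Decision-threshold (bias-adjustment) analysis for a fitted NMA.

For each data point — a study's log odds ratio (study level) or the pooled
direct evidence for a treatment contrast (contrast level) — the analysis asks:
how large an additive bias adjustment to that estimate would change which
intervention has the highest expected effect?  The negative and positive
thresholds bound the *decision-invariant bias-adjustment interval*: as long as
the data point stays inside it, the recommendation stands.  A side with no
finite threshold is reported as NT ("no threshold").

The implementation uses a first-order (linear) approximation to the influence
of each data point on the posterior means of the basic parameters,

    U = Sigma_post @ X.T @ V^{-1},

where ``Sigma_post`` is the posterior covariance of the free basic parameters
(estimated from the MCMC draws), ``X`` the +1/-1 design matrix mapping basic
parameters to each data point's contrast, and ``V`` the diagonal likelihood
covariance — ``v_j + tau^2`` at study level, ``v_pool + tau^2 / m_j`` at
contrast level (``m_j`` direct studies), with ``tau`` plugged in at its
posterior median.  This is exact for normal likelihoods and conjugate priors;
:func:`brute_force_decision_flip` provides an exact (refitting) oracle to
check it.

A row is *robust* when the data point's 95% interval lies inside its invariant
interval: no plausible imprecision-sized change flips the recommendation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import (
    Arm,
    ContrastEstimate,
    Network,
    apply_continuity_correction,
    study_contrast_estimates,
)
from .nma import NMAConfig, NMAResult, fit_nma

__all__ = [
    "InfluenceMatrix",
    "ThresholdRow",
    "ThresholdReport",
    "BruteForceFlip",
    "optimal_intervention",
    "influence_matrix",
    "compute_thresholds",
    "study_level_threshold_analysis",
    "contrast_level_threshold_analysis",
    "threshold_forest_table",
    "brute_force_decision_flip",
    "plot_threshold_forest",
]

Z975 = 1.959963984540054


def optimal_intervention(d_means: np.ndarray, codes: list[int] | None = None) -> int:
    """Code of the intervention with the highest expected effect (largest d).

    Ties are broken toward the lowest code, with a warning.
    """
    d_means = np.asarray(d_means, dtype=float)
    codes = codes or list(range(1, len(d_means) + 1))
    best = float(d_means.max())
    tied = [c for c, v in zip(codes, d_means) if v == best]
    if len(tied) > 1:
        warnings.warn(
            f"tie for the optimal intervention among codes {tied}; choosing {tied[0]}",
            UserWarning,
            stacklevel=2,
        )
    return tied[0]


@dataclass(frozen=True)
class InfluenceMatrix:
    """First-order influence of each data point on each free basic parameter.

    ``u[i, j]`` is the change in the posterior mean of ``d`` for free code
    ``free_codes[i]`` per unit additive bias in data point ``j``.
    """

    u: np.ndarray  # (K-1, J)
    free_codes: tuple[int, ...]  # codes 2..K in order of u's rows
    data_points: tuple[ContrastEstimate, ...]
    intervals: tuple[tuple[float, float], ...]  # 95% interval per data point
    level: str  # "study" | "contrast"
    tau_hat: float


@dataclass(frozen=True)
class ThresholdRow:
    id: str
    contrast: tuple[int, int]
    estimate: float
    ci_low: float
    ci_high: float
    eps_neg: float  # <= 0, -inf means NT
    eps_pos: float  # >= 0, +inf means NT
    new_optimal_low: int | None  # becomes optimal if bias < eps_neg
    new_optimal_high: int | None
    robust: bool

    @property
    def invariant_interval(self) -> tuple[float, float]:
        return self.estimate + self.eps_neg, self.estimate + self.eps_pos

    @property
    def min_abs_threshold(self) -> float:
        return min(abs(self.eps_neg), abs(self.eps_pos))


@dataclass(frozen=True)
class ThresholdReport:
    level: str
    base_optimal: int
    rows: tuple[ThresholdRow, ...]

    @property
    def n_nonrobust(self) -> int:
        return sum(not r.robust for r in self.rows)

    def nonrobust_ids(self) -> list[str]:
        return [r.id for r in self.rows if not r.robust]

    def row(self, id: str | int) -> ThresholdRow:
        for r in self.rows:
            if r.id == str(id):
                return r
        raise KeyError(f"no threshold row with id {id!r}")

    def to_frame(self) -> pd.DataFrame:
        return threshold_forest_table(self)


# ---------------------------------------------------------------------------


def _contrast_level_data(
    network: Network, result: NMAResult
) -> tuple[list[ContrastEstimate], list[int], list[tuple[float, float]]]:
    """Inverse-variance pools of the direct studies per observed contrast.

    The reported 95% interval is the posterior credible interval of the
    contrast from the NMA (the combined evidence the decision actually uses).
    """
    per_study = study_contrast_estimates(network)
    pooled, m_counts, intervals = [], [], []
    for c, k in network.observed_contrasts():
        members = [e for e in per_study if tuple(sorted(e.treatments)) == (c, k)]
        members = [e if e.treatments == (c, k) else e.flipped() for e in members]
        w = np.array([1.0 / e.variance for e in members])
        y = np.array([e.estimate for e in members])
        est = float((w * y).sum() / w.sum())
        var = float(1.0 / w.sum())
        pooled.append(ContrastEstimate(f"{c}v{k}", (c, k), est, var))
        m_counts.append(len(members))
        lo, hi = np.percentile(result.contrast_draws(c, k), [2.5, 97.5])
        intervals.append((float(lo), float(hi)))
    return pooled, m_counts, intervals


def influence_matrix(network: Network, result: NMAResult, level: str = "study") -> InfluenceMatrix:
    """Build ``U = Sigma_post @ X.T @ V^{-1}`` for study- or contrast-level data points."""
    if level not in ("study", "contrast"):
        raise ValueError(f"level must be 'study' or 'contrast', got {level!r}")
    codes = result.codes
    free_codes = tuple(codes[1:])
    tau_hat = result.tau_median
    tau2 = tau_hat**2

    if level == "study":
        data_points = study_contrast_estimates(network)
        v = np.array([e.variance + tau2 for e in data_points])
        intervals = [
            (e.estimate - Z975 * math.sqrt(e.variance), e.estimate + Z975 * math.sqrt(e.variance))
            for e in data_points
        ]
    else:
        data_points, m_counts, intervals = _contrast_level_data(network, result)
        v = np.array([e.variance + tau2 / m for e, m in zip(data_points, m_counts)])

    if np.any(v <= 0):
        j = int(np.argmin(v))
        raise ValueError(f"non-positive likelihood variance for data point {data_points[j].id}")

    col = {c: i for i, c in enumerate(free_codes)}
    X = np.zeros((len(data_points), len(free_codes)))
    for j, e in enumerate(data_points):
        c, k = e.treatments
        if k in col:
            X[j, col[k]] = 1.0
        if c in col:
            X[j, col[c]] = -1.0
    sigma_post = np.atleast_2d(result.d_posterior_cov())
    u = sigma_post @ X.T @ np.diag(1.0 / v)
    return InfluenceMatrix(
        u=u,
        free_codes=free_codes,
        data_points=tuple(data_points),
        intervals=tuple(intervals),
        level=level,
        tau_hat=tau_hat,
    )


def compute_thresholds(infl: InfluenceMatrix, d_means: np.ndarray, codes: list[int]) -> ThresholdReport:
    """Bias-adjustment thresholds and invariant intervals for every data point.

    For data point ``j`` and each rival ``a`` of the base-case optimum ``k*``,
    the bias that equalises their posterior means is

        eps = (d_hat[k*] - d_hat[a]) / (u[a, j] - u[k*, j]);

    the smallest positive and largest negative candidates are the thresholds,
    and the rival attaining them is the new optimum on that side.
    """
    d_means = np.asarray(d_means, dtype=float)
    if len(d_means) != len(codes):
        raise ValueError("d_means and codes length mismatch")
    kstar = optimal_intervention(d_means, codes)
    idx = {c: i for i, c in enumerate(codes)}
    # influence of each data point on every code (reference row is zero)
    u_full = np.zeros((len(codes), len(infl.data_points)))
    for i, c in enumerate(infl.free_codes):
        u_full[idx[c]] = infl.u[i]

    rows = []
    for j, (e, ci) in enumerate(zip(infl.data_points, infl.intervals)):
        eps_neg, eps_pos = -math.inf, math.inf
        new_lo: int | None = None
        new_hi: int | None = None
        for a in codes:
            if a == kstar:
                continue
            denom = u_full[idx[a], j] - u_full[idx[kstar], j]
            if denom == 0.0:
                continue
            eps = (d_means[idx[kstar]] - d_means[idx[a]]) / denom
            if eps > 0 and eps < eps_pos:
                eps_pos, new_hi = eps, a
            elif eps < 0 and eps > eps_neg:
                eps_neg, new_lo = eps, a
        robust = ci[0] >= e.estimate + eps_neg and ci[1] <= e.estimate + eps_pos
        rows.append(
            ThresholdRow(
                id=e.id,
                contrast=e.treatments,
                estimate=e.estimate,
                ci_low=ci[0],
                ci_high=ci[1],
                eps_neg=eps_neg,
                eps_pos=eps_pos,
                new_optimal_low=new_lo,
                new_optimal_high=new_hi,
                robust=robust,
            )
        )
    return ThresholdReport(level=infl.level, base_optimal=kstar, rows=tuple(rows))


def study_level_threshold_analysis(network: Network, result: NMAResult) -> ThresholdReport:
    infl = influence_matrix(network, result, level="study")
    return compute_thresholds(infl, result.d_means, result.codes)


def contrast_level_threshold_analysis(network: Network, result: NMAResult) -> ThresholdReport:
    infl = influence_matrix(network, result, level="contrast")
    return compute_thresholds(infl, result.d_means, result.codes)


def threshold_forest_table(report: ThresholdReport) -> pd.DataFrame:
    """Tabular export of a threshold report; unbounded thresholds become "NT".

    ``df.attrs["n_nonrobust"]`` carries the summary count of non-robust rows.
    """
    def _fmt(x: float) -> float | str:
        return "NT" if math.isinf(x) else round(x, 4)

    recs = []
    for r in report.rows:
        inv_lo, inv_hi = r.invariant_interval
        recs.append(
            {
                "id": r.id,
                "contrast": f"{r.contrast[1]} vs {r.contrast[0]}",
                "estimate": round(r.estimate, 4),
                "ci_low": round(r.ci_low, 4),
                "ci_high": round(r.ci_high, 4),
                "eps_neg": _fmt(r.eps_neg),
                "eps_pos": _fmt(r.eps_pos),
                "inv_low": _fmt(inv_lo),
                "inv_high": _fmt(inv_hi),
                "new_opt_low": r.new_optimal_low,
                "new_opt_high": r.new_optimal_high,
                "robust": r.robust,
            }
        )
    df = pd.DataFrame(recs)
    df.attrs["level"] = report.level
    df.attrs["base_optimal"] = report.base_optimal
    df.attrs["n_nonrobust"] = report.n_nonrobust
    return df


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BruteForceFlip:
    """Exact flip points found by refitting: None on a side means no flip within range."""

    study_id: int
    base_optimal: int
    negative: float | None
    positive: float | None


def _perturb_study(network: Network, study_id: int, bias: float) -> Network:
    """Shift the non-baseline arm's log-odds of one two-arm study by ``bias``."""
    studies = []
    for s in network.studies:
        if s.study_id == study_id:
            if len(s.arms) != 2:
                raise ValueError("brute-force perturbation supports two-arm studies only")
            base_code = s.treatments[0]
            arms = []
            for a in s.arms:
                if a.intervention == base_code:
                    arms.append(a)
                else:
                    eta = math.log(a.events / (a.size - a.events)) + bias
                    r_new = a.size / (1.0 + math.exp(-eta))
                    arms.append(Arm(a.intervention, r_new, a.size))
            s = replace(s, arms=tuple(sorted(arms, key=lambda a: a.intervention)))
        studies.append(s)
    return replace(network, studies=tuple(studies))


def brute_force_decision_flip(
    network: Network,
    study_id: int,
    config: NMAConfig,
    grid: float = 0.05,
    max_bias: float = 5.0,
    direction: str = "both",
) -> BruteForceFlip:
    """Oracle for the linear thresholds: refit the NMA on a grid of biases.

    Walks outward from zero in steps of ``grid`` on each side (or only the
    requested ``direction``), shifting the named study's log odds ratio, until
    the refitted optimal intervention changes; ``None`` on a side means no
    flip within ``max_bias`` (NT).
    """
    if grid > 0.05 + 1e-12:
        raise ValueError("grid step must be <= 0.05")
    if direction not in ("both", "negative", "positive"):
        raise ValueError("direction must be 'both', 'negative' or 'positive'")
    net = apply_continuity_correction(network)
    base = fit_nma(net, config)
    k0 = optimal_intervention(base.d_means, base.codes)

    def _scan(sign: float) -> float | None:
        n_steps = int(round(max_bias / grid))
        for step in range(1, n_steps + 1):
            bias = sign * step * grid
            res = fit_nma(_perturb_study(net, study_id, bias), config)
            if optimal_intervention(res.d_means, res.codes) != k0:
                return bias
        return None

    return BruteForceFlip(
        study_id=study_id,
        base_optimal=k0,
        negative=_scan(-1.0) if direction in ("both", "negative") else None,
        positive=_scan(+1.0) if direction in ("both", "positive") else None,
    )


def plot_threshold_forest(report: ThresholdReport, ax=None):
    """Forest-style plot of estimates, 95% intervals and invariant intervals.

    Non-robust rows are drawn in red.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.45 * len(report.rows) + 1.5))
    for y, r in enumerate(reversed(report.rows)):
        color = "red" if not r.robust else "black"
        inv_lo, inv_hi = r.invariant_interval
        lo = inv_lo if math.isfinite(inv_lo) else r.ci_low - 2
        hi = inv_hi if math.isfinite(inv_hi) else r.ci_high + 2
        ax.plot([lo, hi], [y + 0.18] * 2, color="0.6", lw=5, alpha=0.5, solid_capstyle="butt")
        ax.plot([r.ci_low, r.ci_high], [y, y], color=color, lw=1.5)
        ax.plot([r.estimate], [y], "s", color=color, ms=5)
        ax.text(-0.01, y, str(r.id), transform=ax.get_yaxis_transform(), ha="right", va="center")
    ax.axvline(0.0, color="0.7", lw=0.8, ls="--")
    ax.set_yticks([])
    ax.set_xlabel("log odds ratio")
    ax.set_title(f"{report.level}-level thresholds (base optimum: {report.base_optimal})")
    return ax
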