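"""Simulated evidence networks with known generating truth.

The generator is the exact inverse of the model fitted by
:func:`thresholdnma.nma.fit_nma`: study baselines are normal on the log-odds
scale, study-specific treatment effects are drawn around a single consistent
basic-parameter vector with between-study SD ``tau`` (multi-arm studies use
the correlated construction, variance ``tau^2`` and pairwise correlation 1/2),
and arm counts are binomial.  Optional per-study additive biases on the
log-OR scale emulate the bias adjustments probed by the threshold analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import Arm, Intervention, Network, Study

__all__ = ["SyntheticTruth", "simulate_network", "poison_like_scenario", "POISON_TOPOLOGY"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters kept alongside a simulated network.

    ``d_true`` has length K with the reference entry 0.  ``biases`` maps a
    study id to an additive log-OR bias applied to that study's effect.
    """

    d_true: tuple[float, ...]
    tau_true: float = 0.2
    baseline_mean: float = -0.5
    baseline_sd: float = 0.5
    biases: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_true[0] != 0.0:
            raise ValueError("d_true must have reference entry 0 first")
        if self.tau_true < 0:
            raise ValueError("tau_true must be non-negative")

    def to_dict(self) -> dict:
        return {
            "d_true": list(self.d_true),
            "tau_true": self.tau_true,
            "baseline_mean": self.baseline_mean,
            "baseline_sd": self.baseline_sd,
            "biases": {int(k): float(v) for k, v in self.biases.items()},
            "seed": self.seed,
        }


def _spanning_contrasts(K: int, n_studies: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    """A connected set of two-arm contrasts: spanning star first, then random pairs."""
    if n_studies < K - 1:
        raise ValueError(f"need at least K-1={K-1} studies to connect {K} interventions")
    contrasts: list[tuple[int, ...]] = [(1, k) for k in range(2, K + 1)]
    while len(contrasts) < n_studies:
        c, k = sorted(rng.choice(np.arange(1, K + 1), size=2, replace=False))
        contrasts.append((int(c), int(k)))
    return contrasts


def simulate_network(
    K: int,
    n_studies: int,
    truth: SyntheticTruth,
    arm_size: int = 200,
    contrasts: list[tuple[int, ...]] | None = None,
    arms_per_study: int = 2,
) -> tuple[Network, SyntheticTruth]:
    """Simulate a connected network of (by default two-arm) studies.

    ``contrasts`` fixes the treatment sets per study; otherwise a spanning
    star plus random pairs is used.  With ``arms_per_study > 2`` the random
    design draws that many distinct treatments per study instead.
    """
    if K < 2:
        raise ValueError("need at least two interventions")
    if len(truth.d_true) != K:
        raise ValueError(f"d_true has length {len(truth.d_true)}, expected K={K}")
    rng = np.random.default_rng(truth.seed)
    if contrasts is None:
        if arms_per_study == 2:
            contrasts = _spanning_contrasts(K, n_studies, rng)
        else:
            if arms_per_study > K:
                raise ValueError("arms_per_study cannot exceed K")
            contrasts = [tuple(range(1, arms_per_study + 1))] + [
                tuple(
                    sorted(
                        int(x)
                        for x in rng.choice(np.arange(1, K + 1), size=arms_per_study, replace=False)
                    )
                )
                for _ in range(n_studies - 1)
            ]
    elif len(contrasts) != n_studies:
        raise ValueError("one contrast (treatment set) per study required")

    d = np.asarray(truth.d_true)
    studies = []
    for sid, treats in enumerate(contrasts, start=1):
        treats = tuple(sorted(treats))
        mu = rng.normal(truth.baseline_mean, truth.baseline_sd)
        m = len(treats) - 1
        mean = d[np.array(treats[1:]) - 1] - d[treats[0] - 1] + truth.biases.get(sid, 0.0)
        cov = truth.tau_true**2 * 0.5 * (np.eye(m) + np.ones((m, m)))
        delta = rng.multivariate_normal(mean, cov) if truth.tau_true > 0 else np.asarray(mean, float)
        etas = np.concatenate([[mu], mu + delta])
        arms = tuple(
            Arm(t, float(rng.binomial(arm_size, 1.0 / (1.0 + np.exp(-eta)))), float(arm_size))
            for t, eta in zip(treats, etas)
        )
        studies.append(Study(study_id=sid, name=f"Synthetic {sid}", design="RCT", arms=arms))
    interventions = tuple(Intervention(c, f"Intervention {c}") for c in range(1, K + 1))
    net = Network(interventions=interventions, studies=tuple(studies), outcome_label="synthetic uptake")
    return net, truth


# Topology of the poison-prevention network: 15 two-arm studies over 7 interventions.
POISON_TOPOLOGY: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 2), (1, 2), (1, 2), (1, 2),
    (1, 3), (1, 3),
    (1, 4), (1, 4), (1, 4),
    (1, 5),
    (2, 3),
    (2, 5),
    (3, 7),
    (4, 6),
)


def poison_like_scenario(
    seed: int,
    d_true: tuple[float, ...] | None = None,
    tau_true: float = 0.8,
    arm_size: int = 100,
    biases: dict[int, float] | None = None,
) -> tuple[Network, SyntheticTruth]:
    """A synthetic network with the poison-prevention network's shape.

    Seven interventions, fifteen two-arm studies, sparse contrasts including
    two bridge edges (3-7, 4-6).  Default truth mimics the fitted network:
    moderate positive effects, one weak singleton arm, high heterogeneity.
    """
    if d_true is None:
        d_true = (0.0, 0.25, 0.8, 0.95, 0.3, 1.1, -1.0)
    truth = SyntheticTruth(
        d_true=tuple(d_true), tau_true=tau_true, biases=dict(biases or {}), seed=seed
    )
    return simulate_network(
        7, len(POISON_TOPOLOGY), truth, arm_size=arm_size, contrasts=list(POISON_TOPOLOGY)
    )
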