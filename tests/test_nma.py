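"""Sampler correctness: null cases, exact posterior identities, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import FAST, quiet_fit
from thresholdnma import (
    Arm,
    ConvergenceWarning,
    Intervention,
    Network,
    NMAConfig,
    NotSplittableError,
    SyntheticTruth,
    fit_nma,
    fit_pairwise,
    node_split,
    rank_interventions,
    relative_effects,
    simulate_network,
)
from thresholdnma.data_model import Study, study_contrast_estimates


def identical_arm_network(K, n_studies, events=30, size=60):
    """Every study compares identical arms: all true effects are exactly zero."""
    studies = []
    for sid in range(1, n_studies + 1):
        c, k = 1 + (sid - 1) % (K - 1), 1 + (sid - 1) % (K - 1) + 1
        arms = (Arm(c, events, size), Arm(k, events, size))
        studies.append(Study(study_id=sid, name=f"s{sid}", design="RCT", arms=arms))
    inter = tuple(Intervention(c, f"i{c}") for c in range(1, K + 1))
    return Network(interventions=inter, studies=tuple(studies))


def test_config_invariants():
    with pytest.raises(ValueError):
        NMAConfig(chains=1)
    with pytest.raises(ValueError):
        NMAConfig(iterations=100, burn_in=100)


def test_null_network_effects_centred_at_zero(fast_config):
    net = identical_arm_network(3, 9)
    res = quiet_fit(net, fast_config)
    assert np.all(np.abs(res.d_means) < 0.35)


def test_two_intervention_symmetry_probability_best(fast_config):
    net = identical_arm_network(2, 6)
    res = quiet_fit(net, fast_config)
    pbest = rank_interventions(res).probability_best
    assert pbest.sum() == pytest.approx(1.0)
    assert pbest[1] == pytest.approx(0.5, abs=0.1)


def test_or_table_identity_and_reciprocity(poison_fit):
    # per-draw antisymmetry of contrasts makes the OR table exactly reciprocal
    draws_fwd = poison_fit.contrast_draws(1, 3)
    draws_rev = poison_fit.contrast_draws(3, 1)
    assert np.array_equal(draws_fwd, -draws_rev)
    table = relative_effects(poison_fit)
    for k in poison_fit.codes:
        assert table.loc[k, (k, "or")] == 1.0
    m_fwd = table.loc[1, (3, "or")]
    m_rev = table.loc[3, (1, "or")]
    # reciprocal up to the percentile interpolation between adjacent draws
    assert m_fwd == pytest.approx(1.0 / m_rev, rel=1e-4)


def test_probability_best_sums_to_one(poison_fit, stair_fit):
    for res in (poison_fit, stair_fit):
        rt = rank_interventions(res)
        assert rt.probability_best.sum() == pytest.approx(1.0, abs=1e-3)
        assert set(rt.columns) >= {"median_rank", "rank_low", "rank_high", "probability_best"}


def test_ranking_direction_flag(poison_fit):
    best_up = rank_interventions(poison_fit, higher_is_better=True)
    best_down = rank_interventions(poison_fit, higher_is_better=False)
    # usual care is near-worst for uptake, near-best when the scale flips
    assert best_up.loc[1, "median_rank"] >= 6
    assert best_down.loc[1, "median_rank"] <= 2


def test_common_effect_limit_matches_gls_oracle():
    """With the heterogeneity prior pinned at ~0 the model is common-effect,
    so posterior means of d must match weighted least squares on the
    study-level log odds ratios."""
    truth = SyntheticTruth(d_true=(0.0, 0.4, 0.8), tau_true=0.0, seed=5)
    net, _ = simulate_network(3, 9, truth, arm_size=2000)
    ests = study_contrast_estimates(net)
    X = np.zeros((len(ests), 2))
    y = np.array([e.estimate for e in ests])
    w = np.array([1.0 / e.variance for e in ests])
    for j, e in enumerate(ests):
        c, k = e.treatments
        if k > 1:
            X[j, k - 2] = 1.0
        if c > 1:
            X[j, c - 2] = -1.0
    gls = np.linalg.solve((X.T * w) @ X, (X.T * w) @ y)

    cfg = NMAConfig(chains=2, iterations=9000, burn_in=3000, thin=3, seed=9, tau_upper=0.02)
    res = quiet_fit(net, cfg)
    assert np.allclose(res.d_means[1:], gls, atol=0.06)


def test_fixed_seed_reproducible(fast_config):
    net = identical_arm_network(3, 6)
    a = quiet_fit(net, fast_config)
    b = quiet_fit(net, fast_config)
    assert np.array_equal(a.d, b.d)
    assert np.array_equal(a.tau, b.tau)


def test_deliberately_short_run_warns_about_convergence(poison_network):
    cfg = NMAConfig(chains=2, iterations=160, burn_in=150, thin=1, seed=4)
    with pytest.warns(ConvergenceWarning):
        fit_nma(poison_network, cfg)


def test_multi_arm_studies_supported(fast_config):
    truth = SyntheticTruth(d_true=(0.0, 0.3, 0.6, 0.2), tau_true=0.15, seed=3)
    net, _ = simulate_network(4, 8, truth, arm_size=300, arms_per_study=3)
    assert any(len(s.arms) == 3 for s in net.studies)
    res = quiet_fit(net, fast_config)
    assert res.d.shape[-1] == 4
    assert np.all(np.abs(res.d_means[1:] - np.array(truth.d_true)[1:]) < 0.5)


# ---------------------------------------------------------------------------
# pairwise meta-analysis and node-splitting


def test_pairwise_no_direct_evidence_is_none(poison_network, fast_config):
    assert fit_pairwise(poison_network, (1, 6), fast_config) is None


def test_pairwise_single_study_interval_at_least_delta_method(poison_network, fast_config):
    # contrast 4 vs 6 is observed by study 15 only
    pw = fit_pairwise(poison_network, (4, 6), fast_config)
    assert pw.n_studies == 1
    est = study_contrast_estimates(poison_network)[14]
    ci_width_delta = 2 * 1.96 * np.sqrt(est.variance)
    ci_width_post = np.log(pw.or_ci[1]) - np.log(pw.or_ci[0])
    assert ci_width_post >= ci_width_delta * 0.95


def test_node_split_requires_closed_loop(poison_network, fast_config):
    with pytest.raises(NotSplittableError):
        node_split(poison_network, (4, 6), fast_config)  # bridge edge
    with pytest.raises(NotSplittableError):
        node_split(poison_network, (1, 6), fast_config)  # no direct evidence


def _loop_network(seed, bias=0.0, tau=0.15):
    """K=3 with direct evidence on every edge; optional bias injected into
    the 1-3 studies creates direct-vs-indirect inconsistency on that edge."""
    truth = SyntheticTruth(
        d_true=(0.0, 0.4, 0.7),
        tau_true=tau,
        seed=seed,
        biases={sid: bias for sid in (7, 8, 9)},
    )
    contrasts = [(1, 2)] * 3 + [(2, 3)] * 3 + [(1, 3)] * 3
    net, _ = simulate_network(3, 9, truth, arm_size=300, contrasts=contrasts)
    return net


def test_node_split_calibrated_under_consistency(fast_config):
    """With data generated from a single consistent d_true, inconsistency
    p-values are rarely small."""
    import warnings

    pvals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for seed in range(30):
            net = _loop_network(seed)
            pvals.append(node_split(net, (1, 3), fast_config).p_value)
    assert np.mean(np.array(pvals) < 0.05) <= 0.2


def test_node_split_detects_injected_inconsistency(fast_config):
    import warnings

    pvals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for seed in (100, 101, 102):
            net = _loop_network(seed, bias=2.0)
            pvals.append(node_split(net, (1, 3), fast_config).p_value)
    assert np.median(pvals) < 0.05


def test_node_split_consistent_fixture_contrast(poison_network, fast_config):
    ns = node_split(poison_network, (1, 2), fast_config)
    assert 0.0 <= ns.p_value <= 1.0
    assert ns.p_value > 0.05  # network shows no sign of inconsistency
    lo, hi = ns.direct[1], ns.direct[2]
    assert lo < ns.direct[0] < hi
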