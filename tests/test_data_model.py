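"""Data types, CSV round-trips, continuity correction and effect summaries."""

from __future__ import annotations

import math

import hypothesis.strategies as st
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings

from thresholdnma import (
    Arm,
    Intervention,
    Network,
    NetworkConnectivityError,
    NetworkFormatError,
    NetworkValidationError,
    Study,
    apply_continuity_correction,
    cluster_adjust,
    continuity_correct,
    load_network,
    log_odds_ratio,
    study_contrast_estimates,
    write_network,
)


def make_study(sid, arms, design="RCT"):
    return Study(study_id=sid, name=f"s{sid}", design=design, arms=tuple(arms))


# ---------------------------------------------------------------------------
# continuity correction


@pytest.mark.parametrize(
    "events, size, expected",
    [(0, 104, (0.5, 105)), (1, 101, (1.5, 102)), (5, 10, (5.5, 11))],
)
def test_continuity_correct_adds_half_event_one_total(events, size, expected):
    assert continuity_correct(events, size) == expected


def test_continuity_correct_rejects_negative_input():
    with pytest.raises(NetworkValidationError):
        continuity_correct(-1, 10)


def test_correction_applied_to_all_arms_of_zero_cell_studies_only():
    zero_cell = make_study(1, [Arm(1, 1, 101), Arm(2, 0, 104)])
    clean = make_study(2, [Arm(1, 5, 10), Arm(2, 6, 10)])
    net = Network(
        interventions=(Intervention(1, "a"), Intervention(2, "b")),
        studies=(zero_cell, clean),
    )
    out = apply_continuity_correction(net)
    assert [(a.events, a.size) for a in out.studies[0].arms] == [(1.5, 102), (0.5, 105)]
    assert [(a.events, a.size) for a in out.studies[1].arms] == [(5, 10), (6, 10)]


# ---------------------------------------------------------------------------
# cluster adjustment


@pytest.mark.parametrize(
    "events, size, m, icc, expected",
    [
        (100, 200, 5, 0.05, (100 / 1.2, 200 / 1.2)),  # DEFF = 1.2
        (100, 200, 5, 0.0, (100, 200)),  # no clustering
        (100, 200, 1, 0.9, (100, 200)),  # singleton clusters
    ],
)
def test_cluster_adjust_design_effect(events, size, m, icc, expected):
    out = cluster_adjust(events, size, m, icc)
    assert out == pytest.approx(expected)


@pytest.mark.parametrize("icc", [-0.1, 1.0, 1.5])
def test_cluster_adjust_rejects_invalid_icc(icc):
    with pytest.raises(NetworkValidationError):
        cluster_adjust(10, 20, 5, icc)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    events=st.floats(0.0, 500.0),
    extra=st.floats(1.0, 500.0),
    m=st.floats(1.0, 50.0),
    icc=st.floats(0.0, 0.99),
)
def test_cluster_adjust_preserves_proportion(events, extra, m, icc):
    size = events + extra
    e2, s2 = cluster_adjust(events, size, m, icc)
    assert e2 / s2 == pytest.approx(events / size, rel=1e-12)


# ---------------------------------------------------------------------------
# log odds ratios


def test_log_odds_ratio_matches_hand_computed_examples():
    # Hendrickson 2002 (study 10): 14/40 vs 34/38
    est = log_odds_ratio(Arm(1, 14, 40), Arm(4, 34, 38))
    assert est.estimate == pytest.approx(2.759, abs=5e-3)
    # King 2001 (study 15): 261/469 vs 273/482
    est15 = log_odds_ratio(Arm(4, 261, 469), Arm(6, 273, 482))
    assert est15.estimate == pytest.approx(0.040, abs=5e-3)


def test_log_odds_ratio_identical_arms_zero_estimate():
    est = log_odds_ratio(Arm(1, 10, 20), Arm(2, 10, 20))
    assert est.estimate == 0.0
    assert est.variance == pytest.approx(0.4)


def test_log_odds_ratio_zero_cell_signals_missing_correction():
    with pytest.raises(ZeroDivisionError):
        log_odds_ratio(Arm(1, 0, 10), Arm(2, 5, 10))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    rc=st.floats(0.5, 200.0),
    nc_extra=st.floats(0.5, 200.0),
    rk=st.floats(0.5, 200.0),
    nk_extra=st.floats(0.5, 200.0),
)
def test_log_odds_ratio_antisymmetry(rc, nc_extra, rk, nk_extra):
    a = Arm(1, rc, rc + nc_extra)
    b = Arm(2, rk, rk + nk_extra)
    fwd = log_odds_ratio(a, b)
    rev = log_odds_ratio(b, a)
    assert fwd.estimate == pytest.approx(-rev.estimate, rel=1e-9, abs=1e-12)
    assert fwd.variance == pytest.approx(rev.variance, rel=1e-12)
    assert fwd.flipped().estimate == -fwd.estimate


# ---------------------------------------------------------------------------
# networks and I/O


def test_packaged_networks_shape(poison_network, stair_network):
    assert poison_network.n_studies == 15
    assert poison_network.n_interventions == 7
    assert stair_network.n_studies == 12
    assert stair_network.n_interventions == 7


def test_study_contrast_estimates_one_per_two_arm_study(poison_network):
    ests = study_contrast_estimates(poison_network)
    assert [e.id for e in ests] == [str(i) for i in range(1, 16)]
    assert ests[9].treatments == (1, 4)  # Hendrickson
    assert ests[14].treatments == (4, 6)  # King


def test_network_round_trip(tmp_path, poison_network):
    path = tmp_path / "net.csv"
    write_network(poison_network, path)
    back = load_network(path)
    for s0, s1 in zip(poison_network.studies, back.studies):
        assert s0.study_id == s1.study_id
        assert s0.design == s1.design
        assert [(a.intervention, a.events, a.size) for a in s0.arms] == [
            (a.intervention, a.events, a.size) for a in s1.arms
        ]


def test_load_network_missing_column_is_format_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("study_id,intervention,events\n1,1,5\n")
    with pytest.raises(NetworkFormatError):
        load_network(p)


def test_load_network_events_exceeding_size_is_validation_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text(
        "study_id,study_name,design,intervention,events,size\n"
        "1,a,RCT,1,30,20\n1,a,RCT,2,5,20\n"
    )
    with pytest.raises(NetworkValidationError):
        load_network(p)


def test_disconnected_network_rejected(tmp_path):
    p = tmp_path / "disc.csv"
    p.write_text(
        "study_id,study_name,design,intervention,events,size\n"
        "1,a,RCT,1,5,20\n1,a,RCT,2,6,20\n"
        "2,b,RCT,3,5,20\n2,b,RCT,4,6,20\n"
    )
    with pytest.raises(NetworkConnectivityError):
        load_network(p)


def test_duplicate_arm_codes_rejected():
    with pytest.raises(NetworkValidationError):
        make_study(1, [Arm(1, 5, 10), Arm(1, 6, 10)])


def test_comparison_graphs_are_connected(poison_network, stair_network):
    import networkx as nx

    assert nx.is_connected(poison_network.graph())
    assert nx.is_connected(stair_network.graph())
    assert len(poison_network.observed_contrasts()) == 8
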