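"""Shared fixtures: the packaged networks and session-wide NMA fits.

The full-length fits (default sampler settings) are computed once per session
and reused by the replication and threshold tests; property tests use the
shorter ``fast_config`` on small synthetic networks.
"""

from __future__ import annotations

import warnings

import pytest

from thresholdnma import (
    ConvergenceWarning,
    NMAConfig,
    fit_nma,
    load_poison_network,
    load_stair_gates_network,
)

FAST = NMAConfig(chains=2, iterations=9000, burn_in=3000, thin=3, seed=314)


def quiet_fit(network, config):
    """Fit while suppressing convergence warnings from deliberately short runs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return fit_nma(network, config)


@pytest.fixture(scope="session")
def poison_network():
    return load_poison_network()


@pytest.fixture(scope="session")
def stair_network():
    return load_stair_gates_network()


@pytest.fixture(scope="session")
def poison_fit(poison_network):
    return fit_nma(poison_network, NMAConfig(seed=101))


@pytest.fixture(scope="session")
def stair_fit(stair_network):
    return fit_nma(stair_network, NMAConfig(seed=202))


@pytest.fixture()
def fast_config():
    return FAST
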