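"""Shared fixtures: small networks, series and chains used across tests."""

import numpy as np
import pytest

from rsnphi import (BinaryTimeSeries, GroundTruthNetwork, make_coupled_tpm,
                    simulate_binary_series)


@pytest.fixture(scope="session")
def coupled_3node_series():
    """A strongly coupled 3-node binary series (session-cached: IIT work)."""
    tpm = make_coupled_tpm(3, 0.8, seed=1)
    net = GroundTruthNetwork(3, tpm, 0.8)
    return simulate_binary_series(net, 600, seed=2)


@pytest.fixture(scope="session")
def factorized_3node_series():
    """An uncoupled (conditionally independent) 3-node series."""
    tpm = make_coupled_tpm(3, 0.0, seed=1)
    net = GroundTruthNetwork(3, tpm, 0.0)
    return simulate_binary_series(net, 600, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_subjects(n_subjects: int, n_timepoints: int, n_nodes: int,
                  coupling: float, seed: int) -> list[BinaryTimeSeries]:
    """Per-subject series drawn from one shared generative TPM."""
    tpm = make_coupled_tpm(n_nodes, coupling, seed=seed)
    net = GroundTruthNetwork(n_nodes, tpm, coupling)
    return [simulate_binary_series(net, n_timepoints, seed=seed * 1000 + i)
            for i in range(n_subjects)]
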