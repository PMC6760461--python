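import numpy as np
import pytest

import hyperconn as hc


@pytest.fixture(scope="session")
def coupled_dyad():
    """One synthesized dyad trial with a known lagged-coupling ground truth.

    12 s so that trimming to the central 10 s is non-trivial; computed once
    per test session.
    """
    cfg = hc.SimulationConfig(n_trials=2, trial_duration=12.0, seed=101, noise_sd=0.1)
    truth = hc.common_driver_truth()
    t1, t2 = hc.generate_dyad_trial(cfg, truth, 0)
    return cfg, truth, t1, t2


@pytest.fixture(scope="session")
def hyper_lps(coupled_dyad):
    """Hyperbrain LPS matrix of the coupled dyad (trimmed, default band)."""
    _, _, t1, t2 = coupled_dyad
    return hc.lps_matrix_for_trial((hc.trim_trial(t1), hc.trim_trial(t2)))


@pytest.fixture()
def small_adjacency():
    """A small handcrafted simple graph (5 nodes, 4 edges)."""
    m = np.zeros((5, 5), dtype=int)
    for a, b in [(0, 1), (1, 2), (2, 3), (3, 4)]:
        m[a, b] = m[b, a] = 1
    return hc.AdjacencyMatrix(
        labels=[f"n{i}" for i in range(5)], matrix=m, brain_sizes=(5,)
    )


def random_simple_graph(rng, n, p=0.3, ensure_edge=True):
    """Erdos-Renyi adjacency for oracle comparisons."""
    m = (rng.random((n, n)) < p).astype(int)
    m = np.triu(m, 1)
    m = m + m.T
    if ensure_edge and m.sum() == 0:
        m[0, 1] = m[1, 0] = 1
    return m
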