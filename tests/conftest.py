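"""Shared fixtures: the hand-checkable micro network and random generators."""

import numpy as np
import pytest

from locrec import (
    NetworkRecommender,
    SimulationConfig,
    TableSimilarity,
    build_network,
    compute_recommender_matrix,
    compute_transfer_matrix,
    simulate,
)


@pytest.fixture
def micro_net():
    """Two proteins, two locations: p1→{l1}, p2→{l1, l2}.

    Hand evaluation gives W = [[0.75, 0.5], [0.25, 0.5]] and
    R = [[0.75, 0.25], [1.25, 0.75]].
    """
    return build_network([("p1", {"l1"}), ("p2", {"l1", "l2"})], vocabulary=["l1", "l2"])


@pytest.fixture
def micro_matrices(micro_net):
    w = compute_transfer_matrix(micro_net)
    r = compute_recommender_matrix(micro_net, w)
    return micro_net, w, r


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small informative synthetic dataset shared across harness tests."""
    ds = simulate(SimulationConfig(n=40, m=6, seed=11))
    return ds, TableSimilarity(ds.pair_scores)


@pytest.fixture
def fitted_model(small_synthetic):
    ds, sim = small_synthetic
    return NetworkRecommender(tau=0.3).fit(ds.annotations), sim
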