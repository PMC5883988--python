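import numpy as np
import pytest

from sernet import (
    ConnectivityMatrix,
    FixtureSpec,
    SignedBinaryNetwork,
    make_population_connectivity,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connectivity(n_regions: int, seed: int) -> ConnectivityMatrix:
    """Random symmetric correlation-like matrix with both signs."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(-1, 1, size=(n_regions, n_regions))
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix(vals, [f"r{i}" for i in range(n_regions)])


@pytest.fixture
def conn_4regions() -> ConnectivityMatrix:
    """4-region matrix with off-diagonals {0.9, -0.8, 0.5, -0.4, 0.3, 0.1}."""
    vals = np.eye(4)
    pairs = {(0, 1): 0.9, (0, 2): -0.8, (0, 3): 0.5,
             (1, 2): -0.4, (1, 3): 0.3, (2, 3): 0.1}
    for (i, j), v in pairs.items():
        vals[i, j] = vals[j, i] = v
    return ConnectivityMatrix(vals, ["a", "b", "c", "d"])


@pytest.fixture
def conn_random() -> ConnectivityMatrix:
    return random_connectivity(20, seed=99)


@pytest.fixture
def small_population() -> ConnectivityMatrix:
    spec = FixtureSpec(n_regions=30, n_modules=3, anti_system_fraction=0.2,
                       n_subjects=5, seed=5)
    return make_population_connectivity(spec)


def zero_network(n: int) -> SignedBinaryNetwork:
    return SignedBinaryNetwork(np.zeros((n, n), dtype=np.int8),
                               positive_cost=0.0, negative_cost=0.0,
                               scheme="signed")


def network_from_pairs(n: int, pos=(), neg=()) -> SignedBinaryNetwork:
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in pos:
        adj[i, j] = adj[j, i] = 1
    for i, j in neg:
        adj[i, j] = adj[j, i] = -1
    p = n * (n - 1) // 2
    return SignedBinaryNetwork(adj, positive_cost=len(pos) / p,
                               negative_cost=len(neg) / p, scheme="signed")
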