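import numpy as np
import pytest

from netctrl import HMSWParams, WeightedNetwork, generate_network


@pytest.fixture
def edge_pair():
    """Two nodes joined by a unit-weight edge."""
    return WeightedNetwork(adjacency=np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def triangle():
    adj = np.ones((3, 3)) - np.eye(3)
    return WeightedNetwork(adjacency=adj)


@pytest.fixture
def path3():
    adj = np.zeros((3, 3))
    adj[0, 1] = adj[1, 0] = 1.0
    adj[1, 2] = adj[2, 1] = 1.0
    return WeightedNetwork(adjacency=adj)


def random_network(n: int, seed: int, weighted: bool = True, density: float = 0.5) -> WeightedNetwork:
    rng = np.random.default_rng(seed)
    adj = rng.random((n, n)) * (rng.random((n, n)) < density)
    adj = np.triu(adj, 1)
    if not weighted:
        adj = (adj > 0).astype(float)
    # guarantee connectivity via a random spanning path
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        i, j = min(a, b), max(a, b)
        if adj[i, j] == 0:
            adj[i, j] = rng.random() if weighted else 1.0
    return WeightedNetwork(adjacency=adj + adj.T)


@pytest.fixture
def small_hmsw():
    """32-node hierarchical modular network, dense enough to be feasible."""
    params = HMSWParams(n=32, levels=5, target_density=0.25)
    return generate_network("hmsw", params, seed=0)
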