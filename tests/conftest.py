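import numpy as np
import pytest

from mitoarm.io import MitoNetwork, NetworkDataset


@pytest.fixture
def three_arm_star() -> MitoNetwork:
    """3-way junction with three 2 um arms: the hand-computed metrics case."""
    return MitoNetwork(
        cell_id="star3", condition="test", n_nodes=4,
        edges=[(0, 1, 2.0), (0, 2, 2.0), (0, 3, 2.0)],
    )


@pytest.fixture
def four_arm_star() -> MitoNetwork:
    return MitoNetwork(
        cell_id="star4", condition="test", n_nodes=5,
        edges=[(0, i, 2.0) for i in range(1, 5)],
    )


def make_network(edges, cell_id="cell", condition="cond", n_nodes=None):
    if n_nodes is None:
        n_nodes = 1 + max((max(u, v) for u, v, _ in edges), default=-1)
    return MitoNetwork(cell_id=cell_id, condition=condition,
                       n_nodes=n_nodes, edges=list(edges))


def make_dataset(*networks):
    return NetworkDataset(networks=list(networks))


def random_connected_network(rng: np.random.Generator, n_nodes: int,
                             cell_id="rand", extra_edges: int = 0):
    """Random tree (optionally plus extra edges) — always one component."""
    edges = []
    for v in range(1, n_nodes):
        u = int(rng.integers(0, v))
        edges.append((u, v, float(rng.lognormal(0.0, 0.6))))
    for _ in range(extra_edges):
        u, v = (int(x) for x in rng.integers(0, n_nodes, size=2))
        edges.append((u, v, float(rng.lognormal(0.0, 0.6))))
    return make_network(edges, cell_id=cell_id, n_nodes=n_nodes)
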