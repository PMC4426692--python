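import networkx as nx
import numpy as np
import pytest

from vesselflow import InteractionNetwork


@pytest.fixture
def path3() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star5() -> InteractionNetwork:
    return InteractionNetwork.from_edges(
        [("hub", leaf) for leaf in ("L1", "L2", "L3", "L4", "L5")]
    )


@pytest.fixture
def cycle5() -> InteractionNetwork:
    names = [f"C{i}" for i in range(5)]
    return InteractionNetwork.from_edges(
        [(names[i], names[(i + 1) % 5]) for i in range(5)]
    )


@pytest.fixture
def k4() -> InteractionNetwork:
    names = ["a", "b", "c", "d"]
    return InteractionNetwork.from_edges(
        [(u, v) for i, u in enumerate(names) for v in names[i + 1:]]
    )


def random_network(seed: int, n: int, p: float = 0.3) -> InteractionNetwork:
    """Seeded Erdős–Rényi network with string node labels (may be
    disconnected; isolated nodes kept)."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    relabel = {i: f"N{i:03d}" for i in g.nodes}
    return InteractionNetwork(nx.relabel_nodes(g, relabel))


@pytest.fixture
def random_net_factory():
    return random_network


def adjacency_matrix(net: InteractionNetwork) -> tuple[np.ndarray, list[str]]:
    """Dense adjacency in sorted-node order (for oracle comparisons)."""
    nodes = net.sorted_nodes()
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in net.graph.edges():
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    return a, nodes
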