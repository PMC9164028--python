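import networkx as nx
import numpy as np
import pytest

from coexnet import CoexpressionNetwork, ExpressionMatrix


@pytest.fixture
def toy_matrix():
    """3 genes x 5 samples: g1 ~ g2 perfectly, g3 unrelated."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4", "s5"],
        [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [3, 1, 4, 1, 5]],
    )


@pytest.fixture
def two_triangles():
    """Two disjoint triangles: a1-a2-a3 and b1-b2-b3."""
    net = CoexpressionNetwork()
    for a, b in [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                 ("b1", "b2"), ("b2", "b3"), ("b1", "b3")]:
        net.add_edge(a, b, 0.9)
    return net


def random_network(n_nodes: int, p: float, seed: int) -> CoexpressionNetwork:
    """Erdos-Renyi graph as a CoexpressionNetwork (weight 0.5 everywhere)."""
    g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    net = CoexpressionNetwork()
    for u, v in g.edges():
        net.add_edge(f"n{u:02d}", f"n{v:02d}", 0.5)
    return net


def random_connected_network(n_nodes: int, seed: int) -> CoexpressionNetwork:
    """Connected random graph (spanning tree + extra random edges)."""
    rng = np.random.default_rng(seed)
    net = CoexpressionNetwork()
    order = rng.permutation(n_nodes)
    for i in range(1, n_nodes):
        u = order[i]
        v = order[rng.integers(0, i)]
        net.add_edge(f"n{u:02d}", f"n{v:02d}", 0.5)
    for _ in range(n_nodes):
        u, v = rng.integers(0, n_nodes, size=2)
        if u != v:
            net.add_edge(f"n{u:02d}", f"n{v:02d}", 0.5)
    return net
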