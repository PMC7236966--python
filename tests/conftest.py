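import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from netcompare import Network, load_collection


def net_from_edges(label, edges, extra_nodes=()):
    """Build a Network from (u, v) or (u, v, w) tuples."""
    net = Network(label=label)
    for e in edges:
        net.add_edge(e[0], e[1], e[2] if len(e) > 2 else None)
    net.nodes.update(extra_nodes)
    return net


@pytest.fixture
def make_network():
    return net_from_edges


@pytest.fixture
def pair_collection():
    """Two small overlapping networks used across set/similarity tests:
    N1 = {AB, BC}, N2 = {BC, CD}."""
    n1 = net_from_edges("net1", [("A", "B"), ("B", "C")])
    n2 = net_from_edges("net2", [("B", "C"), ("C", "D")])
    return load_collection([n1, n2])


@pytest.fixture
def random_collection_factory():
    """Random collections of networks over a shared node namespace."""

    def factory(n_networks, n_nodes, n_edges, seed):
        nets = []
        for i in range(n_networks):
            g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed + i)
            g = nx.relabel_nodes(g, {j: f"v{j}" for j in g.nodes})
            nets.append(Network.from_networkx(g, label=f"net{i + 1}"))
        return load_collection(nets)

    return factory


@pytest.fixture
def two_cliques_bridge():
    """Two K4s joined by one bridge edge: a planted two-community graph."""
    edges = []
    a = ["a1", "a2", "a3", "a4"]
    b = ["b1", "b2", "b3", "b4"]
    for grp in (a, b):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((grp[i], grp[j]))
    edges.append(("a1", "b1"))
    return net_from_edges("bridge", edges), frozenset(a), frozenset(b)
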