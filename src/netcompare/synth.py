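"""Synthetic network generation for benchmarks and fixtures.

Three generators, all fully reproducible from an explicit seed:

* ``generate_random`` — uniform G(n, m) simple graphs, the benchmark
  design used for runtime evaluation: node counts from 500 to 5000 and
  edge counts 2n–5n (1000 up to 25,000 edges), with replicates sharing
  (n, m) but differing in wiring.
* ``generate_family`` — a base G(n, m) network plus derived networks
  that retain a chosen fraction of the base edges and rewire the rest,
  emulating network rewiring between biological conditions; the
  measured edge-Jaccard to the base rises monotonically with the
  requested overlap.
* ``generate_planted_partition`` — two-block planted-partition graphs
  with known community labels for recovery tests.

Node labels are "N000001", "N000002", … so lexicographic order equals
generation order and downstream tie-breaks are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import networkx as nx
import numpy as np

from .edgelist_io import Network, NetworkCollection, canonical_edge, load_collection

Structure = Literal["random", "planted_partition", "overlapping_family"]


def _node_label(i: int) -> str:
    return f"N{i + 1:06d}"


def _relabel(g: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(g, {i: _node_label(i) for i in g.nodes}, copy=True)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic-network request."""

    n: int
    m: int
    replicates: int = 1
    seed: int = 0
    structure: Structure = "random"

    def __post_init__(self) -> None:
        cap = self.n * (self.n - 1) // 2
        if self.m > cap:
            raise ValueError(
                f"m={self.m} exceeds the simple-graph capacity {cap} for n={self.n}"
            )
        if self.n < 1 or self.m < 0 or self.replicates < 1:
            raise ValueError("n >= 1, m >= 0, replicates >= 1 required")


def generate_random(spec: SynthSpec) -> list[Network]:
    """Uniform G(n, m) graphs: exactly n labeled nodes, m distinct edges.

    Replicates use seeds seed, seed+1, … so they share (n, m) but differ
    in wiring; the same spec always regenerates identical edge sets.
    """
    nets = []
    for r in range(spec.replicates):
        g = nx.gnm_random_graph(spec.n, spec.m, seed=spec.seed + r)
        nets.append(
            Network.from_networkx(_relabel(g), label=f"random_n{spec.n}_m{spec.m}_r{r + 1}")
        )
    return nets


def generate_family(
    spec: SynthSpec,
    overlap: float,
    networks: int = 3,
    labels: Optional[list[str]] = None,
) -> NetworkCollection:
    """A base G(n, m) network and derived rewired variants.

    Each derived network keeps round(overlap x m) randomly chosen base
    edges and replaces the remainder with edges absent from the base, so
    overlap = 1 reproduces the base everywhere and overlap = 0 shares no
    edge with it.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be within [0, 1]")
    if not 2 <= networks <= 8:
        raise ValueError("family size must be between 2 and 8 networks")
    rng = np.random.default_rng(spec.seed)
    base_g = _relabel(nx.gnm_random_graph(spec.n, spec.m, seed=spec.seed))
    node_names = [_node_label(i) for i in range(spec.n)]
    base_edges = sorted(canonical_edge(u, v) for u, v in base_g.edges)
    if labels is None:
        labels = [f"net{i + 1}" for i in range(networks)]
    if len(labels) != networks:
        raise ValueError("number of labels must match number of networks")
    nets = [Network.from_networkx(base_g, label=labels[0])]
    n_keep = round(overlap * len(base_edges))
    base_set = set(base_edges)
    for i in range(1, networks):
        keep_idx = rng.choice(len(base_edges), size=n_keep, replace=False)
        edges = {base_edges[j] for j in keep_idx}
        # rewire the remainder to edges outside the base network
        while len(edges) < spec.m:
            u, v = rng.choice(spec.n, size=2, replace=False)
            e = canonical_edge(node_names[u], node_names[v])
            if e not in base_set and e not in edges:
                edges.add(e)
        net = Network(label=labels[i])
        net.nodes.update(node_names)
        for u, v in sorted(edges):
            net.add_edge(u, v)
        nets.append(net)
    return load_collection(nets)


def generate_planted_partition(
    block_size: int = 20,
    blocks: int = 2,
    p_in: float = 0.9,
    p_out: float = 0.02,
    seed: int = 0,
    label: str = "planted",
) -> tuple[Network, list[frozenset[str]]]:
    """A planted-partition graph plus its ground-truth communities.

    Within-block edges appear with probability p_in, between-block with
    p_out. Returns the Network and the planted blocks as node sets.
    """
    g = nx.planted_partition_graph(blocks, block_size, p_in, p_out, seed=seed)
    g = _relabel(nx.Graph(g))
    net = Network.from_networkx(g, label=label)
    planted = [
        frozenset(_node_label(b * block_size + i) for i in range(block_size))
        for b in range(blocks)
    ]
    return net, planted
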