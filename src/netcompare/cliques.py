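"""Maximal-clique enumeration, k-filtering and cross-network tracking.

Maximal cliques are enumerated with the Bron–Kerbosch pivoting
algorithm; setting k keeps only maximal cliques of size ≥ k (k = 3 by
default — dyads are just edges). A clique found in one network can be
tracked in every other network of the collection: which members are
present there, which are absent, and how many of the clique's edges
survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .edgelist_io import Network, NetworkCollection, canonical_edge

DEFAULT_MIN_CLIQUE_SIZE = 3


@dataclass(frozen=True)
class CliqueQuery:
    """Filter for clique enumeration: minimum size and optional required
    members (a clique must contain ALL filter nodes to be reported)."""

    k: int = DEFAULT_MIN_CLIQUE_SIZE
    node_filter: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("minimum clique size k must be >= 2")


@dataclass
class CliqueRow:
    network_label: str
    clique_id: int  # 1-based, by (size desc, lexicographic members)
    members: tuple[str, ...]  # sorted lexicographically

    @property
    def size(self) -> int:
        return len(self.members)


def find_cliques(network: Network, query: CliqueQuery = CliqueQuery()) -> list[CliqueRow]:
    """Maximal cliques of size ≥ k in one network, each reported once.

    Output order is deterministic: descending size, then lexicographic
    member tuples. ``query.node_filter`` keeps only cliques containing
    every filter node.
    """
    g = network.to_networkx()
    cliques = [
        tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= query.k
    ]
    if query.node_filter:
        cliques = [c for c in cliques if query.node_filter <= set(c)]
    cliques.sort(key=lambda c: (-len(c), c))
    return [
        CliqueRow(network_label=network.label, clique_id=i, members=c)
        for i, c in enumerate(cliques, start=1)
    ]


@dataclass
class CliqueTracking:
    """One clique's fate in another network."""

    network_label: str
    present: tuple[str, ...]
    absent: tuple[str, ...]
    induced_edges: int

    def to_dict(self) -> dict:
        return {
            "network": self.network_label,
            "present": list(self.present),
            "absent": list(self.absent),
            "induced_edges": self.induced_edges,
        }


def track_clique(
    clique: Sequence[str],
    collection: NetworkCollection,
    selected: Optional[Sequence[str]] = None,
) -> dict[str, CliqueTracking]:
    """Partition a clique's members into present/absent in each selected
    network and count the clique edges induced there."""
    members = sorted(set(clique))
    nets = collection.subset(selected)
    out: dict[str, CliqueTracking] = {}
    for net in nets:
        present = tuple(m for m in members if m in net.nodes)
        absent = tuple(m for m in members if m not in net.nodes)
        edges = sum(
            1
            for i, u in enumerate(members)
            for v in members[i + 1:]
            if canonical_edge(u, v) in net.edges
        )
        out[net.label] = CliqueTracking(
            network_label=net.label, present=present, absent=absent, induced_edges=edges
        )
    return out


def clique_table_tsv(rows: Sequence[CliqueRow]) -> str:
    lines = ["network\tclique_id\tsize\tmembers"]
    for r in rows:
        lines.append(
            f"{r.network_label}\t{r.clique_id}\t{r.size}\t" + ",".join(r.members)
        )
    return "\n".join(lines) + "\n"


def tracking_json(trackings: dict[str, CliqueTracking]) -> str:
    return json.dumps([t.to_dict() for t in trackings.values()], indent=2)
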