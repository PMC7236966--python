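"""Cross-network shortest-path matrices with order numbering.

For one source/target pair, ALL co-optimal shortest paths are enumerated
in every selected network (multiple shortest paths routinely coexist)
and assembled into a path matrix. Each path carries order numbers —
source = 0, target = hop count — which drive the bottom-to-top path
layout. Intermediate nodes appearing on shortest paths in many networks
are the "preferred" nodes: likely load-bearing members of the system.

Unweighted hop-count paths are the default; a weighted mode uses edge
weights as Dijkstra costs (weights must be positive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .edgelist_io import Network, NetworkCollection

logger = logging.getLogger("netcompare")


@dataclass
class PathRecord:
    network_label: str
    nodes: list[str]  # ordered source..target
    length: float  # hop count, or weighted cost in weighted mode

    @property
    def order_numbers(self) -> dict[str, int]:
        """Position of each node along the path, source = 0."""
        return {n: i for i, n in enumerate(self.nodes)}


@dataclass
class PathMatrix:
    source: str
    target: str
    records: list[PathRecord]
    preferred_nodes: dict[str, int]  # intermediate node -> #networks using it

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "target": self.target,
                "records": [
                    {"network": r.network_label, "path": r.nodes, "length": r.length}
                    for r in self.records
                ],
                "preferred": [
                    {"node": n, "count": c}
                    for n, c in sorted(
                        self.preferred_nodes.items(), key=lambda kv: (-kv[1], kv[0])
                    )
                ],
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["network\tlength\tpath"]
        for r in self.records:
            lines.append(f"{r.network_label}\t{r.length:g}\t" + "->".join(r.nodes))
        return "\n".join(lines) + "\n"


def all_shortest_paths(
    network: Network, source: str, target: str, weighted: bool = False
) -> list[PathRecord]:
    """Every minimum-length path from source to target in one network.

    Paths are returned in lexicographic order of their node sequences.
    A disconnected pair yields an empty list (logged, not an error);
    unknown endpoints raise KeyError.
    """
    if source == target:
        raise ValueError("source and target must differ")
    missing = [n for n in (source, target) if n not in network.nodes]
    if missing:
        raise KeyError(
            f"{network.label}: unknown node(s) {missing}"
        )
    g = network.to_networkx()
    weight_key = "weight" if weighted else None
    if weighted:
        for u, v, data in g.edges(data=True):
            w = data.get("weight")
            if w is None or w <= 0:
                raise ValueError(
                    f"{network.label}: weighted mode requires positive weights on "
                    f"all edges; offending edge ({u}, {v}): {w!r}"
                )
    try:
        paths = [list(p) for p in nx.all_shortest_paths(g, source, target, weight=weight_key)]
    except nx.NetworkXNoPath:
        logger.info(
            "%s: no path between %r and %r (different components)",
            network.label, source, target,
        )
        return []
    paths.sort()
    if weighted:
        length = sum(
            g[u][v]["weight"] for u, v in zip(paths[0], paths[0][1:])
        )
    else:
        length = len(paths[0]) - 1
    return [PathRecord(network_label=network.label, nodes=p, length=length) for p in paths]


def path_matrix(
    collection: NetworkCollection,
    source: str,
    target: str,
    selected: Optional[Sequence[str]] = None,
    weighted: bool = False,
) -> PathMatrix:
    """All shortest paths for the pair across every selected network.

    Preferred-node counts tally, for each intermediate node, the number
    of selected networks in whose shortest paths it appears — once per
    network however many of that network's co-optimal paths contain it.
    Source and target are excluded (they trivially lie on every path).
    """
    nets = collection.subset(selected)
    have_pair = [
        n for n in nets if source in n.nodes and target in n.nodes
    ]
    if not have_pair:
        raise KeyError(
            f"pair ({source!r}, {target!r}) is absent from every selected network"
        )
    records: list[PathRecord] = []
    preferred: dict[str, int] = {}
    for net in nets:
        if source not in net.nodes or target not in net.nodes:
            continue
        recs = all_shortest_paths(net, source, target, weighted=weighted)
        records.extend(recs)
        seen_here = set()
        for r in recs:
            seen_here.update(r.nodes[1:-1])
        for node in seen_here:
            preferred[node] = preferred.get(node, 0) + 1
    return PathMatrix(
        source=source, target=target, records=records, preferred_nodes=preferred
    )
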