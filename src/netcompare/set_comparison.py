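"""Exact-combination set comparison of nodes or edges across networks.

The region map assigns every node (or edge) of the union to the exact
subset of networks that contain it — the exclusive regions that underlie
Venn diagrams and UpSet plots. Derived comparison graphs: the
intersection graph (edges common to all selected networks), per-network
exclusive graphs, and the annotated union graph whose membership sets
drive pie-chart node coloring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .edgelist_io import Network, NetworkCollection

ElementKind = Literal["node", "edge"]

#: Practical rendering limit for Venn diagrams; UpSet rows have no limit.
VENN_MAX_SETS = 5


def _elements(net: Network, kind: ElementKind) -> frozenset:
    if kind == "node":
        return frozenset(net.nodes)
    if kind == "edge":
        return net.edge_set
    raise ValueError(f"element_kind must be 'node' or 'edge', got {kind!r}")


@dataclass
class RegionMap:
    """Exclusive regions: label subset -> members in exactly that subset."""

    element_kind: ElementKind
    labels: list[str]  # selected labels, collection order
    regions: dict[frozenset[str], frozenset]

    def members(self, subset: Sequence[str]) -> frozenset:
        return self.regions.get(frozenset(subset), frozenset())

    def inclusive_members(self, subset: Sequence[str]) -> frozenset:
        """Elements shared by at least the given networks ("shared by at
        least this subset" view, derivable from the exclusive regions)."""
        want = frozenset(subset)
        out: set = set()
        for key, mem in self.regions.items():
            if want <= key:
                out |= mem
        return frozenset(out)

    @property
    def union_size(self) -> int:
        return sum(len(m) for m in self.regions.values())

    def to_json(self) -> str:
        recs = [
            {
                "subset": sorted(k),
                "count": len(v),
                "members": sorted(map(_fmt_member, v)),
            }
            for k, v in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
        ]
        return json.dumps({"element_kind": self.element_kind, "regions": recs}, indent=2)

    def to_tsv(self) -> str:
        lines = ["subset\tcount\tmembers"]
        for k, v in sorted(self.regions.items(), key=lambda kv: sorted(kv[0])):
            lines.append(
                "|".join(sorted(k)) + f"\t{len(v)}\t" + ",".join(sorted(map(_fmt_member, v)))
            )
        return "\n".join(lines) + "\n"


def _fmt_member(m) -> str:
    return "--".join(m) if isinstance(m, tuple) else str(m)


@dataclass
class AnnotatedUnionGraph:
    """Union of the selected networks with per-element membership sets."""

    labels: list[str]
    nodes: dict[str, frozenset[str]]  # node -> labels containing it
    edges: dict[tuple[str, str], frozenset[str]]  # canonical edge -> labels

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [
                    {"id": n, "networks": sorted(m)} for n, m in sorted(self.nodes.items())
                ],
                "edges": [
                    {"source": u, "target": v, "networks": sorted(m)}
                    for (u, v), m in sorted(self.edges.items())
                ],
            },
            indent=2,
        )


def compute_regions(
    collection: NetworkCollection,
    selected: Optional[Sequence[str]] = None,
    element_kind: ElementKind = "edge",
) -> RegionMap:
    """Partition the union's elements into exclusive regions.

    Every non-empty subset of the selected labels gets a region holding
    the elements present in exactly those networks; regions are pairwise
    disjoint and cover the union. Empty regions are retained so UpSet
    rows can show zero counts.
    """
    nets = collection.subset(selected)
    if len(nets) < 2:
        raise ValueError("select at least 2 networks for set comparison")
    labels = [n.label for n in nets]
    sets = {n.label: _elements(n, element_kind) for n in nets}
    membership: dict = {}
    for label, elems in sets.items():
        for e in elems:
            membership.setdefault(e, set()).add(label)
    regions: dict[frozenset[str], set] = {}
    # pre-seed every non-empty label subset so zero-count regions exist
    from itertools import combinations

    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions[frozenset(combo)] = set()
    for e, mem in membership.items():
        regions[frozenset(mem)].add(e)
    return RegionMap(
        element_kind=element_kind,
        labels=labels,
        regions={k: frozenset(v) for k, v in regions.items()},
    )


def upset_rows(
    regions: RegionMap,
    sort_by: Literal["combination_cardinality", "set_cardinality"] = "set_cardinality",
    include_empty: bool = False,
) -> list[tuple[tuple[str, ...], int, frozenset]]:
    """Deterministically ordered UpSet rows (subset, count, members).

    ``set_cardinality`` sorts by descending region size,
    ``combination_cardinality`` by descending subset size; ties break
    lexicographically on the sorted label subset.
    """
    rows = [
        (tuple(sorted(k)), len(v), v)
        for k, v in regions.regions.items()
        if include_empty or v
    ]
    if sort_by == "set_cardinality":
        rows.sort(key=lambda r: (-r[1], r[0]))
    elif sort_by == "combination_cardinality":
        rows.sort(key=lambda r: (-len(r[0]), r[0]))
    else:
        raise ValueError(
            "sort_by must be 'combination_cardinality' or 'set_cardinality'"
        )
    return rows


def intersection_graph(
    collection: NetworkCollection, selected: Optional[Sequence[str]] = None
) -> Network:
    """Edges common to ALL selected networks; nodes are their endpoints."""
    nets = collection.subset(selected)
    if len(nets) < 2:
        raise ValueError("select at least 2 networks")
    common = set(nets[0].edge_set)
    for net in nets[1:]:
        common &= net.edge_set
    out = Network(label="intersection(" + ",".join(n.label for n in nets) + ")")
    for u, v in sorted(common):
        out.add_edge(u, v)
    return out


def exclusive_graphs(
    collection: NetworkCollection, selected: Optional[Sequence[str]] = None
) -> dict[str, Network]:
    """Per selected network: the edges found in that network only."""
    nets = collection.subset(selected)
    if len(nets) < 2:
        raise ValueError("select at least 2 networks")
    out: dict[str, Network] = {}
    for net in nets:
        others: set = set()
        for other in nets:
            if other.label != net.label:
                others |= other.edge_set
        excl = net.edge_set - others
        g = Network(label=f"exclusive({net.label})", color=net.color)
        for u, v in sorted(excl):
            g.add_edge(u, v)
        out[net.label] = g
    return out


def union_graph(
    collection: NetworkCollection, selected: Optional[Sequence[str]] = None
) -> AnnotatedUnionGraph:
    """Union of the selected networks, every node and edge annotated with
    the set of networks containing it (the pie-node data)."""
    nets = collection.subset(selected)
    if len(nets) < 2:
        raise ValueError("select at least 2 networks")
    node_mem: dict[str, set[str]] = {}
    edge_mem: dict[tuple[str, str], set[str]] = {}
    for net in nets:
        for n in net.nodes:
            node_mem.setdefault(n, set()).add(net.label)
        for e in net.edge_set:
            edge_mem.setdefault(e, set()).add(net.label)
    return AnnotatedUnionGraph(
        labels=[n.label for n in nets],
        nodes={n: frozenset(m) for n, m in node_mem.items()},
        edges={e: frozenset(m) for e, m in edge_mem.items()},
    )
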