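"""Parsing delimited edge lists into validated networks.

Input files are plain-text edge lists, one interaction per line, with
configurable delimiter and 1-based source/target/weight column indices.
Networks are undirected: every edge is stored canonically with its
endpoints in lexicographic order, and duplicate edges collapse to one.
Node identifiers are case-sensitive string tokens (gene, taxon or
protein names) shared across all networks of a collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

logger = logging.getLogger("netcompare")

#: Default colors assigned to networks in collection order (colorblind-safe).
DEFAULT_PALETTE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
    "#66a61e", "#e6ab02", "#a6761d", "#666666",
)

#: Hard cap on the number of networks in one comparison.
MAX_NETWORKS = 8


class EdgeListParseError(ValueError):
    """A line of an edge list could not be parsed."""


class CollectionError(ValueError):
    """A set of networks cannot form a valid comparison collection."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the undirected edge key: endpoints in lexicographic order."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class ParseConfig:
    """Column layout of a delimited edge-list file.

    Column indices are 1-based, matching how users read their files.
    """

    delimiter: str = "\t"
    source_col: int = 1
    target_col: int = 2
    weight_col: Optional[int] = None
    has_header: bool = False
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")
        if self.source_col < 1 or self.target_col < 1:
            raise ValueError("column indices are 1-based and must be >= 1")
        if self.source_col == self.target_col:
            raise ValueError("source_col and target_col must differ")
        if self.weight_col is not None and self.weight_col in (
            self.source_col,
            self.target_col,
        ):
            raise ValueError("weight_col must differ from source/target columns")


@dataclass
class Network:
    """An undirected labeled graph over string node identifiers.

    ``edges`` maps canonical (u, v) pairs (u <= v lexicographically) to an
    optional weight; ``nodes`` may include isolated nodes not covered by any
    edge. Two networks compare equal on label, nodes and edges.
    """

    label: str
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], Optional[float]] = field(default_factory=dict)
    color: Optional[str] = None

    def add_edge(self, u: str, v: str, weight: Optional[float] = None) -> None:
        key = canonical_edge(u, v)
        self.nodes.update(key)
        self.edges[key] = weight

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.label == other.label
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def to_networkx(self) -> nx.Graph:
        """Materialize as a networkx Graph (weights under the 'weight' key)."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (u, v), w in self.edges.items():
            if w is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, label: str, color: Optional[str] = None) -> "Network":
        net = cls(label=label, color=color)
        net.nodes.update(str(n) for n in g.nodes)
        for u, v, data in g.edges(data=True):
            if u == v:
                continue
            net.add_edge(str(u), str(v), data.get("weight"))
        return net


@dataclass
class NetworkCollection:
    """An ordered set of 2–8 networks sharing a node namespace.

    The unit of every comparison operation. Labels are unique; iteration
    order is the input order, which fixes matrix row order, default colors
    and output ordering everywhere downstream.
    """

    networks: list[Network]
    max_networks: int = MAX_NETWORKS

    def __post_init__(self) -> None:
        if len(self.networks) < 2:
            raise CollectionError(
                f"at least 2 networks are required for comparison, got {len(self.networks)}"
            )
        if len(self.networks) > self.max_networks:
            raise CollectionError(
                f"at most {self.max_networks} networks are supported, got {len(self.networks)}"
            )
        labels = [n.label for n in self.networks]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise CollectionError(
                f"duplicate network labels {sorted(dupes)}; relabel inputs so labels are unique"
            )
        for i, net in enumerate(self.networks):
            if net.color is None:
                net.color = DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.networks]

    def __iter__(self) -> Iterator[Network]:
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    def __getitem__(self, label: str) -> Network:
        for net in self.networks:
            if net.label == label:
                return net
        raise KeyError(f"no network labeled {label!r}; known labels: {self.labels}")

    def subset(self, selected: Optional[Sequence[str]]) -> list[Network]:
        """Resolve a label selection (None = all) to networks, input order."""
        if selected is None:
            return list(self.networks)
        unknown = [l for l in selected if l not in self.labels]
        if unknown:
            raise KeyError(f"unknown network labels {unknown}; known labels: {self.labels}")
        chosen = set(selected)
        return [n for n in self.networks if n.label in chosen]


def parse_edge_list(
    lines: Iterable[str], config: ParseConfig, label: str
) -> Network:
    """Parse text lines into a canonical, deduplicated Network.

    Blank lines and lines starting with ``#`` are skipped. Self-loops are
    dropped with a warning unless ``config.allow_self_loops``. On duplicate
    edges the last weight read wins (a warning is logged when it differs).

    Raises
    ------
    EdgeListParseError
        If a data line has too few fields (the message names the 1-based
        line number), or the file contains no edges at all.
    """
    needed = max(
        config.source_col,
        config.target_col,
        config.weight_col or 0,
    )
    net = Network(label=label)
    seen_data = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if config.has_header and not seen_data:
            seen_data = True  # first non-blank, non-comment line is the header
            continue
        seen_data = True
        fields = line.split(config.delimiter)
        if len(fields) < needed:
            raise EdgeListParseError(
                f"{label}: line {lineno} has {len(fields)} field(s), "
                f"need at least {needed} with delimiter {config.delimiter!r}"
            )
        u = fields[config.source_col - 1].strip()
        v = fields[config.target_col - 1].strip()
        if not u or not v:
            raise EdgeListParseError(
                f"{label}: line {lineno} has an empty node identifier"
            )
        if u == v and not config.allow_self_loops:
            logger.warning("%s: line %d: self-loop %r skipped", label, lineno, u)
            continue
        weight: Optional[float] = None
        if config.weight_col is not None:
            try:
                weight = float(fields[config.weight_col - 1])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{label}: line {lineno}: weight {fields[config.weight_col - 1]!r} "
                    f"is not a number"
                ) from exc
        key = canonical_edge(u, v)
        if key in net.edges and net.edges[key] != weight:
            logger.warning(
                "%s: line %d: duplicate edge %s with conflicting weight; last wins",
                label, lineno, key,
            )
        net.add_edge(u, v, weight)
    if not net.edges and not net.nodes:
        raise EdgeListParseError(f"{label}: no edges found (empty file?)")
    return net


def read_edge_list(path: str, config: ParseConfig, label: Optional[str] = None) -> Network:
    """Parse an edge-list file; the label defaults to the file stem."""
    import os

    if label is None:
        label = os.path.splitext(os.path.basename(path))[0]
    with open(path, "r", encoding="utf-8") as fh:
        return parse_edge_list(fh, config, label)


def write_edge_list(network: Network, path: str) -> None:
    """Write the canonical TSV edge list: source<TAB>target[<TAB>weight]."""
    with open(path, "w", encoding="utf-8") as fh:
        for (u, v) in sorted(network.edges):
            w = network.edges[(u, v)]
            if w is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:g}\n")


def load_collection(
    parsed: Sequence[Network], max_networks: int = MAX_NETWORKS
) -> NetworkCollection:
    """Assemble parsed networks into a NetworkCollection (order preserved)."""
    return NetworkCollection(list(parsed), max_networks=max_networks)
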