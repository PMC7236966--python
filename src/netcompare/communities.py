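"""Community detection, transition scoring and rank embeddings.

Communities are found by Clauset–Newman–Moore greedy modularity
maximization (agglomerate from singletons, always merging the pair with
the largest modularity gain, cut at maximum Q). Community transitions
between two networks are quantified by the Jaccard score and
intersection count of every cross-network community pair, summarized as

    sum_jaccard      = Σ pairwise Jaccard
    weighted_sum     = sum_jaccard / comparisons × 100

with comparisons = |A| × |B| cross pairs. A lower weighted score means
the communities redistributed more between the two networks. Rank
embeddings give each node's degree, HITS hub score and betweenness as
ranks normalized over the pooled observations of the network pair,
feeding the Sankey heatmap strips.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import networkx as nx
from scipy.stats import rankdata

from .edgelist_io import Network, NetworkCollection
from .graph_props import _compute_measure

logger = logging.getLogger("netcompare")


def _order_communities(comms: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    # descending size, ties by lexicographically smallest member
    return sorted(comms, key=lambda c: (-len(c), min(c)))


@dataclass
class Partition:
    """A network's communities: disjoint node sets covering all nodes,
    ordered by descending size (ties by smallest member)."""

    network_label: str
    communities: list[frozenset[str]]
    modularity: float

    def __len__(self) -> int:
        return len(self.communities)

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset().union(*self.communities) if self.communities else frozenset()

    def community_of(self, node: str) -> int:
        """1-based index of the community containing the node."""
        for i, c in enumerate(self.communities, start=1):
            if node in c:
                return i
        raise KeyError(f"{node!r} is not in partition of {self.network_label}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "network": self.network_label,
                "modularity": self.modularity,
                "communities": [sorted(c) for c in self.communities],
            },
            indent=2,
        )


def modularity_score(network: Network, communities: Sequence[frozenset[str]]) -> float:
    """Standard (unweighted) Newman modularity Q of a partition."""
    g = network.to_networkx()
    if g.number_of_edges() == 0:
        return 0.0
    return nx.community.modularity(g, communities, weight=None)


def detect_communities(network: Network) -> Partition:
    """CNM greedy modularity communities of one network.

    Deterministic and seedless: the agglomeration resolves equal
    modularity gains by community representative, so repeated runs on
    the same network give the same partition. Isolated nodes come out
    as singleton communities; an edgeless network yields all singletons
    with modularity 0 (warned).
    """
    g = network.to_networkx()
    if g.number_of_edges() == 0:
        logger.warning(
            "%s: network has no edges; every node is a singleton community",
            network.label,
        )
        comms = [frozenset([n]) for n in g.nodes]
        return Partition(network.label, _order_communities(comms), 0.0)
    raw = nx.community.greedy_modularity_communities(g, weight=None)
    comms = _order_communities([frozenset(c) for c in raw])
    q = modularity_score(network, comms)
    return Partition(network.label, comms, q)


@dataclass
class CommunityRow:
    network_label: str
    community_id: int  # 1-based within its network, by descending size
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CommunityTable:
    """Communities of several networks merged into one size-ordered table."""

    rows: list[CommunityRow]
    partitions: dict[str, Partition]

    def query(
        self, nodes: Sequence[str], mode: Literal["all", "any"] = "all"
    ) -> list[CommunityRow]:
        """Rows containing every queried node (all) or at least one (any)."""
        wanted = set(nodes)
        known = set().union(*(p.node_set for p in self.partitions.values()))
        unknown = sorted(wanted - known)
        if unknown:
            raise KeyError(f"unknown node(s) in query: {unknown}")
        if mode == "all":
            return [r for r in self.rows if wanted <= r.members]
        if mode == "any":
            return [r for r in self.rows if wanted & r.members]
        raise ValueError("mode must be 'all' or 'any'")

    def to_tsv(self) -> str:
        lines = ["network\tcommunity_id\tsize\tmembers"]
        for r in self.rows:
            lines.append(
                f"{r.network_label}\t{r.community_id}\t{r.size}\t"
                + ",".join(sorted(r.members))
            )
        return "\n".join(lines) + "\n"


def community_table(
    collection: NetworkCollection, selected: Optional[Sequence[str]] = None
) -> CommunityTable:
    """Detect communities in every selected network and merge them into
    one table sorted by descending size (parent network retained)."""
    nets = collection.subset(selected)
    partitions = {n.label: detect_communities(n) for n in nets}
    rows = [
        CommunityRow(label, i, c)
        for label, part in partitions.items()
        for i, c in enumerate(part.communities, start=1)
    ]
    rows.sort(key=lambda r: (-r.size, min(r.members), r.network_label))
    return CommunityTable(rows=rows, partitions=partitions)


@dataclass
class TransitionReport:
    """Pairwise community similarity between two partitions."""

    label_a: str
    label_b: str
    pair_scores: dict[tuple[int, int], dict[str, float]]  # 1-based (i, j)
    sum_jaccard: float
    comparisons: int  # |A| x |B| cross pairs
    nonzero_comparisons: int  # cross pairs with a non-empty intersection
    flows: list[dict] = field(default_factory=list)  # Sankey node flows

    @property
    def weighted_sum_jaccard(self) -> float:
        return self.sum_jaccard / self.comparisons * 100.0

    @property
    def weighted_sum_jaccard_nonzero(self) -> float:
        """Variant dividing only by the overlapping pair count."""
        if self.nonzero_comparisons == 0:
            return 0.0
        return self.sum_jaccard / self.nonzero_comparisons * 100.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "networks": [self.label_a, self.label_b],
                "pair_scores": [
                    {
                        "community_a": i,
                        "community_b": j,
                        "intersection_count": int(s["intersection_count"]),
                        "jaccard": s["jaccard"],
                    }
                    for (i, j), s in sorted(self.pair_scores.items())
                ],
                "sum_jaccard": self.sum_jaccard,
                "comparisons": self.comparisons,
                "weighted_sum_jaccard": self.weighted_sum_jaccard,
                "weighted_sum_jaccard_nonzero": self.weighted_sum_jaccard_nonzero,
                "flows": self.flows,
            },
            indent=2,
        )


def community_transitions(part_a: Partition, part_b: Partition) -> TransitionReport:
    """Score the redistribution of community members between two networks.

    Every cross pair of communities gets a Jaccard score and an
    intersection count; nodes absent from the other network count
    against the union (they are genuine departures). Identical
    partitions give each community a perfect match; fully disjoint node
    sets score 0 everywhere.
    """
    if not part_a.communities or not part_b.communities:
        raise ValueError("both partitions must contain at least one community")
    pair_scores: dict[tuple[int, int], dict[str, float]] = {}
    total = 0.0
    nonzero = 0
    for i, ca in enumerate(part_a.communities, start=1):
        for j, cb in enumerate(part_b.communities, start=1):
            inter = len(ca & cb)
            jac = inter / len(ca | cb)
            pair_scores[(i, j)] = {"intersection_count": inter, "jaccard": jac}
            total += jac
            if inter:
                nonzero += 1
    flows = [
        {"node": n, "from_community": part_a.community_of(n), "to_community": part_b.community_of(n)}
        for n in sorted(part_a.node_set & part_b.node_set)
    ]
    return TransitionReport(
        label_a=part_a.network_label,
        label_b=part_b.network_label,
        pair_scores=pair_scores,
        sum_jaccard=total,
        comparisons=len(part_a) * len(part_b),
        nonzero_comparisons=nonzero,
        flows=flows,
    )


EMBEDDING_MEASURES = ("degree", "hub", "betweenness")


def rank_embedding(
    net_a: Network, net_b: Network
) -> dict[str, dict[tuple[str, str], float]]:
    """Rank-normalized degree / hub / betweenness across a network pair.

    For each measure, the per-node values of both networks are pooled
    into one list of (network, node) observations, ranked ascending with
    average ranks on ties, and divided by the pooled observation count —
    so the unique pooled maximum maps to 1.0. Returned as
    measure -> {(network label, node) -> value in (0, 1]}.
    """
    out: dict[str, dict[tuple[str, str], float]] = {}
    graphs = {net_a.label: net_a.to_networkx(), net_b.label: net_b.to_networkx()}
    for measure in EMBEDDING_MEASURES:
        obs: list[tuple[tuple[str, str], float]] = []
        for label, g in graphs.items():
            vals = _compute_measure(g, measure, normalized_betweenness=False)
            obs.extend(((label, str(n)), float(v)) for n, v in vals.items())
        ranks = rankdata([v for _, v in obs], method="average")
        n = len(obs)
        out[measure] = {key: float(r) / n for (key, _), r in zip(obs, ranks)}
    return out
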