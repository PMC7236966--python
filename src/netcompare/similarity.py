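"""Edge-Jaccard similarity of networks, dendrogram, and union distances.

Pairwise similarity between two networks is the Jaccard index of their
edge sets, s = |E_i ∩ E_j| / |E_i ∪ E_j|. Networks are hierarchically
clustered on the distance d = 1 − s by average-linkage (UPGMA)
agglomeration with lexicographic tie-breaking, yielding the selection
dendrogram. Per-network node/edge Jaccard distances from the global
union network provide the radar-chart data: a network identical to the
union sits at distance 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .edgelist_io import Network, NetworkCollection


def jaccard(a: frozenset, b: frozenset) -> float:
    """Jaccard index of two sets; two empty sets count as identical (1)."""
    if not a and not b:
        return 1.0
    inter = len(a & b)
    union = len(a | b)
    return inter / union


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, [0,1], diagonal 1

    def similarity(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def distance(self, a: str, b: str) -> float:
        return 1.0 - self.similarity(a, b)

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for i, l in enumerate(self.labels):
            lines.append(l + "\t" + "\t".join(f"{v:.6f}" for v in self.values[i]))
        return "\n".join(lines) + "\n"


@dataclass
class DendrogramNode:
    """A node of the binary merge tree; leaves carry a label, internal
    nodes carry the merge height on the d = 1 − s scale."""

    height: float
    label: Optional[str] = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()

    def newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""

        def rec(node: "DendrogramNode", parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.6f}"
            inner = ",".join(rec(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6f}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(rec(c, self.height) for c in self.children)
        return f"({inner});"

    def merge_heights(self) -> list[float]:
        if self.is_leaf:
            return []
        return sorted(
            [self.height]
            + self.children[0].merge_heights()
            + self.children[1].merge_heights()
        )


def edge_jaccard_matrix(collection: NetworkCollection) -> SimilarityMatrix:
    """All-versus-all edge-Jaccard similarity of the collection."""
    labels = collection.labels
    sets = [net.edge_set for net in collection]
    k = len(labels)
    m = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = jaccard(sets[i], sets[j])
    return SimilarityMatrix(labels=labels, values=m)


def node_jaccard_matrix(collection: NetworkCollection) -> SimilarityMatrix:
    """All-versus-all node-Jaccard similarity of the collection."""
    labels = collection.labels
    sets = [frozenset(net.nodes) for net in collection]
    k = len(labels)
    m = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = jaccard(sets[i], sets[j])
    return SimilarityMatrix(labels=labels, values=m)


def cluster_networks(matrix: SimilarityMatrix) -> DendrogramNode:
    """Average-linkage (UPGMA) agglomeration on d = 1 − s.

    At every step the cluster pair with the smallest average pairwise
    leaf distance merges; equal distances break ties by the
    lexicographically smallest pair of cluster representatives (the
    smallest leaf label in each cluster), making runs fully
    deterministic. The merge height recorded for a join is the average
    distance itself, so a two-network dendrogram has height 1 − s.
    """
    labels = matrix.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 networks to cluster")
    dist = {
        (a, b): 1.0 - matrix.similarity(a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }

    def leaf_dist(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    clusters: dict[str, tuple[DendrogramNode, list[str]]] = {
        l: (DendrogramNode(height=0.0, label=l), [l]) for l in labels
    }
    while len(clusters) > 1:
        reps = sorted(clusters)
        best: tuple[float, str, str] | None = None
        for i, ra in enumerate(reps):
            for rb in reps[i + 1:]:
                la, lb = clusters[ra][1], clusters[rb][1]
                d = sum(leaf_dist(x, y) for x in la for y in lb) / (len(la) * len(lb))
                # strict < keeps the lexicographically first pair on ties
                if best is None or d < best[0] - 1e-15:
                    best = (d, ra, rb)
        d, ra, rb = best  # type: ignore[misc]
        na, la = clusters.pop(ra)
        nb, lb = clusters.pop(rb)
        merged = DendrogramNode(height=d, children=(na, nb))
        clusters[min(ra, rb)] = (merged, la + lb)
    (root, _), = clusters.values()
    return root


@dataclass
class RadarDistances:
    """Per-network Jaccard distances from the global union network."""

    node_distance: dict[str, float]
    edge_distance: dict[str, float]

    def to_json(self) -> str:
        recs = [
            {
                "label": l,
                "node_distance": self.node_distance[l],
                "edge_distance": self.edge_distance[l],
            }
            for l in self.node_distance
        ]
        return json.dumps(recs, indent=2)


def union_distances(
    collection: NetworkCollection, selected: Optional[Sequence[str]] = None
) -> RadarDistances:
    """Distance of each selected network from the global union.

    Since every network is a subset of the union, the Jaccard index
    reduces to |X_k| / |X_union| and the distance to 1 minus that ratio,
    for nodes and edges alike.
    """
    nets = collection.subset(selected)
    if len(nets) < 2:
        raise ValueError("select at least 2 networks")
    union_nodes: frozenset = frozenset().union(*(frozenset(n.nodes) for n in nets))
    union_edges: frozenset = frozenset().union(*(n.edge_set for n in nets))
    nd = {n.label: 1.0 - jaccard(frozenset(n.nodes), union_nodes) for n in nets}
    ed = {n.label: 1.0 - jaccard(n.edge_set, union_edges) for n in nets}
    return RadarDistances(node_distance=nd, edge_distance=ed)
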