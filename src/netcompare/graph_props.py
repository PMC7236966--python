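"""Global network properties and per-node centrality measures.

The four global preview statistics are total nodes, total edges, cluster
coefficient (average local clustering; nodes of degree < 2 contribute 0)
and density 2E / (N(N-1)). Local measures cover degree, betweenness
(raw pair-count convention by default), HITS hub/authority, eccentricity
(per connected component), eigenvector centrality, closeness and
coreness. Cross-network "delta centrality" tables place one node per row
and one network per column, recording an explicit ABSENT marker — not
zero — where a node does not exist in a network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .edgelist_io import Network, NetworkCollection

#: Marker distinguishing "node not in this network" from a zero value.
ABSENT = None

MEASURES = (
    "degree",
    "betweenness",
    "hub",
    "authority",
    "eccentricity",
    "eigenvector",
    "closeness",
    "coreness",
)

_HITS_TOL = 1e-8
_HITS_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration budget."""


@dataclass(frozen=True)
class GlobalProperties:
    total_nodes: int
    total_edges: int
    cluster_coefficient: float
    density: float

    def as_dict(self) -> dict[str, float]:
        return {
            "total_nodes": self.total_nodes,
            "total_edges": self.total_edges,
            "cluster_coefficient": self.cluster_coefficient,
            "density": self.density,
        }


@dataclass
class CentralityTable:
    """Values of one measure for (network label, node) pairs.

    ``values[label][node]`` is a float, or ABSENT when the node does not
    occur in that network. ``row_order`` fixes the node ordering used by
    TSV/JSON export (descending by the first network's values for delta
    tables, lexicographic otherwise).
    """

    measure: str
    labels: list[str]
    values: dict[str, dict[str, Optional[float]]]
    row_order: list[str]

    def get(self, label: str, node: str) -> Optional[float]:
        return self.values[label].get(node, ABSENT)

    def to_rows(self) -> list[tuple[str, list[Optional[float]]]]:
        return [
            (node, [self.values[l].get(node, ABSENT) for l in self.labels])
            for node in self.row_order
        ]

    def to_tsv(self) -> str:
        lines = ["node\t" + "\t".join(self.labels)]
        for node, vals in self.to_rows():
            cells = ["NA" if v is ABSENT else f"{v:.10g}" for v in vals]
            lines.append(node + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def global_properties(network: Network) -> GlobalProperties:
    """The four global preview statistics of one network."""
    g = network.to_networkx()
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return GlobalProperties(0, 0, 0.0, 0.0)
    # average_clustering counts degree<2 nodes as 0, matching the preview
    cc = nx.average_clustering(g) if n > 0 else 0.0
    dens = nx.density(g) if n >= 2 else 0.0
    return GlobalProperties(n, e, cc, dens)


def transitivity(network: Network) -> float:
    """Global transitivity (3 x triangles / triads), exposed separately
    from the average-local-clustering preview statistic."""
    return nx.transitivity(network.to_networkx())


def _unit_max(values: dict[str, float]) -> dict[str, float]:
    m = max(values.values(), default=0.0)
    if m <= 0:
        return {k: 0.0 for k in values}
    return {k: v / m for k, v in values.items()}


def _eccentricity_per_component(g: nx.Graph) -> dict[str, float]:
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        out.update(nx.eccentricity(g.subgraph(comp)))
    return out


def _hits_power_iteration(g: nx.Graph) -> tuple[dict, dict]:
    """HITS scores by deterministic power iteration (uniform start, L1
    renormalization, convergence at n*tol). On an undirected graph the
    hub and authority equations share the nonnegative Perron vector of
    the adjacency matrix as their fixed point, so iteration runs on A
    directly and hub = authority exactly; the alternating two-step
    update would oscillate between the sides of bipartite components,
    and eigensolver backends can flip signs per component. The shifted
    operator A + I (same Perron vector, strictly dominant eigenvalue)
    keeps the iteration from oscillating on bipartite spectra."""
    import numpy as np

    nodes = list(g)
    a = nx.adjacency_matrix(g, nodelist=nodes, dtype=float)
    n = len(nodes)
    x = np.full(n, 1.0 / n)
    for _ in range(_HITS_MAX_ITER):
        last = x
        x = a @ x + x
        s = x.sum()
        if s > 0:
            x = x / s
        if np.abs(x - last).sum() < n * _HITS_TOL:
            scores = {str(v): float(val) for v, val in zip(nodes, x)}
            return scores, dict(scores)
    raise ConvergenceError(
        f"HITS failed to converge to tol={_HITS_TOL} in {_HITS_MAX_ITER} iterations"
    )


def _compute_measure(g: nx.Graph, measure: str, normalized_betweenness: bool) -> dict[str, float]:
    if measure == "degree":
        return dict(g.degree())
    if measure == "betweenness":
        return nx.betweenness_centrality(g, normalized=normalized_betweenness)
    if measure in ("hub", "authority"):
        if g.number_of_edges() == 0:
            raise ValueError("HITS requires a graph with at least one edge")
        hubs, auths = _hits_power_iteration(g)
        return _unit_max(hubs if measure == "hub" else auths)
    if measure == "eccentricity":
        return _eccentricity_per_component(g)
    if measure == "eigenvector":
        if g.number_of_edges() == 0:
            raise ValueError("eigenvector centrality requires at least one edge")
        try:
            ev = nx.eigenvector_centrality(g, max_iter=_HITS_MAX_ITER, tol=_HITS_TOL)
        except nx.PowerIterationFailedConvergence as exc:
            raise ConvergenceError(
                f"eigenvector power iteration failed to converge to tol={_HITS_TOL} "
                f"in {_HITS_MAX_ITER} iterations"
            ) from exc
        return _unit_max(ev)
    if measure == "closeness":
        return nx.closeness_centrality(g)
    if measure == "coreness":
        return {n: float(k) for n, k in nx.core_number(g).items()}
    raise ValueError(f"unknown measure {measure!r}; supported: {MEASURES}")


def node_centralities(
    network: Network,
    measures: Sequence[str] = MEASURES,
    normalized_betweenness: bool = False,
) -> list[CentralityTable]:
    """One CentralityTable per requested measure, for a single network.

    Betweenness uses raw (unnormalized) pair counts unless
    ``normalized_betweenness``; HITS hub and authority scores coincide on
    undirected graphs and both are reported, normalized to unit maximum,
    as is eigenvector centrality. Eccentricity is computed within each
    node's connected component.
    """
    g = network.to_networkx()
    tables = []
    for measure in measures:
        vals = {str(k): float(v) for k, v in _compute_measure(g, measure, normalized_betweenness).items()}
        tables.append(
            CentralityTable(
                measure=measure,
                labels=[network.label],
                values={network.label: vals},
                row_order=sorted(vals),
            )
        )
    return tables


def delta_centrality(
    collection: NetworkCollection,
    measure: str,
    nodes: Optional[Sequence[str]] = None,
    top: Optional[int] = None,
    normalized_betweenness: bool = False,
) -> CentralityTable:
    """One measure traced across all networks of the collection.

    Rows are ordered by descending value in the first network (ABSENT
    sorts last; ties break lexicographically); ``nodes`` restricts to the
    given identifiers and ``top`` keeps only the leading rows, which
    together express queries like "top-10 degree nodes of network 1
    traced across all networks".

    Raises
    ------
    KeyError
        If any requested node occurs in no network of the collection.
    """
    labels = collection.labels
    values: dict[str, dict[str, Optional[float]]] = {}
    for net in collection:
        g = net.to_networkx()
        values[net.label] = {
            str(k): float(v)
            for k, v in _compute_measure(g, measure, normalized_betweenness).items()
        }
    all_nodes = set().union(*(set(v) for v in values.values()))
    if nodes is not None:
        unknown = sorted(set(nodes) - all_nodes)
        if unknown:
            raise KeyError(f"nodes present in no network: {unknown}")
        chosen = [n for n in dict.fromkeys(nodes)]
    else:
        chosen = sorted(all_nodes)
    first = values[labels[0]]
    chosen.sort(key=lambda n: (-(first[n]) if n in first else float("inf"), n))
    if top is not None:
        chosen = chosen[:top]
    return CentralityTable(measure=measure, labels=labels, values=values, row_order=chosen)


def all_measures_table(network: Network, measures: Sequence[str] = MEASURES) -> str:
    """TSV with one row per node and one column per measure (the
    all-measures-one-network table layout)."""
    tables = node_centralities(network, measures)
    nodes = sorted(network.nodes)
    lines = ["node\t" + "\t".join(t.measure for t in tables)]
    for node in nodes:
        cells = []
        for t in tables:
            v = t.get(network.label, node)
            cells.append("NA" if v is ABSENT else f"{v:.10g}")
        lines.append(node + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
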