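"""Independent brute-force oracles used to validate the implementation.

Everything here works by exhaustive enumeration on small graphs and is
deliberately written without reference to the library code paths it
checks (and without the networkx routines those paths delegate to).
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx


def brute_maximal_cliques(g: nx.Graph) -> set[frozenset]:
    """All maximal cliques by subset enumeration (feasible to ~15 nodes)."""
    nodes = list(g.nodes)
    cliques = set()
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all(g.has_edge(u, v) for u, v in combinations(subset, 2)):
                cliques.add(frozenset(subset))
    return {
        c for c in cliques
        if not any(c < other for other in cliques)
    }


def brute_all_shortest_paths(g: nx.Graph, source, target) -> list[list]:
    """All minimum-hop paths via exhaustive simple-path enumeration."""
    paths = [list(p) for p in nx.all_simple_paths(g, source, target)]
    if source in g and target in g and g.has_edge(source, target):
        pass  # simple paths include the direct edge already
    if not paths:
        return []
    best = min(len(p) for p in paths)
    return sorted(p for p in paths if len(p) == best)


def brute_betweenness(g: nx.Graph) -> dict:
    """Unnormalized betweenness: for every unordered pair, the fraction
    of shortest paths through each intermediate node."""
    bet = {n: 0.0 for n in g.nodes}
    nodes = list(g.nodes)
    for s, t in combinations(nodes, 2):
        try:
            paths = brute_all_shortest_paths(g, s, t)
        except nx.NodeNotFound:
            continue
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bet[v] += 1.0 / len(paths)
    return bet


def direct_modularity(g: nx.Graph, communities) -> float:
    """Newman's Q evaluated straight from its definition:
    Q = sum_c [ L_c / m  -  (d_c / 2m)^2 ]."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for c in communities:
        cset = set(c)
        l_c = sum(1 for u, v in g.edges if u in cset and v in cset)
        d_c = sum(g.degree(n) for n in cset)
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q


def _set_partitions(items: list):
    """Generate all partitions of a list (Bell-number growth; <=10 items)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in _set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {first}] + partial[i + 1:]
        yield partial + [{first}]


def brute_max_modularity(g: nx.Graph) -> tuple[float, list[set]]:
    """Exhaustive maximum-modularity partition (feasible to ~10 nodes)."""
    best_q, best_p = float("-inf"), None
    for partition in _set_partitions(list(g.nodes)):
        q = direct_modularity(g, partition)
        if q > best_q:
            best_q, best_p = q, [set(c) for c in partition]
    return best_q, best_p
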