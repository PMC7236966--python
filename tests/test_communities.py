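import networkx as nx
import pytest

from netcompare import (
    Network,
    Partition,
    community_table,
    community_transitions,
    detect_communities,
    load_collection,
    modularity_score,
    rank_embedding,
)
from oracles import brute_max_modularity, direct_modularity


def make_partition(label, *communities):
    comms = sorted((frozenset(c) for c in communities), key=lambda c: (-len(c), min(c)))
    return Partition(network_label=label, communities=comms, modularity=0.0)


class TestDetectCommunities:
    def test_two_cliques_with_bridge_split_into_the_cliques(self, two_cliques_bridge):
        net, block_a, block_b = two_cliques_bridge
        part = detect_communities(net)
        assert set(part.communities) == {block_a, block_b}
        # matches the exhaustive maximum-modularity partition
        q_best, p_best = brute_max_modularity(net.to_networkx())
        assert {frozenset(c) for c in p_best} == set(part.communities)
        assert part.modularity == pytest.approx(q_best, abs=1e-12)

    def test_single_clique_stays_whole(self, make_network):
        k5 = make_network(
            "k5",
            [(f"v{i}", f"v{j}") for i in range(5) for j in range(i + 1, 5)],
        )
        part = detect_communities(k5)
        assert len(part) == 1
        assert part.communities[0] == frozenset(k5.nodes)

    def test_edgeless_graph_all_singletons(self):
        net = Network(label="iso", nodes={"a", "b", "c"})
        part = detect_communities(net)
        assert len(part) == 3
        assert part.modularity == 0.0

    def test_isolated_node_becomes_singleton(self, make_network):
        net = make_network("n", [("a", "b"), ("b", "c"), ("a", "c")],
                           extra_nodes=["lonely"])
        part = detect_communities(net)
        assert frozenset(["lonely"]) in part.communities

    def test_partition_is_disjoint_cover_on_random_graphs(self):
        for seed in range(8):
            g = nx.gnm_random_graph(25, 50, seed=seed)
            net = Network.from_networkx(g, "r")
            part = detect_communities(net)
            members = [n for c in part.communities for n in c]
            assert len(members) == len(set(members)) == net.n_nodes
            assert set(members) == net.nodes

    def test_reported_modularity_matches_direct_q_formula(self):
        for seed in range(8):
            g = nx.gnm_random_graph(20, 40, seed=seed)
            net = Network.from_networkx(g, "r")
            part = detect_communities(net)
            q = direct_modularity(net.to_networkx(), part.communities)
            assert part.modularity == pytest.approx(q, abs=1e-12)

    def test_cnm_q_never_exceeds_bruteforce_maximum(self):
        for seed in range(4):
            g = nx.gnm_random_graph(8, 12, seed=seed)
            if g.number_of_edges() == 0:
                continue
            net = Network.from_networkx(g, "r")
            part = detect_communities(net)
            q_best, _ = brute_max_modularity(net.to_networkx())
            assert part.modularity <= q_best + 1e-12

    def test_communities_ordered_by_descending_size(self):
        g = nx.gnm_random_graph(30, 45, seed=1)
        part = detect_communities(Network.from_networkx(g, "r"))
        sizes = [len(c) for c in part.communities]
        assert sizes == sorted(sizes, reverse=True)

    def test_detection_is_deterministic(self, two_cliques_bridge):
        net, _, _ = two_cliques_bridge
        assert detect_communities(net).communities == detect_communities(net).communities


class TestCommunityTable:
    def make_table(self, make_network):
        n1 = make_network("n1", [("a", "b"), ("b", "c"), ("a", "c"),
                                 ("d", "e"), ("e", "f"), ("d", "f")])
        n2 = make_network("n2", [("a", "b"), ("c", "d"), ("c", "e"), ("d", "e")])
        return community_table(load_collection([n1, n2]))

    def test_rows_strictly_size_ordered(self, make_network):
        table = self.make_table(make_network)
        sizes = [r.size for r in table.rows]
        assert sizes == sorted(sizes, reverse=True)

    def test_query_all_semantics(self, make_network):
        table = self.make_table(make_network)
        rows = table.query(["a", "b"], mode="all")
        assert all({"a", "b"} <= r.members for r in rows)
        assert len(rows) == 2  # the {a,b,c} triangle of n1 and {a,b} of n2

    def test_query_any_vs_all(self, make_network):
        table = self.make_table(make_network)
        assert table.query(["a", "d"], mode="all") == []
        hit_nets = {
            (r.network_label, r.members) for r in table.query(["a", "d"], mode="any")
        }
        assert len(hit_nets) == 4  # a's and d's communities in both networks

    def test_unknown_query_node_errors(self, make_network):
        table = self.make_table(make_network)
        with pytest.raises(KeyError, match="zzz"):
            table.query(["a", "zzz"])


class TestCommunityTransitions:
    def test_identical_partitions_worked_example(self):
        a = make_partition("A", {"a", "b", "c"}, {"d", "e", "f"})
        b = make_partition("B", {"a", "b", "c"}, {"d", "e", "f"})
        rep = community_transitions(a, b)
        assert rep.sum_jaccard == pytest.approx(2.0)
        assert rep.comparisons == 4
        assert rep.weighted_sum_jaccard == pytest.approx(50.0)

    def test_split_community_worked_example(self):
        a = make_partition("A", {"a", "b", "c"}, {"d", "e", "f"})
        b = make_partition("B", {"a", "b"}, {"c", "d", "e", "f"})
        rep = community_transitions(a, b)
        jaccards = sorted(s["jaccard"] for s in rep.pair_scores.values())
        assert jaccards == pytest.approx(sorted([2 / 3, 1 / 6, 0.0, 3 / 4]))
        assert rep.sum_jaccard == pytest.approx(2 / 3 + 1 / 6 + 3 / 4)  # ~1.5833
        assert rep.weighted_sum_jaccard == pytest.approx(39.5833, abs=1e-3)

    def test_disjoint_node_sets_score_zero(self):
        a = make_partition("A", {"a", "b"}, {"c"})
        b = make_partition("B", {"x", "y"}, {"z"})
        rep = community_transitions(a, b)
        assert rep.sum_jaccard == 0.0
        assert rep.weighted_sum_jaccard == 0.0

    def test_score_invariant_under_node_renaming(self):
        a = make_partition("A", {"a", "b", "c"}, {"d", "e"})
        b = make_partition("B", {"a", "b"}, {"c", "d", "e"})
        rename = {n: f"X{n}" for n in "abcde"}
        a2 = make_partition("A", *[{rename[n] for n in c} for c in a.communities])
        b2 = make_partition("B", *[{rename[n] for n in c} for c in b.communities])
        r1, r2 = community_transitions(a, b), community_transitions(a2, b2)
        assert r1.weighted_sum_jaccard == pytest.approx(r2.weighted_sum_jaccard)

    def test_refining_b_never_improves_best_match(self):
        a = make_partition("A", {"a", "b", "c", "d"})
        b_whole = make_partition("B", {"a", "b", "c", "d"})
        b_split = make_partition("B", {"a", "b"}, {"c", "d"})
        def best_match(rep):
            return max(s["jaccard"] for s in rep.pair_scores.values())
        assert best_match(community_transitions(a, b_split)) <= best_match(
            community_transitions(a, b_whole)
        )

    def test_intersection_counts_reported(self):
        a = make_partition("A", {"a", "b", "c"})
        b = make_partition("B", {"b", "c", "d"})
        rep = community_transitions(a, b)
        assert rep.pair_scores[(1, 1)]["intersection_count"] == 2

    def test_flow_records_cover_shared_nodes(self):
        a = make_partition("A", {"a", "b"}, {"c"})
        b = make_partition("B", {"a"}, {"b", "c"})
        rep = community_transitions(a, b)
        assert {f["node"] for f in rep.flows} == {"a", "b", "c"}


class TestRankEmbedding:
    def test_average_ranks_on_pooled_degrees(self, make_network):
        # pooled degrees {1,1,2,2,2} -> ranks {1.5,1.5,4,4,4}/5
        edge = make_network("E", [("P", "Q")])
        tri = make_network("T", [("R", "S"), ("S", "U"), ("R", "U")])
        emb = rank_embedding(edge, tri)["degree"]
        assert emb[("E", "P")] == pytest.approx(1.5 / 5)
        assert emb[("T", "R")] == pytest.approx(4 / 5)

    def test_full_tie_gives_identical_values(self, make_network):
        edge = make_network("E", [("P", "Q")])
        tri = make_network("T", [("R", "S"), ("S", "U"), ("R", "U")])
        bet = rank_embedding(edge, tri)["betweenness"]
        assert len(set(bet.values())) == 1  # all betweenness 0 -> one tied rank

    def test_unique_pooled_maximum_maps_to_one(self, make_network):
        star = make_network("S", [("c", f"l{i}") for i in range(4)])
        edge = make_network("E", [("x", "y")])
        emb = rank_embedding(star, edge)["degree"]
        assert emb[("S", "c")] == pytest.approx(1.0)

    def test_all_three_measures_present(self, make_network):
        a = make_network("A", [("x", "y")])
        b = make_network("B", [("y", "z")])
        emb = rank_embedding(a, b)
        assert set(emb) == {"degree", "hub", "betweenness"}
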