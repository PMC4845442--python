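import random

import pytest

from netcompare import (
    Network,
    NetworkCollection,
    community_distribution,
    community_subgraph,
    detect_communities,
    modularity,
    union_networks,
)

import _oracles as oracle
from conftest import random_network


class TestDetect:
    def test_two_triangles_split_at_bridge(self, two_triangles):
        part = detect_communities(two_triangles)
        assert sorted(map(sorted, part.communities)) == [
            ["a", "b", "c"], ["d", "e", "f"]
        ]
        # exhaustive enumeration confirms this is the global optimum
        best_q, _ = oracle.best_partition_exhaustive(two_triangles)
        assert part.modularity == pytest.approx(best_q)

    def test_single_triangle_one_community(self, triangle):
        part = detect_communities(triangle)
        assert len(part.communities) == 1
        assert part.communities[0] == frozenset("abc")

    def test_all_in_one_partition_has_zero_modularity(self, two_triangles):
        assert modularity(two_triangles, [frozenset(two_triangles.nodes)]) \
            == pytest.approx(0.0)

    def test_isolated_nodes_become_singletons(self):
        net = Network("mix", nodes={"x", "y"}, edges=[("a", "b"), ("b", "c"), ("a", "c")])
        part = detect_communities(net)
        assert frozenset({"x"}) in part.communities
        assert frozenset({"y"}) in part.communities

    def test_edgeless_network(self):
        part = detect_communities(Network("iso", nodes={"a", "b"}))
        assert part.modularity == 0.0
        assert len(part.communities) == 2

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(Network("empty"))

    def test_unknown_method_rejected(self, triangle):
        with pytest.raises(ValueError):
            detect_communities(triangle, method="louvain")

    def test_sizes_non_increasing_and_ids(self, two_triangles):
        part = detect_communities(two_triangles)
        sizes = [len(c) for c in part.communities]
        assert sizes == sorted(sizes, reverse=True)
        assert part.ids == [f"C{i+1}" for i in range(len(sizes))]

    def test_deterministic_across_runs(self):
        rng = random.Random(5)
        for i in range(10):
            net = random_network(rng, f"G{i}", max_nodes=10)
            p1 = detect_communities(net)
            p2 = detect_communities(net)
            assert p1.communities == p2.communities
            assert p1.modularity == p2.modularity

    def test_reported_modularity_matches_oracle_formula(self):
        rng = random.Random(6)
        for i in range(20):
            net = random_network(rng, f"G{i}", max_nodes=11)
            part = detect_communities(net)
            assert part.modularity == pytest.approx(
                oracle.modularity(net, part.communities)
            )

    def test_partition_covers_nodes_disjointly(self):
        rng = random.Random(8)
        for i in range(10):
            net = random_network(rng, f"G{i}")
            part = detect_communities(net)
            assert part.node_set() == net.nodes
            assert sum(len(c) for c in part.communities) == net.n_nodes

    def test_no_community_spans_components(self):
        net = Network(
            "2comp",
            edges=[("a", "b"), ("b", "c"), ("a", "c"),
                   ("x", "y"), ("y", "z"), ("x", "z")],
        )
        part = detect_communities(net)
        for comm in part.communities:
            assert comm <= frozenset("abc") or comm <= frozenset("xyz")


class TestDistribution:
    def test_worked_example(self, collection_ab):
        union, _ = union_networks(collection_ab)
        part = detect_communities(union)
        # the A,B union is a single path → communities partition abcde;
        # profile against a hand-built one-community partition:
        from netcompare.community import CommunityPartition

        single = CommunityPartition((frozenset("abcde"),), 0.0)
        profile = community_distribution(single, collection_ab)
        assert profile.loc["C1", "A:nodes"] == 4
        assert profile.loc["C1", "B:nodes"] == 4
        assert profile.loc["C1", "A:edges"] == 3
        assert profile.loc["C1", "B:edges"] == 3
        assert part.node_set() == union.nodes

    def test_disjoint_network_zero_cells(self, collection_ab, net_a, net_b):
        from netcompare.community import CommunityPartition

        other = Network("Z", edges=[("x", "y")])
        coll = NetworkCollection([net_a, net_b, other])
        part = CommunityPartition(
            (frozenset("abcde"), frozenset({"x", "y"})), 0.0
        )
        profile = community_distribution(part, coll)
        assert profile.loc["C2", "A:nodes"] == 0
        assert profile.loc["C2", "A:edges"] == 0

    def test_uncovered_union_rejected(self, collection_ab):
        from netcompare.community import CommunityPartition

        short = CommunityPartition((frozenset("abcd"),), 0.0)  # e missing
        with pytest.raises(ValueError, match="does not cover"):
            community_distribution(short, collection_ab)

    def test_node_count_conservation_over_disjoint_networks(self):
        from netcompare.community import CommunityPartition

        n1 = Network("N1", edges=[("a", "b")])
        n2 = Network("N2", edges=[("c", "d")])
        coll = NetworkCollection([n1, n2])
        part = CommunityPartition((frozenset("abcd"),), 0.0)
        profile = community_distribution(part, coll)
        assert profile.loc["C1", "N1:nodes"] + profile.loc["C1", "N2:nodes"] == 4


class TestSubgraph:
    def test_c1_of_two_triangles(self, two_triangles):
        part = detect_communities(two_triangles)
        sub = community_subgraph(two_triangles, part, "C1")
        assert sub.n_nodes == 3 and sub.n_edges == 3

    def test_singleton_community(self):
        net = Network("mix", nodes={"x"}, edges=[("a", "b"), ("b", "c"), ("a", "c")])
        part = detect_communities(net)
        cid = part.membership["x"]
        sub = community_subgraph(net, part, cid)
        assert sub.n_nodes == 1 and sub.n_edges == 0

    def test_subgraphs_union_covers_all_nodes(self, two_triangles):
        part = detect_communities(two_triangles)
        covered = set()
        for cid in part.ids:
            covered |= community_subgraph(two_triangles, part, cid).nodes
        assert covered == two_triangles.nodes

    def test_unknown_id_rejected(self, triangle):
        part = detect_communities(triangle)
        with pytest.raises(KeyError, match="valid ids"):
            community_subgraph(triangle, part, "C99")
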