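import random

import numpy as np
import pytest
from hypothesis import given

from netcompare import (
    Network,
    NetworkCollection,
    bubble_chart_data,
    cluster_networks,
    jaccard_edge,
    jaccard_node,
    nsi,
    similarity_matrix,
)

import _oracles as oracle
from conftest import networks, random_network


class TestJaccard:
    def test_node_worked_example(self, net_a, net_b):
        assert jaccard_node(net_a, net_b) == pytest.approx(0.6)

    def test_edge_worked_example(self, net_a, net_b):
        assert jaccard_edge(net_a, net_b) == pytest.approx(0.5)

    def test_identity_and_disjoint(self, net_a):
        assert jaccard_node(net_a, net_a) == 1
        assert jaccard_edge(net_a, net_a) == 1
        other = Network("Z", edges=[("x", "y")])
        assert jaccard_node(net_a, other) == 0
        assert jaccard_edge(net_a, other) == 0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard_node(Network("E1"), Network("E2"))
        with pytest.raises(ValueError, match="empty"):
            jaccard_edge(Network("E1"), Network("E2"))


class TestNsi:
    def test_worked_example(self, net_a, net_b):
        score = nsi(net_a, net_b)
        # terms a:0, b:1/2, c:1, d:1/2, e:0
        assert score.raw == pytest.approx(2.0)
        assert score.normalized == pytest.approx(0.4)
        assert score.undefined_terms == 0

    def test_self_similarity(self, net_a):
        score = nsi(net_a, net_a)
        assert score.raw == net_a.n_nodes  # no isolates in A
        assert score.normalized == 1

    def test_shared_nodes_no_shared_edges(self):
        a = Network("A", edges=[("a", "b")])
        b = Network("B", edges=[("a", "c")])
        assert nsi(a, b).raw == 0

    def test_isolates_in_both_counted_not_scored(self):
        a = Network("A", nodes={"i"}, edges=[("a", "b")])
        b = Network("B", nodes={"i"}, edges=[("a", "b")])
        score = nsi(a, b)
        assert score.undefined_terms == 1
        assert score.raw == pytest.approx(2.0)
        assert score.normalized == pytest.approx(2 / 3)

    @given(networks(name="P"), networks(name="Q"))
    def test_symmetry_and_bounds(self, p, q):
        s1, s2 = nsi(p, q), nsi(q, p)
        assert s1.raw == pytest.approx(s2.raw)
        assert 0 <= s1.normalized <= 1
        assert jaccard_node(p, q) == pytest.approx(jaccard_node(q, p))
        assert jaccard_edge(p, q) == pytest.approx(jaccard_edge(q, p))

    def test_raw_matches_bruteforce_oracle(self):
        rng = random.Random(13)
        for i in range(30):
            p = random_network(rng, "P", max_nodes=15)
            q = random_network(rng, "Q", max_nodes=15)
            assert nsi(p, q).raw == pytest.approx(oracle.nsi_raw(p, q))

    def test_relabeling_invariance(self, net_a, net_b):
        mapping = {c: c.upper() for c in "abcde"}

        def relabel(net):
            return Network(
                net.name, edges=[(mapping[u], mapping[v]) for u, v in net.edges]
            )

        assert nsi(relabel(net_a), relabel(net_b)).raw == pytest.approx(
            nsi(net_a, net_b).raw
        )
        assert jaccard_node(relabel(net_a), relabel(net_b)) == pytest.approx(
            jaccard_node(net_a, net_b)
        )


class TestSimilarityMatrix:
    def test_worked_example(self, collection_abc):
        m = similarity_matrix(collection_abc, method="jaccard_edge")
        assert m.score("A", "B") == pytest.approx(0.5)
        assert m.score("A", "C") == pytest.approx(1 / 4)
        assert m.score("B", "C") == pytest.approx(1 / 4)
        assert np.allclose(np.diag(m.values), 1)

    def test_identical_networks_all_ones(self, net_a):
        coll = NetworkCollection([net_a, net_a.renamed("A2"), net_a.renamed("A3")])
        m = similarity_matrix(coll, method="jaccard_node")
        assert np.allclose(m.values, 1)

    def test_order_invariance(self, net_a, net_b, net_c):
        m1 = similarity_matrix(NetworkCollection([net_a, net_b, net_c]))
        m2 = similarity_matrix(NetworkCollection([net_c, net_a, net_b]))
        for x in "ABC":
            for y in "ABC":
                assert m1.score(x, y) == pytest.approx(m2.score(x, y))

    def test_unknown_method_rejected(self, collection_ab):
        with pytest.raises(ValueError, match="unknown method"):
            similarity_matrix(collection_ab, method="cosine")

    def test_pair_failure_identifies_pair(self, net_a):
        coll = NetworkCollection([net_a, Network("E1"), Network("E2")])
        with pytest.raises(ValueError, match=r"\('E1', 'E2'\)"):
            similarity_matrix(coll, method="jaccard_node")


class TestClustering:
    def test_upgma_worked_example(self, collection_abc):
        m = similarity_matrix(collection_abc, method="jaccard_edge")
        dendro = cluster_networks(m, "average")
        heights = dendro.merge_heights()
        assert heights[0] == pytest.approx(0.5)  # A,B merge first
        assert heights[1] == pytest.approx(0.75)  # C joins at mean distance
        assert set(dendro.names) == {"A", "B", "C"}
        nwk = dendro.to_newick()
        assert nwk.startswith("(") and nwk.endswith(");")
        assert "A" in nwk and "C" in nwk

    def test_two_networks_single_merge(self, collection_ab):
        m = similarity_matrix(collection_ab, method="jaccard_edge")
        dendro = cluster_networks(m)
        assert len(dendro.linkage_matrix) == 1
        assert dendro.merge_heights()[0] == pytest.approx(0.5)

    def test_newick_parses_with_standard_tools(self, collection_abc):
        import io

        from Bio import Phylo

        m = similarity_matrix(collection_abc, method="jaccard_edge")
        tree = Phylo.read(io.StringIO(cluster_networks(m).to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]

    def test_deterministic(self, collection_abc):
        m = similarity_matrix(collection_abc, method="nsi_normalized")
        assert cluster_networks(m).to_newick() == cluster_networks(m).to_newick()


class TestBubbleChart:
    def test_worked_example(self, collection_abc):
        m = similarity_matrix(collection_abc, method="jaccard_edge")
        bubble = bubble_chart_data(m)
        assert bubble.iloc[0].tolist() == ["A", "B", 0.5]
        assert len(bubble) == 3  # C(3,2)

    def test_two_networks_single_row(self, collection_ab):
        m = similarity_matrix(collection_ab, method="jaccard_node")
        assert len(bubble_chart_data(m)) == 1

    def test_pair_count(self):
        rng = random.Random(2)
        nets = [random_network(rng, f"N{i}") for i in range(5)]
        m = similarity_matrix(NetworkCollection(nets), method="jaccard_node")
        assert len(bubble_chart_data(m)) == 10
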