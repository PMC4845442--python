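import math
import random

import pytest

from netcompare import (
    Network,
    NetworkCollection,
    global_properties,
    global_properties_table,
    node_properties,
    top_k_report,
)

import _oracles as oracle
from conftest import random_network


class TestGlobalProperties:
    def test_path_graph(self, path_graph):
        gp = global_properties(path_graph)
        assert (gp.n_nodes, gp.n_edges) == (4, 3)
        assert gp.density == pytest.approx(0.5)
        assert gp.clustering_coefficient == 0
        assert gp.average_path_length == pytest.approx(10 / 6)
        assert gp.diameter == 3

    def test_triangle(self, triangle):
        gp = global_properties(triangle)
        assert gp.density == 1
        assert gp.clustering_coefficient == 1
        assert gp.average_path_length == 1
        assert gp.diameter == 1

    def test_empty_network_degenerate(self):
        gp = global_properties(Network("empty"))
        assert gp.degenerate
        assert all(v == 0 for v in gp.as_dict().values())

    def test_disconnected_uses_reachable_pairs(self):
        net = Network("two-comp", edges=[("a", "b"), ("c", "d")])
        gp = global_properties(net)
        assert gp.average_path_length == 1.0
        assert gp.diameter == 1.0

    def test_average_local_clustering_option(self):
        # triangle + pendant: transitivity 3*1/5, mean local (1+1+1/3+0)/4
        net = Network("paw", edges=[("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        assert global_properties(net).clustering_coefficient == pytest.approx(3 / 5)
        assert global_properties(net, clustering="average_local") \
            .clustering_coefficient == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)

    def test_diameter_bounds_apl(self):
        rng = random.Random(3)
        for i in range(20):
            net = random_network(rng, f"G{i}")
            gp = global_properties(net)
            if gp.n_edges >= 1:
                assert gp.diameter >= gp.average_path_length >= 1


class TestNodeProperties:
    def test_star_center(self):
        star = Network("star", edges=[("z", l) for l in "abcd"])
        props = node_properties(star)
        assert props.loc["z", "degree"] == 4
        assert props.loc["z", "betweenness"] == 6  # all C(4,2) leaf pairs
        assert props.loc["a", "betweenness"] == 0

    def test_path_leaf_betweenness_zero(self, path_graph):
        props = node_properties(path_graph, ["betweenness"])
        assert props.loc["a", "betweenness"] == 0
        assert props.loc["d", "betweenness"] == 0

    def test_triangle_coreness(self, triangle):
        props = node_properties(triangle, ["coreness"])
        assert (props["coreness"] == 2).all()

    def test_unknown_metric_lists_valid(self, triangle):
        with pytest.raises(ValueError, match="valid metrics"):
            node_properties(triangle, ["pagerank"])

    def test_degree_sums_to_twice_edges(self):
        rng = random.Random(11)
        for i in range(20):
            net = random_network(rng, f"G{i}")
            props = node_properties(net, ["degree", "coreness"])
            assert props["degree"].sum() == 2 * net.n_edges
            assert (props["coreness"] <= props["degree"]).all()

    def test_normalized_betweenness_flag(self):
        star = Network("star", edges=[("z", l) for l in "abcd"])
        props = node_properties(star, ["betweenness"], normalized_betweenness=True)
        assert props.loc["z", "betweenness"] == pytest.approx(1.0)

    def test_agrees_with_bruteforce_oracles(self):
        rng = random.Random(42)
        for i in range(25):
            net = random_network(rng, f"G{i}", max_nodes=10)
            props = node_properties(
                net, ["degree", "betweenness", "closeness", "eccentricity", "coreness"]
            )
            bw = oracle.betweenness(net)
            cl = oracle.closeness(net)
            ecc = oracle.eccentricity(net)
            core = oracle.coreness(net)
            for v in net.nodes:
                assert props.loc[v, "betweenness"] == pytest.approx(bw[v])
                assert props.loc[v, "closeness"] == pytest.approx(cl[v])
                assert props.loc[v, "eccentricity"] == ecc[v]
                assert props.loc[v, "coreness"] == core[v]
            gp = global_properties(net)
            assert gp.clustering_coefficient == pytest.approx(oracle.transitivity(net))
            assert gp.average_path_length == pytest.approx(oracle.average_path_length(net))
            assert gp.diameter == oracle.diameter(net)


class TestTopK:
    def test_worked_example(self, collection_ab):
        # union is the path a-b-c-d-e: b, c, d tie at degree 2 and the
        # lexicographic tie-break puts b first; b occurs in both networks
        report = top_k_report(collection_ab, metric="degree", k=1)
        assert report.iloc[0]["node"] == "b"
        assert report.iloc[0]["degree"] == 2
        assert report.iloc[0][["A", "B"]].tolist() == [1, 1]

    def test_k_larger_than_node_count(self, collection_ab):
        report = top_k_report(collection_ab, metric="degree", k=99)
        assert len(report) == 5

    def test_identical_networks_all_flags_one(self, net_a):
        coll = NetworkCollection([net_a, net_a.renamed("A2")])
        report = top_k_report(coll, metric="degree", k=4)
        assert (report[["A", "A2"]] == 1).all().all()

    def test_ties_break_lexicographically(self, path_graph):
        coll = NetworkCollection([path_graph])
        report = top_k_report(coll, metric="degree", k=4)
        # b and c tie at degree 2, then a and d at 1
        assert report["node"].tolist() == ["b", "c", "a", "d"]

    def test_per_network_scope_adds_value_columns(self, collection_ab):
        report = top_k_report(collection_ab, metric="degree", k=2, scope="per-network")
        assert "degree:A" in report.columns and "degree:B" in report.columns
        row = report[report.node == "c"].iloc[0]
        assert row["degree:A"] == 2 and row["degree:B"] == 2
        a_only = report[report.node == "a"]
        if not a_only.empty:
            assert math.isnan(a_only.iloc[0]["degree:B"])


def test_global_properties_table_shape(collection_abc):
    table = global_properties_table(collection_abc)
    assert list(table.index) == ["A", "B", "C"]
    assert table.loc["A", "n_edges"] == 3
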