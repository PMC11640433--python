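import math

import networkx as nx
import numpy as np
import pytest

import groupnet as gn
from groupnet.metrics import PathLengthSummary, node_metrics, species_summary

from .oracles import (
    betweenness_bruteforce,
    clustering_bruteforce,
    degree_bruteforce,
    density_bruteforce,
    eigenvector_bruteforce,
    path_lengths_bruteforce,
    random_weighted_graph,
)


def graph_from_adjacency(adj):
    net = nx.Graph()
    n = adj.shape[0]
    net.add_nodes_from(str(i) for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] > 0:
                net.add_edge(str(i), str(j), weight=float(adj[i, j]))
    return net


def weighted_graph(edges, nodes=None):
    net = nx.Graph()
    if nodes:
        net.add_nodes_from(nodes)
    for u, v, w in edges:
        net.add_edge(u, v, weight=w)
    return net


class TestBuildNetwork:
    def test_zero_matrix_gives_edgeless_network(self):
        matrix = gn.AssociationMatrix(np.zeros((3, 3)), list("ABC"))
        net = gn.build_network(matrix)
        assert net.number_of_edges() == 0 and net.number_of_nodes() == 3

    def test_all_ones_gives_triangle(self):
        values = np.ones((3, 3)) - np.eye(3)
        net = gn.build_network(gn.AssociationMatrix(values, list("ABC")))
        assert net.number_of_edges() == 3

    def test_threshold_is_strict(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.4
        values[1, 2] = values[2, 1] = 0.6
        net = gn.build_network(gn.AssociationMatrix(values, list("ABC")), threshold=0.5)
        assert list(net.edges) == [("B", "C")]

    def test_negative_threshold_rejected(self):
        matrix = gn.AssociationMatrix(np.zeros((2, 2)), ["A", "B"])
        with pytest.raises(gn.ValidationError):
            gn.build_network(matrix, threshold=-0.1)


class TestDensity:
    def test_triangle_is_full(self):
        assert gn.density(weighted_graph([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])) == 1.0

    def test_one_of_three_possible_ties(self):
        net = weighted_graph([("a", "b", 1)], nodes=["a", "b", "c"])
        assert gn.density(net) == pytest.approx(1 / 3)

    def test_single_node_rejected(self):
        assert pytest.raises(gn.ValidationError, gn.density, weighted_graph([], nodes=["a"]))


class TestDegree:
    def test_star(self):
        net = weighted_graph([("hub", leaf, 0.5) for leaf in "abc"])
        deg = gn.degree_centrality(net)
        assert deg["hub"] == 3 and all(deg[leaf] == 1 for leaf in "abc")

    def test_complete_graph(self):
        net = graph_from_adjacency(np.ones((5, 5)) - np.eye(5))
        assert set(gn.degree_centrality(net).values()) == {4}


class TestEigenvector:
    def test_complete_graph_all_one(self):
        net = graph_from_adjacency(np.ones((4, 4)) - np.eye(4))
        assert gn.eigenvector_centrality(net) == pytest.approx(
            {str(i): 1.0 for i in range(4)}
        )

    def test_star_closed_form(self):
        """K_{1,3} principal eigenvector: center 1, leaves 1/sqrt(3)."""
        net = weighted_graph([("hub", leaf, 1.0) for leaf in "abc"])
        eig = gn.eigenvector_centrality(net)
        assert eig["hub"] == pytest.approx(1.0)
        for leaf in "abc":
            assert eig[leaf] == pytest.approx(1 / math.sqrt(3))

    def test_heavier_clique_carries_the_maximum(self):
        heavy = [(f"h{i}", f"h{j}", 0.9) for i in range(3) for j in range(i + 1, 3)]
        light = [(f"l{i}", f"l{j}", 0.2) for i in range(3) for j in range(i + 1, 3)]
        net = weighted_graph(heavy + light)
        eig = gn.eigenvector_centrality(net)
        assert max(eig, key=eig.get).startswith("h")
        assert all(eig[f"l{i}"] < 0.5 for i in range(3))

    def test_all_zero_adjacency_warns(self):
        net = weighted_graph([], nodes=["a", "b"])
        with pytest.warns(UserWarning):
            assert gn.eigenvector_centrality(net) == {"a": 0.0, "b": 0.0}


class TestBetweenness:
    def test_path_middle_node(self):
        net = weighted_graph([("a", "b", 0.3), ("b", "c", 0.2)])
        bc = gn.betweenness_centrality(net)
        assert bc == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_complete_equal_weights_all_zero(self):
        net = graph_from_adjacency(0.5 * (np.ones((4, 4)) - np.eye(4)))
        assert set(gn.betweenness_centrality(net).values()) == {0.0}

    def test_five_node_weighted_vs_bruteforce(self, rng):
        for _ in range(20):
            adj = random_weighted_graph(rng, max_n=5)
            net = graph_from_adjacency(adj)
            got = gn.betweenness_centrality(net)
            want = betweenness_bruteforce(adj)
            for i, v in enumerate(want):
                assert got[str(i)] == pytest.approx(v, abs=1e-9)


class TestClustering:
    def test_triangle_all_one(self):
        net = weighted_graph([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        assert set(gn.clustering_coefficient(net).values()) == {1.0}

    def test_star_center_zero_leaves_undefined(self):
        net = weighted_graph([("hub", leaf, 1.0) for leaf in "abc"])
        clu = gn.clustering_coefficient(net)
        assert clu["hub"] == 0.0
        assert all(math.isnan(clu[leaf]) for leaf in "abc")

    def test_four_node_vs_bruteforce(self, rng):
        for _ in range(20):
            adj = random_weighted_graph(rng, max_n=4)
            got = gn.clustering_coefficient(graph_from_adjacency(adj))
            want = clustering_bruteforce(adj)
            for i, v in enumerate(want):
                if math.isnan(v):
                    assert math.isnan(got[str(i)])
                else:
                    assert got[str(i)] == pytest.approx(v, abs=1e-9)


class TestAveragePathLength:
    def test_single_edge(self):
        net = weighted_graph([("a", "b", 0.25)])
        res = gn.average_path_length(net)
        assert res == PathLengthSummary(0.25, 0.0, 1, 0)

    def test_three_node_path_hand_enumeration(self):
        net = weighted_graph([("a", "b", 0.1), ("b", "c", 0.2)])
        res = gn.average_path_length(net)
        assert res.mean == pytest.approx(np.mean([0.1, 0.2, 0.3]))
        assert res.sd == pytest.approx(np.std([0.1, 0.2, 0.3], ddof=1))

    def test_unreachable_pairs_excluded_and_counted(self):
        net = weighted_graph([("a", "b", 0.1), ("c", "d", 0.2)])
        res = gn.average_path_length(net)
        assert res.n_pairs == 2 and res.n_unreachable == 4
        assert res.mean == pytest.approx(0.15)

    def test_subset_pairs(self):
        net = weighted_graph([("a", "b", 0.1), ("b", "c", 0.2)])
        res = gn.average_path_length(net, subset=["a"])
        assert res.n_pairs == 2
        assert res.mean == pytest.approx(np.mean([0.1, 0.3]))

    def test_no_reachable_pairs_rejected(self):
        with pytest.raises(gn.ValidationError):
            gn.average_path_length(weighted_graph([], nodes=["a", "b"]))

    def test_inverse_distance_mode(self):
        # with 1/w distances the strong tie becomes the short route
        net = weighted_graph([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.1)])
        direct = gn.average_path_length(net, distance="inverse")
        # a-c via b costs 2+2=4 < 10 direct
        assert direct.mean == pytest.approx(np.mean([2.0, 2.0, 4.0]))


class TestSpeciesSummary:
    def make_metrics(self, species, **columns):
        import pandas as pd

        data = {"species": species}
        data.update(columns)
        base = {
            "degree": [0] * len(species),
            "eigenvector": [0.0] * len(species),
            "betweenness": [0.0] * len(species),
            "clustering": [0.0] * len(species),
        }
        base.update(columns)
        data = {"species": species, **base}
        return pd.DataFrame(data, index=[f"i{k}" for k in range(len(species))])

    def test_identical_values_have_zero_sd(self):
        df = self.make_metrics(["cap"] * 3, degree=[2, 2, 2])
        out = species_summary(df)
        assert out.loc["cap", "degree_mean"] == 2
        assert out.loc["cap", "degree_sd"] == 0.0

    def test_two_species_means(self):
        df = self.make_metrics(["cap", "cap", "squ"], degree=[1, 3, 2])
        out = species_summary(df)
        assert out.loc["cap", "degree_mean"] == 2 and out.loc["squ", "degree_mean"] == 2

    def test_undefined_clustering_skipped(self):
        df = self.make_metrics(
            ["cap", "cap", "cap"], clustering=[0.5, float("nan"), 1.0]
        )
        out = species_summary(df)
        assert out.loc["cap", "clustering_mean"] == pytest.approx(0.75)


class TestInvariants:
    def test_mean_degree_equals_density_times_n_minus_one(self, rng):
        for _ in range(20):
            adj = random_weighted_graph(rng)
            net = graph_from_adjacency(adj)
            deg = np.array(list(gn.degree_centrality(net).values()), dtype=float)
            n = net.number_of_nodes()
            assert deg.mean() == pytest.approx(gn.density(net) * (n - 1), abs=1e-12)

    def test_published_degree_means_reproduce_published_densities(self):
        """Size-weighted species degree means / (n-1) give 0.590 and 0.733."""
        from groupnet import datasets

        assert datasets.implied_density("West") == pytest.approx(0.590, abs=5e-4)
        assert datasets.implied_density("East") == pytest.approx(0.733, abs=5e-4)

    def test_rescaling_weights(self, rng):
        """Scaling all weights by c > 0 fixes degree/density/clustering/
        eigenvector and scales path lengths and geodesics by c."""
        adj = random_weighted_graph(rng, max_n=6)
        c = 3.7
        a, b = graph_from_adjacency(adj), graph_from_adjacency(c * adj)
        assert gn.degree_centrality(a) == gn.degree_centrality(b)
        assert gn.density(a) == gn.density(b)
        for (k1, v1), (k2, v2) in zip(
            gn.clustering_coefficient(a).items(), gn.clustering_coefficient(b).items()
        ):
            assert k1 == k2 and (v1 == pytest.approx(v2, nan_ok=True))
        eig_a, eig_b = gn.eigenvector_centrality(a), gn.eigenvector_centrality(b)
        for k in eig_a:
            assert eig_a[k] == pytest.approx(eig_b[k], abs=1e-9)
        pa = gn.average_path_length(a)
        pb = gn.average_path_length(b)
        assert pb.mean == pytest.approx(c * pa.mean)
        bc_a = gn.betweenness_centrality(a)
        bc_b = gn.betweenness_centrality(b)
        for k in bc_a:
            assert bc_a[k] == pytest.approx(bc_b[k], abs=1e-9)

    def test_oracle_agreement_random_graphs(self, rng):
        """Spot-check all metric implementations against brute force."""
        for _ in range(30):
            adj = random_weighted_graph(rng)
            net = graph_from_adjacency(adj)
            n = adj.shape[0]
            assert gn.density(net) == pytest.approx(density_bruteforce(adj), abs=1e-12)
            assert list(gn.degree_centrality(net).values()) == \
                degree_bruteforce(adj).tolist()
            if adj.any():
                eig = gn.eigenvector_centrality(net)
                want = eigenvector_bruteforce(adj)
                for i in range(n):
                    assert eig[str(i)] == pytest.approx(want[i], abs=1e-7)
            lengths = path_lengths_bruteforce(adj)
            if lengths:
                want_mean = np.mean(list(lengths.values()))
                assert gn.average_path_length(net).mean == pytest.approx(
                    want_mean, abs=1e-9
                )


class TestNodeMetricsTable:
    def test_table_carries_attributes_and_metrics(self, abc_roster):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.5
        matrix = gn.AssociationMatrix(values, ["A", "B", "C"])
        net = gn.build_network(matrix, roster=abc_roster)
        table = node_metrics(net)
        assert list(table.columns) == [
            "species", "sex", "group", "degree", "eigenvector",
            "betweenness", "clustering",
        ]
        assert table.loc["A", "species"] == "capuchin"
        assert table.loc["C", "degree"] == 0
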