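import numpy as np
import pytest

from covstab import (
    BinaryGraph,
    WeightedGraph,
    average_strength,
    characteristic_path_length,
    clustering_coefficient,
    compute_metric,
    global_efficiency,
    nodal_stats,
    shortest_paths,
    transitivity,
)
from covstab.exceptions import DisconnectedGraphError, ParameterError
from oracles import (
    brute_clustering,
    brute_distances,
    brute_efficiency,
    brute_transitivity,
)


def binary(adj):
    return BinaryGraph(np.asarray(adj, dtype=float), target_density=0.5)


def weighted(w):
    return WeightedGraph(np.asarray(w, dtype=float))


def path_graph():
    return binary([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


def complete_binary(n):
    return binary(np.ones((n, n)) - np.eye(n))


def star_graph():
    a = np.zeros((4, 4))
    a[0, 1:] = a[1:, 0] = 1
    return binary(a)


class TestShortestPaths:
    def test_binary_path_graph_hops(self):
        D = shortest_paths(path_graph()).distances
        assert D[0, 2] == 2
        assert D[0, 1] == 1

    def test_weighted_detour_beats_weak_direct_edge(self):
        w = np.array([[0, 1.0, 0.4], [1.0, 0, 1.0], [0.4, 1.0, 0]])
        D = shortest_paths(weighted(w)).distances
        assert D[0, 2] == pytest.approx(2.0)  # via the middle node, not 1/0.4

    def test_isolated_node_is_unreachable(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1
        D = shortest_paths(binary(a)).distances
        assert np.isinf(D[0, 2]) and np.isinf(D[2, 1])
        assert D[2, 2] == 0


class TestCharacteristicPathLength:
    def test_complete_binary_graph(self):
        assert characteristic_path_length(shortest_paths(complete_binary(5))) == 1.0

    def test_three_node_path(self):
        L = characteristic_path_length(shortest_paths(path_graph()))
        assert L == pytest.approx(4 / 3)

    def test_uniform_weighted_complete_graph(self):
        w = 0.5 * (np.ones((6, 6)) - np.eye(6))
        assert characteristic_path_length(shortest_paths(weighted(w))) == pytest.approx(2.0)

    def test_disconnected_graph_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1
        with pytest.raises(DisconnectedGraphError):
            characteristic_path_length(shortest_paths(binary(a)))


class TestGlobalEfficiency:
    def test_complete_binary_graph(self):
        assert global_efficiency(shortest_paths(complete_binary(4))) == 1.0

    def test_three_node_path(self):
        E = global_efficiency(shortest_paths(path_graph()))
        assert E == pytest.approx(5 / 6)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(shortest_paths(binary(np.zeros((4, 4))))) == 0.0


class TestNodalStats:
    def test_binary_triangle(self):
        s = nodal_stats(complete_binary(3))
        np.testing.assert_array_equal(s.triangles, [1, 1, 1])
        np.testing.assert_array_equal(s.degree, [2, 2, 2])

    def test_uniform_weighted_triangle_intensity_equals_weight(self):
        for w in (0.3, 0.6, 1.0):
            W = w * (np.ones((3, 3)) - np.eye(3))
            s = nodal_stats(weighted(W))
            np.testing.assert_allclose(s.triangles, w)

    def test_star_has_no_triangles(self):
        assert nodal_stats(star_graph()).triangles.sum() == 0

    def test_negative_weight_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -0.2
        with pytest.raises(ParameterError):
            WeightedGraph(w)


class TestClusteringAndTransitivity:
    def test_complete_binary_graph_is_fully_clustered(self):
        assert clustering_coefficient(complete_binary(5)) == 1.0
        assert transitivity(complete_binary(5)) == 1.0

    def test_uniform_weighted_complete_three_nodes(self):
        W = 0.6 * (np.ones((3, 3)) - np.eye(3))
        assert clustering_coefficient(weighted(W)) == pytest.approx(0.6)

    def test_star_graph_clustering_zero(self):
        assert clustering_coefficient(star_graph()) == 0.0

    def test_path_graph_transitivity_zero(self):
        assert transitivity(path_graph()) == 0.0

    def test_transitivity_undefined_without_degree_two(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1
        with pytest.raises(ParameterError):
            transitivity(binary(a))

    def test_fully_connected_weighted_clustering_equals_transitivity(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            w = rng.uniform(0.05, 1.0, size=(7, 7))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            G = weighted(w)
            assert clustering_coefficient(G) == pytest.approx(
                transitivity(G), abs=1e-12
            )


class TestAverageStrength:
    def test_uniform_weights(self):
        W = 0.5 * (np.ones((5, 5)) - np.eye(5))
        assert average_strength(weighted(W)) == 0.5

    def test_three_pair_mean(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.9
        assert average_strength(weighted(w)) == pytest.approx(0.5)

    def test_zero_graph(self):
        assert average_strength(weighted(np.zeros((4, 4)))) == 0.0


class TestOracleAgreement:
    """Vectorized measures agree with naive path-enumeration / triple-loop code."""

    def test_random_binary_graphs_match_brute_force_and_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(3, 7))
            a = (rng.random((n, n)) < 0.5).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            G = binary(a)
            D = shortest_paths(G).distances
            np.testing.assert_allclose(D, brute_distances(a, weighted=False))
            assert global_efficiency(shortest_paths(G)) == pytest.approx(
                brute_efficiency(a, False), abs=1e-12
            )
            assert clustering_coefficient(G) == pytest.approx(
                brute_clustering(a, False), abs=1e-12
            )
            gx = nx.from_numpy_array(a)
            assert global_efficiency(shortest_paths(G)) == pytest.approx(
                nx.global_efficiency(gx), abs=1e-12
            )
            assert clustering_coefficient(G) == pytest.approx(
                nx.average_clustering(gx), abs=1e-12
            )
            bt = brute_transitivity(a, False)
            if bt is None:
                with pytest.raises(ParameterError):
                    transitivity(G)
            else:
                assert transitivity(G) == pytest.approx(bt, abs=1e-12)
                assert transitivity(G) == pytest.approx(nx.transitivity(gx), abs=1e-12)

    def test_random_weighted_graphs_match_brute_force(self):
        rng = np.random.default_rng(43)
        for _ in range(15):
            n = int(rng.integers(3, 7))
            w = rng.uniform(0.05, 1.0, size=(n, n))
            w = np.where(rng.random((n, n)) < 0.3, 0.0, w)
            w = np.triu(w, 1)
            w = w + w.T
            G = weighted(w)
            np.testing.assert_allclose(
                shortest_paths(G).distances, brute_distances(w, weighted=True), atol=1e-12
            )
            assert global_efficiency(shortest_paths(G)) == pytest.approx(
                brute_efficiency(w, True), abs=1e-12
            )
            assert clustering_coefficient(G) == pytest.approx(
                brute_clustering(w, True), abs=1e-12
            )


class TestInvariances:
    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a = (rng.random((8, 8)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        perm = rng.permutation(8)
        ap = a[np.ix_(perm, perm)]
        for metric in ("global_efficiency", "clustering", "transitivity"):
            assert compute_metric(binary(a), metric) == pytest.approx(
                compute_metric(binary(ap), metric), abs=1e-12
            )

    def test_weight_rescaling_laws(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0.1, 1.0, size=(7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        c = 0.5
        G, Gc = weighted(w), weighted(c * w)
        assert average_strength(Gc) == pytest.approx(c * average_strength(G), rel=1e-12)
        assert clustering_coefficient(Gc) == pytest.approx(
            c * clustering_coefficient(G), rel=1e-12
        )
        assert transitivity(Gc) == pytest.approx(c * transitivity(G), rel=1e-12)
        # distances scale by 1/c, so L scales by 1/c and E by c
        assert characteristic_path_length(shortest_paths(Gc)) == pytest.approx(
            characteristic_path_length(shortest_paths(G)) / c, rel=1e-12
        )
        assert global_efficiency(shortest_paths(Gc)) == pytest.approx(
            c * global_efficiency(shortest_paths(G)), rel=1e-12
        )
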