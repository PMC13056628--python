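"""Graph metrics on canonical graphs with hand-computed values, plus the
behaviour of thresholding, null models and the bundled suite."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_symmetric
from mmconn.core import ConnectivityMatrix
from mmconn.graphnet import (
    NullConfig,
    ThresholdConfig,
    ThresholdError,
    assortativity,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    degree_preserving_rewire,
    density,
    edge_count_for,
    global_efficiency,
    metrics_suite,
    modularity_louvain,
    proportional_threshold,
    rich_club,
    rich_club_curve,
    small_worldness,
)


def adj_from_edges(n, edges):
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return a


PATH3 = adj_from_edges(3, [(0, 1), (1, 2)])
TRIANGLE = adj_from_edges(3, [(0, 1), (1, 2), (0, 2)])
K4 = adj_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
STAR5 = adj_from_edges(5, [(0, i) for i in range(1, 5)])


class TestProportionalThreshold:
    def test_fixed_edge_count_104(self, rng):
        w = random_symmetric(104, rng, positive=True)
        adj = proportional_threshold(w, ThresholdConfig(0.05, True))
        assert edge_count_for(104, 0.05) == 268
        assert int(adj.sum() / 2) == 268
        assert density(adj) == pytest.approx(268 / 5356)
        assert adj.sum(axis=1).mean() == pytest.approx(5.154, abs=5e-4)

    def test_tie_break_deterministic(self):
        w = np.ones((10, 10)) - np.eye(10)  # every edge ties
        a1 = proportional_threshold(w, ThresholdConfig(0.2, True))
        a2 = proportional_threshold(w, ThresholdConfig(0.2, True))
        assert np.array_equal(a1, a2)
        assert int(a1.sum() / 2) == edge_count_for(10, 0.2)
        # ties resolved toward ascending (i, j): first rows fill first
        i, j = np.nonzero(np.triu(a1, 1))
        expected = sorted(zip(i, j))[: edge_count_for(10, 0.2)]
        assert list(zip(i, j)) == expected

    def test_exact_k_regardless_of_tie_pattern(self, rng):
        w = rng.integers(0, 3, size=(30, 30)).astype(float)  # heavy ties
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        w[w == 0] = 0.5  # make all edges eligible
        np.fill_diagonal(w, 0)
        adj = proportional_threshold(w, ThresholdConfig(0.1, True))
        assert int(adj.sum() / 2) == edge_count_for(30, 0.1)

    def test_permutation_equivariance(self, rng):
        w = random_symmetric(20, rng, positive=True)
        perm = rng.permutation(20)
        a = proportional_threshold(w, ThresholdConfig(0.1, True))
        ap = proportional_threshold(w[np.ix_(perm, perm)], ThresholdConfig(0.1, True))
        # equivariant up to tie handling; generic continuous weights are tie-free
        assert np.array_equal(ap, a[np.ix_(perm, perm)])

    def test_too_few_positive_edges(self):
        w = -np.abs(random_symmetric(104, np.random.default_rng(0)))
        np.fill_diagonal(w, 0)
        with pytest.raises(ThresholdError):
            proportional_threshold(w, ThresholdConfig(0.05, True))

    def test_weighted_mode_keeps_weights(self, rng):
        w = random_symmetric(104, rng, positive=True)
        adj = proportional_threshold(w, ThresholdConfig(0.05, True, "weighted"))
        nz = adj != 0
        assert np.allclose(adj[nz], w[nz])


class TestDensity:
    def test_complete_and_empty(self):
        assert density(K4) == 1.0
        assert density(np.zeros((6, 6))) == 0.0


class TestGlobalEfficiency:
    def test_complete_k4(self):
        assert global_efficiency(K4) == pytest.approx(1.0)

    def test_path_graph(self):
        assert global_efficiency(PATH3) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_isolated_nodes(self):
        assert global_efficiency(np.zeros((5, 5))) == 0.0


class TestClustering:
    def test_triangle(self):
        assert clustering_coefficient(TRIANGLE)[0] == 1.0

    def test_star(self):
        assert clustering_coefficient(STAR5)[0] == 0.0

    def test_k4_minus_edge(self):
        a = K4.copy()
        a[0, 1] = a[1, 0] = 0
        c, ci = clustering_coefficient(a)
        assert c == pytest.approx((2 / 3 + 2 / 3 + 1 + 1) / 4)


class TestPathLength:
    def test_complete(self):
        assert characteristic_path_length(K4) == (1.0, 0)

    def test_path_graph(self):
        l, exc = characteristic_path_length(PATH3)
        assert l == pytest.approx(4 / 3)
        assert exc == 0

    def test_disconnected_pairs_excluded(self):
        a = adj_from_edges(4, [(0, 1), (2, 3)])
        l, exc = characteristic_path_length(a)
        assert l == 1.0
        assert exc == 4


class TestModularity:
    def test_two_triangles(self, rng):
        a = adj_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        q, parts = modularity_louvain(a, rng)
        assert q == pytest.approx(0.5)
        assert sorted(sorted(p) for p in parts) == [[0, 1, 2], [3, 4, 5]]

    def test_complete_graph_single_community(self, rng):
        q, parts = modularity_louvain(K4, rng)
        assert q == pytest.approx(0.0)
        assert len(parts) == 1

    def test_seed_determinism(self):
        a = (random_symmetric(30, np.random.default_rng(3), positive=True) > 0.8).astype(float)
        a = np.triu(a, 1) + np.triu(a, 1).T
        q1, p1 = modularity_louvain(a, np.random.default_rng(9))
        q2, p2 = modularity_louvain(a, np.random.default_rng(9))
        assert q1 == q2 and p1 == p2


class TestAssortativity:
    def test_star_is_minus_one(self):
        assert assortativity(STAR5) == pytest.approx(-1.0)

    def test_ring_undefined(self):
        ring = adj_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        assert assortativity(ring) is None

    def test_two_cliques_undefined(self):
        a = adj_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert assortativity(a) is None


class TestRewire:
    def test_degree_sequence_and_edge_count_preserved(self, rng):
        g = nx.to_numpy_array(nx.erdos_renyi_graph(40, 0.15, seed=4))
        r = degree_preserving_rewire(g, rng)
        assert np.array_equal(g.sum(axis=1), r.sum(axis=1))
        assert g.sum() == r.sum()
        assert np.all(np.diag(r) == 0)

    def test_randomization_destroys_lattice_clustering(self):
        lattice = nx.to_numpy_array(nx.watts_strogatz_graph(50, 4, 0.0))
        c0 = clustering_coefficient(lattice)[0]
        cs = [
            clustering_coefficient(
                degree_preserving_rewire(lattice, np.random.default_rng(s))
            )[0]
            for s in range(10)
        ]
        assert np.mean(cs) < c0 / 2


class TestSmallWorldness:
    def test_erdos_renyi_near_unity(self):
        sigmas = []
        for s in range(10):
            g = nx.to_numpy_array(nx.erdos_renyi_graph(104, 0.05, seed=s))
            sigmas.append(small_worldness(g, np.random.default_rng(s), n_null=10))
        assert 0.5 < np.mean(sigmas) < 2.0

    def test_watts_strogatz_small_world(self):
        g = nx.to_numpy_array(nx.watts_strogatz_graph(104, 6, 0.1, seed=1))
        sigma = small_worldness(g, np.random.default_rng(1), n_null=20)
        assert sigma > 1.0


class TestRichClub:
    def test_complete_graph_raw_curve_is_one(self):
        curve = rich_club_curve(K4)
        assert all(v == 1.0 for v in curve.values())

    def test_erdos_renyi_normalized_near_one(self):
        devs = []
        for s in range(10):
            g = nx.to_numpy_array(nx.erdos_renyi_graph(60, 0.15, seed=s))
            _, norm = rich_club(g, np.random.default_rng(s), n_null=20)
            devs.extend(abs(v - 1.0) for v in norm.values())
        assert np.mean(devs) < 0.3

    def test_planted_core_periphery(self, rng):
        n = 60
        a = (random_symmetric(n, rng, positive=True) > 0.92).astype(float)
        a = np.triu(a, 1) + np.triu(a, 1).T
        a[:10, :10] = 1.0  # dense 10-node core
        np.fill_diagonal(a, 0)
        summary, _ = rich_club(a, np.random.default_rng(0), n_null=30)
        assert summary is not None and summary > 1.0


class TestBetweenness:
    def test_path_graph(self):
        bc = betweenness_centrality(PATH3)
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_complete_graph_all_zero(self):
        assert np.allclose(betweenness_centrality(K4), 0.0)


class TestMetricsSuite:
    def test_density_and_degree_fixed_by_threshold(self, scheme, rng):
        m = ConnectivityMatrix.create(random_symmetric(104, rng, positive=True),
                                      scheme, weight_kind="raw")
        suite = metrics_suite(m, ThresholdConfig(0.05, True), NullConfig(0), rng)
        assert suite.density == pytest.approx(0.05, abs=1e-3)
        assert suite.mean_degree == pytest.approx(5.154, abs=5e-4)

    def test_suite_consistent_with_standalone(self, scheme, rng):
        m = ConnectivityMatrix.create(random_symmetric(104, rng, positive=True), scheme)
        suite = metrics_suite(m, ThresholdConfig(0.05, True), NullConfig(0), rng)
        adj = proportional_threshold(m, ThresholdConfig(0.05, True))
        assert suite.global_efficiency == global_efficiency(adj)
        assert suite.clustering == clustering_coefficient(adj)[0]

    def test_reproducible_under_fixed_seed(self, scheme):
        m = ConnectivityMatrix.create(
            random_symmetric(104, np.random.default_rng(5), positive=True), scheme)
        s1 = metrics_suite(m, ThresholdConfig(0.05, True), NullConfig(10),
                           np.random.default_rng(11))
        s2 = metrics_suite(m, ThresholdConfig(0.05, True), NullConfig(10),
                           np.random.default_rng(11))
        assert s1.global_dict() == s2.global_dict()


class TestEdgeAdditionMonotonicity:
    def test_global_efficiency_strictly_increases(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            a = (random_symmetric(n, rng) > 0.2).astype(float)
            a = np.triu(a, 1) + np.triu(a, 1).T
            absent = [(i, j) for i in range(n) for j in range(i + 1, n) if a[i, j] == 0]
            if not absent:
                continue
            i, j = absent[int(rng.integers(len(absent)))]
            e0 = global_efficiency(a)
            a[i, j] = a[j, i] = 1.0
            assert global_efficiency(a) > e0
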