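import warnings

import numpy as np
import pytest

from aanet.graph_metrics import (
    average_shortest_path_length,
    betweenness,
    betweenness_zscores,
    node_strength,
    shortest_paths,
    small_world_summary,
    weighted_clustering,
)
from aanet.network_build import distance_matrix

from conftest import distance_from_matrix, network_from_matrices
from oracles import (
    betweenness_bruteforce,
    clustering_bruteforce,
    random_test_network,
    shortest_paths_bruteforce,
    strength_bruteforce,
)

INF = np.inf


class TestStrength:
    def test_mixed_sign_links(self):
        a = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        w = np.array([[0, -0.5, 0.3], [-0.5, 0, 0], [0.3, 0, 0]])
        net = network_from_matrices(a, w)
        assert node_strength(net)[0] == pytest.approx(0.8)

    def test_isolated_node(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = a[1, 0] = 1
        w = np.full((3, 3), -0.4)
        net = network_from_matrices(a, w)
        assert node_strength(net)[2] == 0.0

    def test_covalent_links_contribute_zero(self):
        a = np.array([[0, 1], [1, 0]])
        w = np.array([[0, -0.9], [-0.9, 0]])
        cov = np.zeros((2, 2), dtype=bool)
        cov[0, 1] = cov[1, 0] = True
        net = network_from_matrices(a, w, covalent=cov)
        assert np.allclose(node_strength(net), 0.0)


class TestWeightedClustering:
    def test_unit_triangle_is_one(self):
        a = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        w = -(np.ones((3, 3)) - np.eye(3))
        net = network_from_matrices(a, w)
        assert np.allclose(weighted_clustering(net), 1.0)

    def test_path_middle_node_is_zero(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        w = -0.5 * a.astype(float)
        net = network_from_matrices(a, w)
        assert np.allclose(weighted_clustering(net), 0.0)

    def test_all_covalent_star_is_zero(self):
        a = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        cov = a.astype(bool)
        net = network_from_matrices(a, -0.5 * a.astype(float), covalent=cov)
        assert np.allclose(weighted_clustering(net), 0.0)

    def test_bounded_by_unit_interval(self, table, small_chain):
        from aanet.network_build import build_network

        net = build_network(small_chain, table)
        c = weighted_clustering(net)
        assert np.all(c >= 0) and np.all(c <= 1 + 1e-12)


class TestShortestPaths:
    def test_three_chain(self):
        d = np.array([[0, 1, INF], [1, 0, 1], [INF, 1, 0]])
        sp = shortest_paths(distance_from_matrix(d))
        assert sp[0, 2] == pytest.approx(2.0)
        L, frac = average_shortest_path_length(distance_from_matrix(d))
        assert L == pytest.approx(4 / 3)
        assert frac == 1.0

    def test_indirect_route_beats_long_direct_edge(self):
        d = np.array([[0, 1.76, 0.46], [1.76, 0, 0.46], [0.46, 0.46, 0]])
        sp = shortest_paths(distance_from_matrix(d))
        assert sp[0, 1] == pytest.approx(0.92)

    def test_disconnected_pair_reported(self):
        d = np.full((4, 4), INF)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 1.0
        L, frac = average_shortest_path_length(distance_from_matrix(d))
        assert L == pytest.approx(1.0)
        assert frac == pytest.approx(1 / 6)

    def test_negative_edge_is_hard_error(self):
        d = np.array([[0, -0.1], [-0.1, 0]])
        with pytest.raises(ValueError, match="negative"):
            shortest_paths(distance_from_matrix(d))


class TestBetweenness:
    def test_path_graph(self):
        d = np.array([[0, 1, INF], [1, 0, 1], [INF, 1, 0]])
        b = betweenness(distance_from_matrix(d))
        assert b == pytest.approx([0, 1, 0])

    def test_star_center(self):
        d = np.full((4, 4), INF)
        np.fill_diagonal(d, 0)
        for leaf in (1, 2, 3):
            d[0, leaf] = d[leaf, 0] = 1.0
        b = betweenness(distance_from_matrix(d))
        assert b[0] == pytest.approx(3.0)
        assert b[1:] == pytest.approx([0, 0, 0])

    def test_tied_paths_split_fractionally(self):
        # square: two equal shortest routes between opposite corners
        d = np.full((4, 4), INF)
        np.fill_diagonal(d, 0)
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            d[i, j] = d[j, i] = 1.0
        b = betweenness(distance_from_matrix(d))
        assert b == pytest.approx([0.5, 0.5, 0.5, 0.5])


class TestZScores:
    def test_hand_computed_example(self):
        z = betweenness_zscores(np.array([0.0, 0.0, 1.0]))
        assert z == pytest.approx([-1 / np.sqrt(2), -1 / np.sqrt(2), np.sqrt(2)])

    def test_constant_betweenness_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero spread"):
            z = betweenness_zscores(np.array([2.0, 2.0, 2.0]))
        assert np.allclose(z, 0.0)

    def test_population_zscores_sum_to_zero(self, table, small_chain):
        from aanet.network_build import build_network

        net = build_network(small_chain, table)
        z = betweenness_zscores(betweenness(distance_matrix(net, 1)))
        assert z.sum() == pytest.approx(0.0, abs=1e-9)

    def test_sample_sd_option(self):
        b = np.array([0.0, 0.0, 1.0])
        z_pop = betweenness_zscores(b)
        z_samp = betweenness_zscores(b, ddof=1)
        assert np.all(np.abs(z_samp) < np.abs(z_pop))


class TestSmallWorldSummary:
    def test_random_baseline_closed_forms(self, table):
        from aanet.network_build import build_network
        from aanet.synthetic import SyntheticSpec, make_compact_chain

        chain = make_compact_chain(SyntheticSpec(n_residues=100, seed=11))
        net = build_network(chain, table)
        sw = small_world_summary(net, distance_matrix(net, 1))
        assert sw.random_clustering == pytest.approx(sw.mean_degree / 100)
        assert sw.random_path == pytest.approx(
            np.log(100) / np.log(sw.mean_degree)
        )

    def test_known_substitution(self):
        # N = 100, <K> = 10 gives C_r = 0.1, L_r = 2 exactly
        assert 10 / 100 == pytest.approx(0.1)
        assert np.log(100) / np.log(10) == pytest.approx(2.0)


class TestOracleEquivalence:
    """Production metrics must match brute-force enumeration on small graphs."""

    N_GRAPHS = 120

    def test_all_metrics_match_bruteforce(self):
        rng = np.random.default_rng(1234)
        checked = 0
        for _ in range(self.N_GRAPHS):
            n = int(rng.integers(4, 9))
            adjacency, weights = random_test_network(rng, n)
            net = network_from_matrices(adjacency, weights)

            assert np.allclose(
                node_strength(net), strength_bruteforce(net.weighted_adjacency),
                atol=1e-12,
            )
            assert np.allclose(
                weighted_clustering(net),
                clustering_bruteforce(adjacency, net.weighted_adjacency),
                atol=1e-9,
            )
            dm = distance_matrix(net, 1)
            sp = shortest_paths(dm)
            sp_ref = shortest_paths_bruteforce(dm.d)
            assert np.allclose(sp, sp_ref, atol=1e-9)
            assert np.allclose(
                betweenness(dm), betweenness_bruteforce(dm.d), atol=1e-9
            )
            checked += 1
        assert checked == self.N_GRAPHS

    def test_betweenness_matches_networkx(self):
        networkx = pytest.importorskip("networkx")
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(5, 12))
            adjacency, weights = random_test_network(rng, n)
            net = network_from_matrices(adjacency, weights)
            dm = distance_matrix(net, 1)
            g = networkx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if np.isfinite(dm.d[i, j]):
                        g.add_edge(i, j, weight=dm.d[i, j])
            ref = networkx.betweenness_centrality(
                g, weight="weight", normalized=False
            )
            mine = betweenness(dm)
            assert np.allclose(mine, [ref[i] for i in range(n)], atol=1e-9)
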