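import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import panelnet as pn
from panelnet.centrality import (betweenness, closeness, compute_centrality,
                                 expected_influence, shortest_paths, standardize,
                                 strength)
from conftest import random_edge_matrix
from enumeration import brute_betweenness, brute_closeness, brute_shortest


class TestStrengthAndEI:
    def test_toy_strength(self, toy3_W):
        np.testing.assert_allclose(strength(toy3_W), [0.75, 0.5, 0.25])

    def test_empty_network(self):
        np.testing.assert_array_equal(strength(np.zeros((5, 5))), np.zeros(5))
        np.testing.assert_array_equal(expected_influence(np.zeros((5, 5))), np.zeros(5))

    def test_all_positive_ei_equals_strength(self):
        rng = np.random.default_rng(0)
        W = random_edge_matrix(rng, 9, signed=False)
        np.testing.assert_array_equal(expected_influence(W), strength(W))

    def test_mixed_sign_example(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = -0.25
        assert expected_influence(W)[0] == pytest.approx(0.25)
        assert strength(W)[0] == pytest.approx(0.75)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_strength_dominates_abs_ei(self, seed):
        rng = np.random.default_rng(seed)
        W = random_edge_matrix(rng, 7)
        s, ei = strength(W), expected_influence(W)
        assert np.all(s >= np.abs(ei) - 1e-12)
        # brute-force summation oracle
        np.testing.assert_allclose(s, [np.abs(W[i]).sum() for i in range(7)])
        np.testing.assert_allclose(ei, [W[i].sum() for i in range(7)])


class TestShortestPaths:
    def test_toy_detour_through_hub(self, toy3_W):
        paths = shortest_paths(toy3_W)
        assert paths.d[1, 2] == pytest.approx(1 / 0.5 + 1 / 0.25)  # B-A-C = 6
        assert paths.sigma[1, 2] == 1
        assert paths.sigma_through(0)[1, 2] == 1

    def test_four_cycle_two_shortest_paths(self):
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            W[i, j] = W[j, i] = 0.5
        paths = shortest_paths(W)
        assert paths.sigma[0, 2] == 2
        assert paths.d[0, 2] == pytest.approx(4.0)

    def test_disconnected_pair(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        paths = shortest_paths(W)
        assert np.isinf(paths.d[0, 2])
        assert paths.sigma[0, 2] == 0

    def test_sigma_through_bounded_by_sigma(self):
        rng = np.random.default_rng(3)
        W = random_edge_matrix(rng, 7)
        paths = shortest_paths(W)
        for i in range(7):
            thr = paths.sigma_through(i)
            assert np.all(thr <= paths.sigma + 1e-12)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            W = random_edge_matrix(rng, 6, density=0.5)
            d_brute, _ = brute_shortest(W)
            paths = shortest_paths(W)
            np.testing.assert_allclose(paths.d, d_brute, rtol=1e-9)


class TestClosenessBetweenness:
    def test_toy_values(self, toy3_W):
        paths = shortest_paths(toy3_W)
        np.testing.assert_allclose(closeness(paths), [1 / 6, 1 / 8, 1 / 10])
        np.testing.assert_allclose(betweenness(paths), [1.0, 0.0, 0.0])

    def test_isolated_node_closeness_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        c = closeness(shortest_paths(W))
        assert c[2] == 0.0 and c[0] == 0.0  # node 0 cannot reach node 2 either

    def test_triangle_betweenness_zero(self):
        W = np.full((3, 3), 0.5)
        np.fill_diagonal(W, 0.0)
        np.testing.assert_array_equal(betweenness(shortest_paths(W)), np.zeros(3))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        W = random_edge_matrix(rng, 6, density=0.7)
        c1 = closeness(shortest_paths(W))
        c2 = closeness(shortest_paths(2.0 * W))
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-10)
        t1 = compute_centrality(W).table
        t2 = compute_centrality(2.0 * W).table
        np.testing.assert_allclose(t1["closeness_z"], t2["closeness_z"], atol=1e-10)

    @pytest.mark.parametrize("seed", range(12))
    def test_enumeration_oracle(self, seed):
        """Closeness and betweenness agree exactly with exhaustive simple-path
        enumeration on random networks of up to 7 nodes."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 8))
        W = random_edge_matrix(rng, n, density=float(rng.uniform(0.3, 0.9)))
        paths = shortest_paths(W)
        np.testing.assert_allclose(closeness(paths), brute_closeness(W), rtol=1e-9)
        np.testing.assert_allclose(betweenness(paths), brute_betweenness(W), rtol=1e-9)


class TestStandardize:
    def test_simple_zscore(self):
        table = compute_centrality(np.zeros((3, 3)))
        table.table["strength"] = [1.0, 2.0, 3.0]
        out = standardize(table)
        np.testing.assert_allclose(out.table["strength_z"], [-1.0, 0.0, 1.0])

    def test_constant_maps_to_zero(self):
        table = compute_centrality(np.zeros((4, 4)))
        out = standardize(table)
        assert np.all(out.table.filter(like="_z") == 0.0)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        W = random_edge_matrix(rng, 9)
        t = compute_centrality(W).table
        for name in ["strength", "expected_influence", "closeness", "betweenness"]:
            z = t[f"{name}_z"].to_numpy()
            if np.std(t[name]) > 0:
                assert abs(z.mean()) < 1e-12
                assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        W = random_edge_matrix(rng, 9)
        perm = rng.permutation(9)
        t1 = compute_centrality(W).table
        t2 = compute_centrality(W[np.ix_(perm, perm)]).table
        for name in ["strength", "expected_influence", "closeness", "betweenness"]:
            np.testing.assert_allclose(t1[name].to_numpy()[perm], t2[name].to_numpy(),
                                       rtol=1e-10)
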