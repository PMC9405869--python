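"""Graph-parameter correctness: toy values, oracle equivalence, invariants."""

import numpy as np
import pytest

from funconn.connectivity import WeightedNetwork
from funconn.metrics import (
    NullEnsembleConfig,
    degree_centrality,
    global_efficiency,
    local_efficiency,
    modularity,
    modularity_value,
    nodal_efficiency,
    rewired_null,
    shortest_path_distances,
    small_worldness,
    weighted_clustering,
)
from oracles import (
    brute_clustering,
    brute_distances,
    brute_global_efficiency,
    brute_local_efficiency,
    brute_max_modularity,
    brute_modularity_value,
    random_weighted_graph,
)


def star(n=5):
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    return WeightedNetwork(w)


class TestDistances:
    def test_triangle_unit_weights(self):
        w = np.ones((3, 3)) - np.eye(3)
        d = shortest_path_distances(WeightedNetwork(w))
        assert np.allclose(d[~np.eye(3, dtype=bool)], 1.0)

    def test_inverse_weight_lengths_add_along_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        d = shortest_path_distances(WeightedNetwork(w))
        assert d[0, 2] == pytest.approx(4.0)

    def test_disconnected_dyads_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        d = shortest_path_distances(WeightedNetwork(w))
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])


class TestEfficiencies:
    def test_complete_graph_global_efficiency_one(self, k4):
        assert global_efficiency(k4) == pytest.approx(1.0)

    def test_edgeless_graph_zero(self):
        assert global_efficiency(WeightedNetwork(np.zeros((5, 5)))) == 0.0

    def test_unit_path3_global_efficiency(self, unit_path3):
        assert global_efficiency(unit_path3) == pytest.approx(5 / 6)

    def test_star_centre_nodal_efficiency_one(self):
        assert nodal_efficiency(star(), 0) == pytest.approx(1.0)

    def test_isolated_node_nodal_efficiency_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        assert nodal_efficiency(WeightedNetwork(w), 2) == 0.0

    def test_path_end_nodal_efficiency(self, unit_path3):
        assert nodal_efficiency(unit_path3, 0) == pytest.approx(0.75)

    def test_k4_local_efficiency_one(self, k4):
        for node in range(4):
            assert local_efficiency(k4, node) == pytest.approx(1.0)

    def test_star_centre_local_efficiency_zero(self):
        assert local_efficiency(star(), 0) == 0.0

    def test_local_efficiency_of_path_neighbourhood(self):
        # node 0 adjacent to 1,2,3; neighbours form a unit path 1-2-3
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (2, 3)]:
            w[i, j] = w[j, i] = 1.0
        assert local_efficiency(WeightedNetwork(w), 0) == pytest.approx(5 / 6)


class TestDegreeAndClustering:
    def test_strength_is_sum_of_incident_weights(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.25
        assert degree_centrality(WeightedNetwork(w))[0] == pytest.approx(0.75)

    def test_k4_strengths(self, k4):
        assert np.allclose(degree_centrality(k4), 3.0)

    def test_unit_triangle_clustering_one(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert np.allclose(weighted_clustering(WeightedNetwork(w)), 1.0)

    def test_star_centre_clustering_zero(self):
        assert weighted_clustering(star())[0] == 0.0

    def test_geometric_mean_triangle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.125
        # node 0 joins the two unit edges: C = (1 * 1 * 0.125)^(1/3) = 0.5
        assert weighted_clustering(WeightedNetwork(w))[0] == pytest.approx(0.5)


class TestModularity:
    def test_two_cliques_component_partition(self, two_cliques):
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert modularity_value(two_cliques, labels) == pytest.approx(0.5)
        q, part = modularity(two_cliques, seed=3)
        assert q == pytest.approx(0.5)
        assert len(np.unique(part)) == 2

    def test_single_community_q_zero_on_complete_graph(self, k4):
        assert modularity_value(k4, np.zeros(4, dtype=int)) == pytest.approx(0.0)

    def test_optimizer_beats_trivial_partition(self, rng):
        w = random_weighted_graph(rng, 7)
        if not np.any(w):
            pytest.skip("empty draw")
        q, _ = modularity(WeightedNetwork(w), seed=0)
        assert q >= modularity_value(w, np.zeros(7, dtype=int)) - 1e-12

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            modularity(WeightedNetwork(np.zeros((4, 4))), seed=0)

    def test_deterministic_given_seed(self, rng):
        w = random_weighted_graph(rng, 7)
        q1, p1 = modularity(WeightedNetwork(w), seed=42)
        q2, p2 = modularity(WeightedNetwork(w), seed=42)
        assert q1 == q2 and np.array_equal(p1, p2)


class TestOracleEquivalence:
    """Cross-check every metric against shared-nothing brute force on small graphs."""

    @pytest.mark.parametrize("seed", range(25))
    def test_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(3, 8))
        w = random_weighted_graph(rng, n)
        net = WeightedNetwork(w)
        assert np.allclose(shortest_path_distances(net), brute_distances(w), atol=1e-9)
        assert global_efficiency(net) == pytest.approx(brute_global_efficiency(w), abs=1e-9)
        for node in range(n):
            assert local_efficiency(net, node) == pytest.approx(
                brute_local_efficiency(w, node), abs=1e-9
            )
        assert np.allclose(weighted_clustering(net), brute_clustering(w), atol=1e-9)
        if np.any(w):
            labels = rng.integers(0, 3, size=n)
            assert modularity_value(net, labels) == pytest.approx(
                brute_modularity_value(w, labels), abs=1e-12
            )
            q, _ = modularity(net, seed=seed)
            assert q <= brute_max_modularity(w) + 1e-12


class TestRewiredNulls:
    def test_preserves_degree_sequence_and_weight_multiset(self, rng):
        w = random_weighted_graph(rng, 10, p_edge=0.4)
        net = WeightedNetwork(w)
        cfg = NullEnsembleConfig(n_random=5, n_swaps_per_edge=10, seed=5)
        for null in rewired_null(net, cfg):
            assert np.array_equal(
                (null.weights > 0).sum(axis=1), (net.weights > 0).sum(axis=1)
            )
            assert np.allclose(
                np.sort(null.edge_list()[2]), np.sort(net.edge_list()[2])
            )
            assert null.weights.sum() == pytest.approx(net.weights.sum())

    def test_complete_graph_is_rigid(self, k4):
        cfg = NullEnsembleConfig(n_random=3, n_swaps_per_edge=20, seed=1)
        for null in rewired_null(k4, cfg):
            assert np.allclose(null.weights, k4.weights)

    def test_deterministic_given_seed(self, rng):
        w = random_weighted_graph(rng, 10, p_edge=0.4)
        net = WeightedNetwork(w)
        cfg = NullEnsembleConfig(n_random=2, n_swaps_per_edge=10, seed=9)
        a = rewired_null(net, cfg)
        b = rewired_null(net, cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.weights, y.weights)

    def test_too_small_graph_warns_and_copies(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        cfg = NullEnsembleConfig(n_random=2, n_swaps_per_edge=5, seed=0)
        with pytest.warns(UserWarning, match="too small"):
            nulls = rewired_null(WeightedNetwork(w), cfg)
        assert all(np.array_equal(nu.weights, w) for nu in nulls)


def ring_lattice(n=30, k=3, rewire_frac=0.1, seed=0):
    """Watts–Strogatz-style weighted ring: dense local cliques, few shortcuts."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    for i in range(n):
        for off in range(1, k + 1):
            j = (i + off) % n
            w[i, j] = w[j, i] = rng.uniform(0.5, 1.0)
    n_rewire = int(rewire_frac * n * k)
    for _ in range(n_rewire):
        i, j = rng.integers(0, n, size=2)
        if i != j and w[i, j] == 0:
            w[i, j] = w[j, i] = rng.uniform(0.5, 1.0)
    return WeightedNetwork(w)


class TestSmallWorldness:
    def test_complete_graph_sigma_exactly_one(self):
        net = WeightedNetwork(np.ones((6, 6)) - np.eye(6))
        cfg = NullEnsembleConfig(n_random=4, n_swaps_per_edge=10, seed=2)
        assert small_worldness(net, cfg) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_ring_lattice_is_small_world(self, seed):
        net = ring_lattice(seed=seed)
        cfg = NullEnsembleConfig(n_random=10, n_swaps_per_edge=10, seed=seed)
        assert small_worldness(net, cfg) > 1.0

    def test_scale_invariance_under_weight_rescaling(self, rng):
        net = ring_lattice(seed=3)
        scaled = WeightedNetwork(net.weights * 7.5)
        cfg = NullEnsembleConfig(n_random=5, n_swaps_per_edge=10, seed=4)
        assert small_worldness(net, cfg) == pytest.approx(
            small_worldness(scaled, cfg), rel=1e-9
        )


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_adding_edge_never_decreases_integration(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, 7, p_edge=0.4)
        absent = [(i, j) for i in range(7) for j in range(i + 1, 7) if w[i, j] == 0]
        if not absent:
            pytest.skip("graph already complete")
        i, j = absent[rng.integers(len(absent))]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = rng.uniform(0.1, 1.0)
        assert global_efficiency(WeightedNetwork(w2)) >= global_efficiency(WeightedNetwork(w)) - 1e-12
        assert np.all(
            degree_centrality(WeightedNetwork(w2)) >= degree_centrality(WeightedNetwork(w)) - 1e-12
        )
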