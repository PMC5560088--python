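"""Graph-topology battery vs independent oracles (networkx / igraph / brute force)."""

import igraph as ig
import networkx as nx
import numpy as np
import pytest

import contranet as cn
from contranet import network as net
from contranet.connectivity import ConnectivityMatrix

from conftest import random_weighted_graph


# ---------------------------------------------------------------------------
# independent oracles (naive, library-based — no shared code with the package)


def oracle_global_efficiency(w):
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, length=1.0 / w[i, j])
    acc = 0.0
    for i in range(n):
        d = nx.single_source_dijkstra_path_length(g, i, weight="length")
        for j, dij in d.items():
            if j != i:
                acc += 1.0 / dij
    return acc / (n * (n - 1))


def oracle_local_efficiency(w):
    n = w.shape[0]
    total = 0.0
    for u in range(n):
        nbrs = [v for v in range(n) if w[u, v] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        g = nx.Graph()
        g.add_nodes_from(nbrs)
        for a in nbrs:
            for b in nbrs:
                if a < b and w[a, b] > 0:
                    g.add_edge(a, b, length=(1.0 / w[a, b]) ** (1 / 3))
        acc = 0.0
        for a in nbrs:
            d = nx.single_source_dijkstra_path_length(g, a, weight="length")
            for b in nbrs:
                if b != a and b in d and d[b] > 0:
                    acc += (w[u, a] * w[u, b]) ** (1 / 3) / d[b]
        total += acc / (k * (k - 1))
    return total / n


def make_matrix(z, names=None):
    z = np.asarray(z, dtype=float)
    names = names or [f"R{i}" for i in range(z.shape[0])]
    return ConnectivityMatrix(z, names)


# ---------------------------------------------------------------------------


class TestProportionalThreshold:
    def test_45_rois_10_percent_keeps_99_edges(self, rng):
        z = np.abs(rng.normal(0.3, 0.2, (45, 45)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        g = net.proportional_threshold(make_matrix(z), 0.10)
        assert g.n_edges == 99

    def test_full_sparsity_keeps_all_positives(self, rng):
        z = rng.normal(0.0, 0.3, (10, 10))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        g = net.proportional_threshold(make_matrix(z), 1.0)
        expected = np.where(z > 0, z, 0.0)
        np.testing.assert_allclose(g.weights, expected)

    def test_fewer_positives_than_requested(self):
        z = np.zeros((6, 6))
        for k, (i, j) in enumerate([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5)]):
            z[i, j] = z[j, i] = 0.1 * (k + 1)
        g = net.proportional_threshold(make_matrix(z), 0.9)  # asks for 14
        assert g.n_edges == 5

    def test_retained_weights_keep_values(self, rng):
        z = np.abs(rng.normal(0.5, 0.1, (8, 8)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        g = net.proportional_threshold(make_matrix(z), 0.3)
        kept = g.weights > 0
        np.testing.assert_allclose(g.weights[kept], z[kept])


class TestEfficiency:
    def test_complete_unit_graph_global_one(self):
        w = np.ones((6, 6)) - np.eye(6)
        assert cn.global_efficiency(cn.WeightedGraph(w, list("abcdef"))) == 1.0

    def test_isolated_nodes_global_zero(self):
        g = cn.WeightedGraph(np.zeros((2, 2)), ["a", "b"])
        assert cn.global_efficiency(g) == 0.0

    def test_weighted_path_graph_matches_oracle(self):
        w = np.zeros((5, 5))
        for i, wt in enumerate([0.5, 2.0, 0.25, 1.0]):
            w[i, i + 1] = w[i + 1, i] = wt
        g = cn.WeightedGraph(w, [f"N{i}" for i in range(5)])
        assert cn.global_efficiency(g) == pytest.approx(
            oracle_global_efficiency(w), abs=1e-12
        )

    def test_triangle_local_efficiency_one(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert cn.local_efficiency(cn.WeightedGraph(w, list("abc"))) == pytest.approx(1.0)

    def test_star_local_efficiency_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = 1.0
        w = w + w.T
        assert cn.local_efficiency(cn.WeightedGraph(w, list("abcde"))) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        g = random_weighted_graph(rng, rng.integers(4, 9), density=rng.uniform(0.3, 0.9))
        assert cn.global_efficiency(g) == pytest.approx(
            oracle_global_efficiency(g.weights), abs=1e-12
        )
        assert cn.local_efficiency(g) == pytest.approx(
            oracle_local_efficiency(g.weights), abs=1e-12
        )

    def test_global_efficiency_monotone_in_sparsity(self, rng):
        """Adding edges can only shorten shortest paths."""
        z = rng.normal(0.3, 0.3, (20, 20))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        mat = make_matrix(z)
        effs = [cn.global_efficiency(net.proportional_threshold(mat, s))
                for s in net.DEFAULT_SPARSITY_GRID]
        assert np.all(np.diff(effs) >= -1e-12)


class TestRewiredNulls:
    def test_weight_multiset_and_degrees_preserved(self, rng):
        g = random_weighted_graph(rng, 20, density=0.3)
        nulls = cn.rewired_nulls(g, n_nulls=20, seed=3)
        for null in nulls:
            np.testing.assert_allclose(
                np.sort(null.edge_list()[1]), np.sort(g.edge_list()[1]), atol=0
            )
            np.testing.assert_array_equal(null.degrees(), g.degrees())

    def test_topology_actually_changes(self, rng):
        g = random_weighted_graph(rng, 20, density=0.3)
        nulls = cn.rewired_nulls(g, n_nulls=5, seed=1)
        assert any(
            not np.array_equal(n.weights > 0, g.weights > 0) for n in nulls
        )

    def test_reproducible_given_seed(self, rng):
        g = random_weighted_graph(rng, 12, density=0.4)
        n1 = cn.rewired_nulls(g, n_nulls=3, seed=9)
        n2 = cn.rewired_nulls(g, n_nulls=3, seed=9)
        for a, b in zip(n1, n2):
            np.testing.assert_array_equal(a.weights, b.weights)

    def test_null_modularity_below_planted(self, rng):
        """Rewiring destroys planted modular structure."""
        z = np.where(
            np.repeat([0, 1, 2], 5)[:, None] == np.repeat([0, 1, 2], 5)[None, :],
            0.8, 0.1,
        ) + rng.normal(0, 0.01, (15, 15))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        g = net.proportional_threshold(make_matrix(z), 0.4)
        obs = cn.modularity_partition(g, n_runs=10, seed=0).q
        null_q = [
            cn.modularity_partition(n, n_runs=10, seed=0).q
            for n in cn.rewired_nulls(g, n_nulls=10, seed=2)
        ]
        assert np.mean(null_q) < obs


class TestNormalizedEfficiency:
    def test_self_reference_gives_one(self, rng):
        g = random_weighted_graph(rng, 10, density=0.5)
        gn, ln = cn.normalized_efficiency(g, [g, g, g])
        assert gn == pytest.approx(1.0) and ln == pytest.approx(1.0)

    def test_lattice_local_norm_above_one(self):
        # ring lattice with neighbours at distance 1 and 2: highly clustered
        n = 20
        w = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                w[i, (i + d) % n] = w[(i + d) % n, i] = 1.0
        g = cn.WeightedGraph(w, [f"N{i}" for i in range(n)])
        _, ln = cn.normalized_efficiency(g, cn.rewired_nulls(g, 30, seed=4))
        assert ln > 1.0

    def test_random_graph_ratios_near_one(self, rng):
        g = random_weighted_graph(rng, 25, density=0.4)
        # weights shuffled to break any weight-topology coupling
        gn, ln = cn.normalized_efficiency(g, cn.rewired_nulls(g, 50, seed=5))
        assert abs(gn - 1.0) < 0.1
        assert abs(ln - 1.0) < 0.25


class TestModularity:
    def test_two_disconnected_cliques_q_half(self):
        w = np.zeros((8, 8))
        for blk in (range(4), range(4, 8)):
            for i in blk:
                for j in blk:
                    if i != j:
                        w[i, j] = 1.0
        g = cn.WeightedGraph(w, [f"N{i}" for i in range(8)])
        res = cn.modularity_partition(g, n_runs=5, seed=0)
        assert res.q == pytest.approx(0.5, abs=1e-12)
        assert len(np.unique(res.assignment)) == 2

    def test_complete_graph_q_zero(self):
        w = np.ones((6, 6)) - np.eye(6)
        g = cn.WeightedGraph(w, list("abcdef"))
        res = cn.modularity_partition(g, n_runs=5, seed=1)
        assert res.q == pytest.approx(0.0, abs=1e-12)

    def test_q_formula_matches_igraph(self, rng):
        g = random_weighted_graph(rng, 12, density=0.5)
        assignment = rng.integers(0, 3, 12)
        edges, weights = g.edge_list()
        graph = ig.Graph(n=12, edges=[tuple(e) for e in edges])
        expected = graph.modularity(assignment.tolist(), weights=weights.tolist())
        assert cn.modularity_q(g.weights, assignment) == pytest.approx(
            expected, abs=1e-12
        )

    def test_planted_three_module_recovery(self):
        """Partition recovery on strongly modular planted graphs."""
        from sklearn.metrics import adjusted_rand_score

        recovered = 0
        planted = np.repeat([0, 1, 2], 10)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = np.where(planted[:, None] == planted[None, :], 0.6, 0.1)
            z = z + rng.normal(0, 0.02, (30, 30))
            z = (z + z.T) / 2
            np.fill_diagonal(z, 0)
            g = net.proportional_threshold(make_matrix(z), 0.3)
            res = cn.modularity_partition(g, n_runs=10, seed=seed)
            if adjusted_rand_score(planted, res.assignment) == 1.0:
                recovered += 1
        assert recovered >= 9

    def test_q_at_least_trivial_partition(self, rng):
        g = random_weighted_graph(rng, 15, density=0.3)
        res = cn.modularity_partition(g, n_runs=5, seed=2)
        trivial = cn.modularity_q(g.weights, np.zeros(15, dtype=int))
        assert res.q >= trivial
        assert trivial <= 1e-12

    def test_edgeless_graph_rejected(self):
        g = cn.WeightedGraph(np.zeros((4, 4)), list("abcd"))
        with pytest.raises(ValueError):
            cn.modularity_partition(g)


class TestIntraInterConnectivity:
    def _two_module_graph(self, w_in=0.8, w_out=0.4):
        # 4 nodes, 2 modules; equal counts of within and between edges
        w = np.zeros((4, 4))
        w[0, 1] = w[2, 3] = w_in
        w[0, 2] = w[1, 3] = w_out
        w = w + w.T
        return cn.WeightedGraph(w, list("abcd")), np.array([0, 0, 1, 1])

    def test_equal_weights_give_unit_metrics(self):
        g, part = self._two_module_graph(0.5, 0.5)
        intra, inter, ratio = cn.intra_inter_connectivity(g, part)
        assert intra == pytest.approx(1.0)
        assert inter == pytest.approx(1.0)
        assert ratio == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        g, part = self._two_module_graph(0.8, 0.4)
        intra, inter, ratio = cn.intra_inter_connectivity(g, part)
        assert intra == pytest.approx(0.8 / 0.6)
        assert inter == pytest.approx(0.4 / 0.6)
        assert ratio == pytest.approx(2.0)

    def test_scale_invariance(self, rng):
        g = random_weighted_graph(rng, 10, density=0.6)
        part = rng.integers(0, 2, 10)
        a = cn.intra_inter_connectivity(g, part)
        g2 = cn.WeightedGraph(g.weights * 7.3, g.node_names)
        b = cn.intra_inter_connectivity(g2, part)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_no_between_module_edges_errors(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        g = cn.WeightedGraph(w, list("abcd"))
        with pytest.raises(ValueError, match="between-module"):
            cn.intra_inter_connectivity(g, np.array([0, 0, 1, 1]))

    def test_per_module_variant_on_balanced_graph(self):
        g, part = self._two_module_graph(0.8, 0.4)
        pooled = cn.intra_inter_connectivity(g, part, per_module=False)
        permod = cn.intra_inter_connectivity(g, part, per_module=True)
        np.testing.assert_allclose(pooled, permod)  # equal-weight modules agree


@pytest.fixture(scope="module")
def example_matrix():
    rng = np.random.default_rng(99)
    planted = np.repeat([0, 1, 2], 5)
    z = np.where(planted[:, None] == planted[None, :], 0.5, 0.2)
    z = z + rng.normal(0, 0.05, (15, 15))
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0)
    return make_matrix(z)


class TestMetricProfile:

    def test_default_grid_has_nine_levels(self, example_matrix):
        prof = cn.metric_profile(example_matrix, n_nulls=10, n_runs=3, seed=0)
        assert len(prof.per_level) == 9
        np.testing.assert_allclose(
            prof.per_level.index.to_numpy(), np.arange(0.10, 0.501, 0.05), atol=1e-9
        )

    def test_single_level_integration_identity(self, example_matrix):
        prof = cn.metric_profile(example_matrix, grid=[0.4], n_nulls=10,
                                 n_runs=3, seed=1)
        for name in net.METRIC_NAMES:
            assert prof.integrated[name] == pytest.approx(
                prof.per_level[name].iloc[0]
            )

    def test_ratio_consistency_per_level(self, example_matrix):
        prof = cn.metric_profile(example_matrix, n_nulls=10, n_runs=3, seed=2)
        lv = prof.per_level.dropna()
        np.testing.assert_allclose(
            lv["intra_inter_ratio"],
            lv["intramodular_norm"] / lv["intermodular_norm"],
            atol=1e-10,
        )

    def test_deterministic_given_seed(self, example_matrix):
        p1 = cn.metric_profile(example_matrix, n_nulls=10, n_runs=3, seed=7)
        p2 = cn.metric_profile(example_matrix, n_nulls=10, n_runs=3, seed=7)
        assert p1.per_level.equals(p2.per_level)
        assert p1.integrated == p2.integrated
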