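import numpy as np
import networkx as nx
import pytest

import oracles
from cerenet.metrics import (
    MetricSettings,
    betweenness,
    characteristic_path_length,
    clustering,
    global_efficiency,
    local_efficiency,
    metrics_over_ensemble,
    nodal_degree,
    nodal_efficiency,
    random_rewire,
    shortest_paths,
    small_world,
)
from cerenet.network import BinaryGraphEnsemble, binarize_ensemble


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


K4 = adj_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
PATH3 = adj_from_edges(3, [(0, 1), (1, 2)])
STAR5 = adj_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])


class TestElementaryGraphs:
    def test_degrees(self):
        assert (nodal_degree(K4) == 3).all()
        assert (nodal_degree(np.zeros((5, 5), dtype=int)) == 0).all()
        assert nodal_degree(PATH3).tolist() == [1, 2, 1]

    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            nodal_degree(a)

    def test_clustering(self):
        tri = adj_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        cc, cp = clustering(tri)
        assert (cc == 1).all() and cp == 1
        cc, _ = clustering(STAR5)
        assert (cc == 0).all()
        k4_minus = adj_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2),
                                      (1, 3)])
        cc, _ = clustering(k4_minus)
        np.testing.assert_allclose(cc,
                                   oracles.clustering_bruteforce(k4_minus))

    def test_path_lengths(self):
        d = shortest_paths(PATH3)
        assert d[0, 2] == 2
        lp, flag, frac = characteristic_path_length(d)
        assert lp == pytest.approx(4 / 3)
        assert not flag and frac == 0
        lp_k4, _, _ = characteristic_path_length(shortest_paths(K4))
        assert lp_k4 == 1.0

    def test_disconnected_pairs_infinite(self):
        two_dyads = adj_from_edges(4, [(0, 1), (2, 3)])
        d = shortest_paths(two_dyads)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])
        lp, flag, frac = characteristic_path_length(d)
        assert flag and frac == pytest.approx(8 / 12)
        empty = np.zeros((3, 3), dtype=int)
        lp, flag, _ = characteristic_path_length(shortest_paths(empty))
        assert np.isnan(lp) and flag

    def test_efficiencies(self):
        assert global_efficiency(shortest_paths(K4)) == 1.0
        assert global_efficiency(shortest_paths(PATH3)) == \
            pytest.approx((1 + 1 + 0.5) / 3)
        nle, _ = local_efficiency(STAR5)
        assert nle[0] == 0.0          # hub neighbors form an empty graph

    def test_betweenness(self):
        raw, norm = betweenness(K4)
        assert (raw == 0).all()
        raw, _ = betweenness(PATH3)
        assert raw.tolist() == [0, 1, 0]
        raw, norm = betweenness(STAR5)
        assert raw[0] == 6.0          # C(4,2) pairs through the hub
        assert norm[0] == 1.0
        assert (raw[1:] == 0).all()   # leaves never intermediate


class TestOracleAgreementOnRandomGraphs:
    @pytest.mark.parametrize("seed", range(8))
    def test_distances_match_floyd_warshall(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((7, 7)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        np.testing.assert_array_equal(shortest_paths(a),
                                      oracles.floyd_warshall(a))

    @pytest.mark.parametrize("seed", range(5))
    def test_betweenness_matches_networkx(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = (rng.random((10, 10)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        raw, _ = betweenness(a)
        ref = nx.betweenness_centrality(nx.from_numpy_array(a),
                                        normalized=False)
        np.testing.assert_allclose(raw, [ref[v] for v in range(10)],
                                   atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_efficiency_matches_networkx(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = (rng.random((9, 9)) < 0.35).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        g = nx.from_numpy_array(a)
        assert global_efficiency(shortest_paths(a)) == pytest.approx(
            nx.global_efficiency(g))
        _, eloc = local_efficiency(a)
        assert eloc == pytest.approx(nx.local_efficiency(g))
        cc, cp = clustering(a)
        assert cp == pytest.approx(nx.average_clustering(g))


class TestPermutationEquivariance:
    @pytest.mark.parametrize("seed", range(4))
    def test_relabeling_permutes_nodal_and_fixes_global(self, seed):
        rng = np.random.default_rng(300 + seed)
        a = (rng.random((8, 8)) < 0.4).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        perm = rng.permutation(8)
        ap = a[np.ix_(perm, perm)]
        np.testing.assert_array_equal(nodal_degree(ap),
                                      nodal_degree(a)[perm])
        raw, _ = betweenness(a)
        raw_p, _ = betweenness(ap)
        np.testing.assert_allclose(raw_p, raw[perm], atol=1e-9)
        assert global_efficiency(shortest_paths(ap)) == pytest.approx(
            global_efficiency(shortest_paths(a)))


class TestRandomRewire:
    def test_degree_sequence_preserved(self, rng):
        for _ in range(20):
            a = (rng.random((10, 10)) < 0.35).astype(int)
            a = np.triu(a, 1)
            a = a + a.T
            if a.sum() < 4:
                continue
            b = random_rewire(a, seed=int(rng.integers(1 << 31)))
            np.testing.assert_array_equal(b.sum(axis=1), a.sum(axis=1))
            assert np.array_equal(b, b.T) and not np.diag(b).any()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        a = (rng.random((12, 12)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        np.testing.assert_array_equal(random_rewire(a, seed=42),
                                      random_rewire(a, seed=42))

    def test_triangle_has_no_valid_swap(self):
        tri = adj_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        with pytest.warns(RuntimeWarning, match="no valid"):
            out = random_rewire(tri, n_swaps=5)
        np.testing.assert_array_equal(out, tri)


class TestSmallWorld:
    def test_self_normalization_is_unity(self):
        rng = np.random.default_rng(3)
        a = (rng.random((12, 12)) < 0.4).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        sw = small_world(a, n_random=5, n_swaps=0, seed=0)
        assert sw["sigma"] == pytest.approx(1.0)
        assert sw["lambda"] == pytest.approx(1.0)
        assert sw["gamma"] == pytest.approx(1.0)

    def test_erdos_renyi_near_unity(self):
        g = nx.erdos_renyi_graph(60, 0.15, seed=1)
        a = nx.to_numpy_array(g).astype(int)
        sw = small_world(a, n_random=20, seed=0)
        assert abs(sw["gamma"] - 1) < max(3 * sw["cp_rand_sd"] /
                                          sw["cp_rand_mean"], 0.15)
        assert abs(sw["lambda"] - 1) < 0.1

    def test_watts_strogatz_is_small_world(self):
        g = nx.watts_strogatz_graph(60, 6, 0.1, seed=2)
        a = nx.to_numpy_array(g).astype(int)
        sw = small_world(a, n_random=20, seed=0)
        assert sw["sigma"] > 1.0
        assert sw["gamma"] > 1.0


class TestEnsembleAggregation:
    def _ensemble(self, rng, r=10):
        w = rng.normal(0.2, 1.0, size=(r, r))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        return binarize_ensemble(w)

    def test_constant_metric_auc_is_rectangle(self):
        grid = np.linspace(0.05, 0.35, 31)
        from cerenet.metrics import _grid_auc
        auc, excl = _grid_auc(grid, np.full(31, 2.5))
        assert auc == pytest.approx(2.5 * 0.3)
        assert excl == []

    def test_linear_metric_auc_closed_form(self):
        grid = np.linspace(0.05, 0.35, 31)
        from cerenet.metrics import _grid_auc
        vals = 2.0 * grid + 1.0
        auc, _ = _grid_auc(grid, vals)
        exact = (0.35 ** 2 - 0.05 ** 2) + (0.35 - 0.05)
        assert auc == pytest.approx(exact)

    def test_nan_thresholds_excluded_and_logged(self):
        grid = np.linspace(0.05, 0.35, 31)
        from cerenet.metrics import _grid_auc
        vals = np.full(31, 1.0)
        vals[0] = np.nan
        auc, excl = _grid_auc(grid, vals)
        assert auc == pytest.approx(0.35 - 0.06)
        assert excl == [0.05]

    def test_average_degree_monotone_in_sparsity(self, rng):
        ens = self._ensemble(rng)
        table = metrics_over_ensemble(
            ens, MetricSettings(compute_small_world=False))
        deg = table.global_metrics["average_degree"].to_numpy()
        assert (np.diff(deg) >= -1e-12).all()

    def test_degree_auc_scale_matches_grid_arithmetic(self, rng):
        """With plentiful positive weights, degree at sparsity s is
        2*floor(s*M)/R, so its grid AUC sits near 25 * mean(s) * width
        for a 26-node network."""
        r = 26
        w = np.abs(rng.normal(1.0, 0.3, size=(r, r)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        ens = binarize_ensemble(w)
        table = metrics_over_ensemble(
            ens, MetricSettings(compute_small_world=False))
        auc = table.auc_global["average_degree"]
        assert auc == pytest.approx(25 * 0.2 * 0.3, rel=0.02)
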