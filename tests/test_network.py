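import numpy as np
import pandas as pd
import pytest

from cerenet.atlas import RoiTemplate
from cerenet.network import (
    BinaryGraphEnsemble,
    ReferenceNetwork,
    PerturbedNetwork,
    binarize_ensemble,
    build_perturbed_network,
    build_reference_network,
    default_sparsity_grid,
    fisher_transform,
    individual_networks,
    nodal_strength_table,
    perturbation_zscore,
)
from cerenet.suvr import SuvrMatrix


def _suvr(values, roi_names=None):
    values = np.asarray(values, dtype=float)
    roi_names = roi_names or [f"r{k}" for k in range(values.shape[1])]
    template = RoiTemplate(tuple(roi_names),
                           ("cerebellar",) * len(roi_names))
    df = pd.DataFrame(values, index=[f"s{k}" for k in range(len(values))],
                      columns=roi_names)
    return SuvrMatrix(df, template)


class TestReferenceNetwork:
    def test_copied_roi_gives_perfect_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        suvr = _suvr(np.column_stack([x, x, x[::-1]]))
        ren = build_reference_network(suvr)
        assert ren.matrix[0, 1] == pytest.approx(1.0)
        assert ren.matrix[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_formula(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.3, 1.2, size=(5, 3))
        ren = build_reference_network(_suvr(vals))
        for i in range(3):
            for j in range(3):
                x, y = vals[:, i], vals[:, j]
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum())
                assert ren.matrix[i, j] == pytest.approx(num / den)

    def test_zero_variance_roi_named(self):
        vals = np.column_stack([np.ones(4), np.arange(4) + 1.0])
        with pytest.raises(ValueError, match="r0"):
            build_reference_network(_suvr(vals))

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError, match=">= 3"):
            build_reference_network(_suvr([[1.0, 2.0], [2.0, 1.0]]))


class TestPerturbedNetwork:
    def test_equals_direct_recomputation(self, rng):
        vals = rng.uniform(0.3, 1.2, size=(10, 4))
        suvr = _suvr(vals)
        row = rng.uniform(0.3, 1.2, size=4)
        cdn = build_perturbed_network(suvr, row, subject_id="new")
        oracle = np.corrcoef(np.vstack([vals, row]), rowvar=False)
        np.testing.assert_allclose(cdn.matrix, oracle, atol=1e-12)

    def test_mean_subject_shifts_little(self, rng):
        vals = rng.uniform(0.3, 1.2, size=(40, 4))
        suvr = _suvr(vals)
        ren = build_reference_network(suvr)
        cdn = build_perturbed_network(suvr, vals.mean(axis=0))
        # adding the centroid perturbs each correlation by at most the
        # leverage bound measured from the recomputation oracle itself
        delta = np.abs(cdn.matrix - ren.matrix)
        assert delta.max() < 0.05

    def test_duplicate_subject_matches_duplicated_recomputation(self, rng):
        vals = rng.uniform(0.3, 1.2, size=(8, 3))
        suvr = _suvr(vals)
        cdn = build_perturbed_network(suvr, vals[2])
        oracle = np.corrcoef(np.vstack([vals, vals[2]]), rowvar=False)
        np.testing.assert_allclose(cdn.matrix, oracle, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        suvr = _suvr(rng.uniform(0.3, 1.2, size=(5, 3)))
        with pytest.raises(ValueError, match="expected 3"):
            build_perturbed_network(suvr, np.ones(4))


class TestPerturbationZscore:
    def test_spot_value_matches_one_line_oracle(self):
        """delta=0.01 at CDN=0.6 with n=172 reference subjects."""
        n = 172
        names = ("a", "b")
        ren = ReferenceNetwork(names, np.array([[1.0, 0.59], [0.59, 1.0]]), n)
        cdn = PerturbedNetwork(names, np.array([[1.0, 0.60], [0.60, 1.0]]),
                               "s")
        net = perturbation_zscore(ren, cdn)
        oracle = 0.01 / ((1 - 0.6 ** 2) / (n - 1))
        assert round(oracle, 4) == 2.6719
        assert net.z_matrix[0, 1] == pytest.approx(oracle, abs=5e-13)

    def test_zero_delta_gives_zero_z(self):
        names = ("a", "b")
        m = np.array([[1.0, 0.4], [0.4, 1.0]])
        net = perturbation_zscore(ReferenceNetwork(names, m, 20),
                                  PerturbedNetwork(names, m.copy(), "s"))
        assert np.all(net.z_matrix == 0)

    def test_sign_preservation(self, rng):
        vals = rng.uniform(0.3, 1.2, size=(30, 6))
        suvr = _suvr(vals)
        ren = build_reference_network(suvr)
        for k in range(5):
            cdn = build_perturbed_network(suvr,
                                          rng.uniform(0.3, 1.2, size=6))
            net = perturbation_zscore(ren, cdn)
            assert np.array_equal(np.sign(net.z_matrix),
                                  np.sign(net.delta))
            assert np.allclose(np.diag(net.z_matrix), 0)

    def test_saturated_edge_clipped_with_warning(self):
        names = ("a", "b")
        ren = ReferenceNetwork(names, np.array([[1.0, 0.5], [0.5, 1.0]]), 10)
        cdn = PerturbedNetwork(names, np.array([[1.0, 1.0], [1.0, 1.0]]),
                               "s")
        with pytest.warns(RuntimeWarning, match="clipped"):
            net = perturbation_zscore(ren, cdn)
        assert np.isfinite(net.z_matrix).all()
        assert net.saturated_edges == [(0, 1)]

    def test_sqrt_denominator_variant(self):
        names = ("a", "b")
        ren = ReferenceNetwork(names, np.array([[1.0, 0.59], [0.59, 1.0]]),
                               172)
        cdn = PerturbedNetwork(names, np.array([[1.0, 0.6], [0.6, 1.0]]),
                               "s")
        net = perturbation_zscore(ren, cdn, use_sqrt_denominator=True)
        oracle = 0.01 / np.sqrt((1 - 0.36) / 171)
        assert net.z_matrix[0, 1] == pytest.approx(oracle)


class TestFisherTransform:
    def test_fixed_point_and_known_value(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert fisher_transform(m)[0, 1] == 0.0
        m2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert fisher_transform(m2)[0, 1] == pytest.approx(0.5493, abs=5e-5)

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.9, 0.9, size=(4, 4))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        np.testing.assert_allclose(fisher_transform(-r + 2 * np.eye(4)),
                                   -fisher_transform(r), atol=1e-12)

    def test_rejects_zscored_matrix(self):
        z = np.array([[0.0, 2.7], [2.7, 0.0]])
        with pytest.raises(ValueError, match="correlation-valued"):
            fisher_transform(z)


class TestBinarization:
    def test_default_grid_has_31_thresholds(self):
        assert len(default_sparsity_grid()) == 31

    def test_edge_counts_follow_floor_rule_26_rois(self, rng):
        r = 26
        w = rng.normal(0.5, 1.0, size=(r, r))   # mostly positive weights
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        ens = binarize_ensemble(w, default_sparsity_grid())
        m = r * (r - 1) // 2
        n_pos = int((w[np.triu_indices(r, 1)] > 0).sum())
        for s, count in zip(ens.sparsity_grid, ens.edge_counts()):
            assert count == min(int(np.floor(s * m)), n_pos)
        # the specific spot check: s=0.10 with enough positive weights
        k = list(ens.sparsity_grid).index(0.10)
        if n_pos >= 32:
            assert ens.edge_counts()[k] == 32

    def test_nesting_invariant(self, rng):
        for _ in range(5):
            w = rng.normal(0, 1, size=(12, 12))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            ens = binarize_ensemble(w, default_sparsity_grid())
            assert ens.check_nesting()

    def test_all_negative_weights_warn_and_empty(self):
        w = -np.ones((4, 4))
        np.fill_diagonal(w, 0)
        with pytest.warns(RuntimeWarning, match="no positive"):
            ens = binarize_ensemble(w, np.array([0.2, 0.5]))
        assert ens.adjacency_stack.sum() == 0

    def test_deterministic_tie_break(self):
        w = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (1, 3), (2, 3)]
        for i, j in pairs:
            w[i, j] = w[j, i] = 1.0       # all tied
        ens = binarize_ensemble(w, np.array([2 / 6]))   # keep floor(2/6*6)=2
        kept = {tuple(p) for p in np.argwhere(np.triu(
            ens.adjacency_stack[0]))}
        assert kept == {(0, 1), (0, 2)}   # lexicographically first

    def test_invalid_grid_rejected(self):
        w = np.zeros((3, 3))
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            binarize_ensemble(w, np.array([0.0, 0.5]))
        with pytest.raises(ValueError, match="increasing"):
            binarize_ensemble(w, np.array([0.3, 0.2]))


class TestNullSelfConsistency:
    def test_in_distribution_subject_has_zero_mean_z(self, rng):
        """Edge-wise Z over repeated in-distribution draws is centred on
        zero (standard-error-scaled check at 200 draws)."""
        n_ref, r = 60, 8
        corr = np.full((r, r), 0.5)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)
        ref = 0.6 + 0.05 * (rng.standard_normal((n_ref, r)) @ chol.T)
        suvr = _suvr(ref)
        from cerenet.network import build_reference_network
        ren = build_reference_network(suvr)
        zs = []
        for _ in range(200):
            row = 0.6 + 0.05 * (rng.standard_normal(r) @ chol.T)
            cdn = build_perturbed_network(suvr, row)
            zs.append(perturbation_zscore(ren, cdn).z_matrix)
        zs = np.array(zs)
        iu = np.triu_indices(r, 1)
        mean_z = zs[:, iu[0], iu[1]].mean()
        assert abs(mean_z) < 0.1


class TestIndividualNetworks:
    def test_cohort_wrapper_covers_all_subjects(self, fixture_cohort):
        ren, nets = individual_networks(fixture_cohort.suvr,
                                        fixture_cohort.labels, "CN")
        assert ren.n_reference == 12
        assert len(nets) == fixture_cohort.suvr.n_subjects
        table = nodal_strength_table(nets)
        assert table.shape == (48, 8)
        assert np.isfinite(table.to_numpy()).all()

    def test_missing_labels_rejected(self, fixture_cohort):
        labels = fixture_cohort.labels.iloc[:-1]
        with pytest.raises(ValueError, match="cover"):
            individual_networks(fixture_cohort.suvr, labels, "CN")
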