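"""Ridge / mixed-model / PCA predictors and their algebraic equivalences."""

import numpy as np
import pytest

from multiline_gp.datatypes import VarianceComponents
from multiline_gp.kinship import RelationshipMatrix
from multiline_gp.predictors import (
    CenterScale,
    center_scale,
    pc_sweep,
    pca_fit,
    predict_validation,
    ridge_solve,
    rrpca_solve,
    solve_mixed_model,
)
from conftest import make_genotypes


class TestCenterScale:
    def test_columns_standardized(self, rng):
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 30), size=(60, 30))
        z, _ = center_scale(make_genotypes(codes.astype(np.int8)))
        assert np.max(np.abs(z.mean(axis=0))) < 1e-10
        assert np.max(np.abs(z.var(axis=0) - 1.0)) < 1e-10

    def test_monomorphic_column_rejected(self):
        geno = make_genotypes(np.array([[2, 1], [2, 0], [2, 1]]))
        with pytest.raises(ValueError):
            center_scale(geno)

    def test_validation_uses_training_constants(self, rng):
        codes = rng.binomial(2, 0.5, size=(40, 10)).astype(np.int8)
        geno = make_genotypes(codes)
        train_ids = geno.ids[:30]
        z_train, transform = center_scale(geno, reference_ids=train_ids)
        z_val = transform.apply(geno.subset(ids=geno.ids[30:]))
        expect = (codes[30:] - codes[:30].mean(axis=0)) / codes[:30].std(axis=0)
        assert np.allclose(z_val, expect)
        # validation columns generally NOT centred in their own moments
        assert np.max(np.abs(z_val.mean(axis=0))) > 1e-6


class TestRidgeSolve:
    def test_alpha_zero_equals_ols(self, rng):
        z = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        w = ridge_solve(z, y, 0.0).weights
        w_ols, *_ = np.linalg.lstsq(z, y - y.mean(), rcond=None)
        assert np.allclose(w, w_ols, atol=1e-8)

    def test_total_shrinkage_at_huge_alpha(self, rng):
        z = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        w_big = ridge_solve(z, y, 1e12).weights
        w_one = ridge_solve(z, y, 1.0).weights
        assert np.linalg.norm(w_big) < 1e-6 * np.linalg.norm(w_one)

    def test_two_snp_hand_inversion(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 2.0, 3.0])
        alpha = 0.5
        yc = y - y.mean()
        lhs = z.T @ z + alpha * np.eye(2)
        # 2x2 inverse by hand: [[2.5, 1], [1, 2.5]]
        det = 2.5 * 2.5 - 1.0
        inv = np.array([[2.5, -1.0], [-1.0, 2.5]]) / det
        expect = inv @ (z.T @ yc)
        got = ridge_solve(z, y, alpha).weights
        assert np.allclose(got, expect, atol=1e-12)

    def test_primal_and_dual_agree(self, rng):
        z = rng.normal(size=(20, 50))  # p > n exercises the dual path
        y = rng.normal(size=20)
        w_dual = ridge_solve(z, y, 2.0).weights
        lhs = z.T @ z + 2.0 * np.eye(50)
        w_primal = np.linalg.solve(lhs, z.T @ (y - y.mean()))
        assert np.allclose(w_dual, w_primal, atol=1e-8)

    def test_shrinkage_monotonic_in_alpha(self, rng):
        z = rng.normal(size=(50, 30))
        y = rng.normal(size=50)
        norms = [np.linalg.norm(ridge_solve(z, y, a).weights)
                 for a in (0.01, 0.1, 1.0, 10.0, 100.0)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_singular_system_at_alpha_zero_rejected(self):
        z = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(np.linalg.LinAlgError):
            ridge_solve(z, np.array([1.0, 2.0, 3.0]), 0.0)


class TestMixedModel:
    def ids(self, n):
        return np.array([f"i{k}" for k in range(n)], dtype=object)

    def test_identity_kinship_closed_form(self, rng):
        n, nv = 20, 5
        ids = self.ids(n + nv)
        k = RelationshipMatrix(ids, np.eye(n + nv), "G_vanraden")
        y = rng.normal(5.0, 1.0, n)
        vc = VarianceComponents(genetic=2.0, residual=3.0)
        ebv = solve_mixed_model(k, y, ids[:n], ids[n:], vc, ridge=0.0)
        expect = (2.0 / 5.0) * (y - y.mean())
        assert np.allclose(ebv.aligned_to(ids[:n]), expect, atol=1e-10)
        assert np.allclose(ebv.aligned_to(ids[n:]), 0.0)

    def test_infinite_shrinkage_sends_ebv_to_zero(self, rng):
        n = 15
        ids = self.ids(n)
        k = RelationshipMatrix(ids, np.eye(n), "G_vanraden")
        y = rng.normal(size=10)
        vc = VarianceComponents(genetic=1e-10, residual=1.0)
        ebv = solve_mixed_model(k, y, ids[:10], ids[10:], vc, ridge=0.0)
        assert np.max(np.abs(ebv.values)) < 1e-8

    def test_rrblup_gblup_equivalence(self, marker_sim):
        """GBLUP on K = ZZ'/p reproduces ridge with alpha = sigma_e^2/(sigma_a^2/p)."""
        z_train, z_val = marker_sim["z_train"], marker_sim["z_val"]
        y, vc = marker_sim["y"], marker_sim["vc"]
        n, p = z_train.shape
        eff = ridge_solve(z_train, y, vc.alpha)
        ebv_rr = z_val @ eff.weights
        zz = np.vstack([z_train, z_val])
        ids = self.ids(len(zz))
        k = RelationshipMatrix(ids, zz @ zz.T / p, "G_vanraden")
        ebv_g = solve_mixed_model(k, y, ids[:n], ids[n:], vc,
                                  ridge=0.0).aligned_to(ids[n:])
        rel = np.max(np.abs(ebv_g - ebv_rr)) / np.max(np.abs(ebv_g))
        assert rel < 1e-8


class TestPredictValidation:
    def test_identical_genotypes_identical_ebv(self, rng):
        codes = rng.binomial(2, 0.5, size=(20, 15)).astype(np.int8)
        codes[10] = codes[0]
        geno = make_genotypes(codes)
        z, transform = center_scale(geno, reference_ids=geno.ids[:10])
        y = rng.normal(size=10)
        eff = ridge_solve(z, y, 1.0, scaling=transform)
        ebv = predict_validation(eff, geno.subset(ids=geno.ids[[0, 10]]))
        assert ebv.values[0] == pytest.approx(ebv.values[1])

    def test_zero_weights_give_fitted_mean(self, rng):
        codes = rng.binomial(2, 0.5, size=(10, 5)).astype(np.int8)
        geno = make_genotypes(codes)
        z, transform = center_scale(geno)
        eff = ridge_solve(z, np.full(10, 3.5), 1.0, scaling=transform)
        ebv = predict_validation(eff, geno, include_mean=True)
        assert np.allclose(ebv.values, 3.5, atol=1e-8)

    def test_panel_mismatch_rejected(self, rng):
        z = rng.normal(size=(10, 5))
        eff = ridge_solve(z, rng.normal(size=10), 1.0)
        with pytest.raises(ValueError):
            predict_validation(eff, rng.normal(size=(4, 6)))

    def test_prediction_invariant_to_snp_permutation(self, rng):
        z = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        zv = rng.normal(size=(5, 12))
        perm = rng.permutation(12)
        e1 = ridge_solve(z, y, 3.0).weights
        e2 = ridge_solve(z[:, perm], y, 3.0).weights
        assert np.allclose(zv @ e1, zv[:, perm] @ e2, atol=1e-10)


class TestPCA:
    def test_threshold_one_keeps_full_rank(self, rng):
        z = rng.normal(size=(12, 30))
        z = z - z.mean(axis=0)
        proj = pca_fit(z, variance_threshold=1.0)
        assert proj.n_components == proj.rank == np.linalg.matrix_rank(z)

    def test_threshold_picks_minimal_d(self, rng):
        z = rng.normal(size=(40, 60))
        proj = pca_fit(z, variance_threshold=0.97)
        d = proj.n_components
        assert proj.cumulative_fraction[d - 1] >= 0.97
        assert d == 1 or proj.cumulative_fraction[d - 2] < 0.97
        assert np.all(np.diff(proj.eigenvalues) <= 1e-9)

    def test_known_eigenstructure_toy(self):
        # rows along (1,1,0)/sqrt(2) with variance 8 and (0,0,1) with var 2
        z = np.array([
            [2.0, 2.0, 0.0], [-2.0, -2.0, 0.0],
            [0.0, 0.0, 1.0], [0.0, 0.0, -1.0],
        ])
        proj = pca_fit(z, n_components=2)
        assert np.allclose(proj.eigenvalues, [16.0, 2.0])
        assert np.allclose(np.abs(proj.components[0]),
                           [1 / np.sqrt(2), 1 / np.sqrt(2), 0.0], atol=1e-12)
        assert np.allclose(np.abs(proj.components[1]), [0.0, 0.0, 1.0],
                           atol=1e-12)

    def test_rows_orthonormal(self, rng):
        z = rng.normal(size=(25, 40))
        proj = pca_fit(z, variance_threshold=0.9)
        t = proj.components[:proj.n_components]
        assert np.allclose(t @ t.T, np.eye(proj.n_components), atol=1e-10)

    def test_invalid_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(5, 5)), variance_threshold=1.5)


class TestRRPCA:
    def test_full_rank_equals_rrblup(self, marker_sim):
        z_train, z_val = marker_sim["z_train"], marker_sim["z_val"]
        y, vc = marker_sim["y"], marker_sim["vc"]
        eff = ridge_solve(z_train, y, vc.alpha)
        ebv_rr = z_val @ eff.weights
        proj = pca_fit(z_train, variance_threshold=1.0)
        ebv_pca, _ = rrpca_solve(proj, z_train, y, vc.alpha, z_val,
                                 d=proj.rank)
        rel = np.max(np.abs(ebv_pca.values - ebv_rr)) / np.max(np.abs(ebv_rr))
        assert rel < 1e-8

    def test_single_component_prediction_is_first_score(self, marker_sim):
        z_train, z_val = marker_sim["z_train"], marker_sim["z_val"]
        y, vc = marker_sim["y"], marker_sim["vc"]
        proj = pca_fit(z_train, variance_threshold=1.0)
        ebv, _ = rrpca_solve(proj, z_train, y, vc.alpha, z_val, d=1)
        first_score = z_val @ proj.components[0]
        r = np.corrcoef(ebv.values, first_score)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_pc_sweep_endpoint_matches_rrblup_accuracy(self, marker_sim):
        from multiline_gp.evaluation import accuracy

        z_train, z_val = marker_sim["z_train"], marker_sim["z_val"]
        y, vc, h2 = marker_sim["y"], marker_sim["vc"], marker_sim["h2"]
        y_val = marker_sim["g_val"]
        proj = pca_fit(z_train, variance_threshold=1.0)
        curve = pc_sweep({"train": proj}, z_train, y, z_val, y_val, h2,
                         vc.alpha, d_grid=[1, proj.rank])
        eff = ridge_solve(z_train, y, vc.alpha)
        acc_rr = accuracy(z_val @ eff.weights, y_val, h2).accuracy
        endpoint = curve.loc[curve["d"] == proj.rank, "accuracy"].iloc[0]
        assert endpoint == pytest.approx(acc_rr, abs=1e-10)

    def test_pc_sweep_deterministic(self, marker_sim):
        z_train, z_val = marker_sim["z_train"], marker_sim["z_val"]
        y, vc, h2 = marker_sim["y"], marker_sim["vc"], marker_sim["h2"]
        proj = pca_fit(z_train, variance_threshold=1.0)
        args = ({"t": proj}, z_train, y, z_val, marker_sim["g_val"], h2,
                vc.alpha)
        c1 = pc_sweep(*args, d_grid=[5, 50])
        c2 = pc_sweep(*args, d_grid=[5, 50])
        assert c1.equals(c2)

    def test_wider_reference_set_extends_available_components(self, rng):
        p = 400
        z_small = rng.normal(size=(50, p))
        z_large = np.vstack([z_small, rng.normal(size=(100, p))])
        proj_small = pca_fit(z_small, variance_threshold=1.0)
        proj_large = pca_fit(z_large, variance_threshold=1.0)
        assert proj_large.rank > proj_small.rank
        with pytest.raises(ValueError):
            pc_sweep({"s": proj_small}, z_small, rng.normal(size=50),
                     z_small, rng.normal(size=50), 0.5, 1.0,
                     d_grid=[proj_small.rank + 1])
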