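import numpy as np
import pytest

import shapepose as sp
from shapepose.alignment import procrustes_align
from shapepose.datamodel import ModelError, ShapePoseError
from shapepose.ssm_fit import (
    estimate_mean_pose,
    knn_impute,
    ogk_covariance,
    ppca_regularize,
    select_reference_pose,
)

from conftest import make_clean_dataset, random_rigid


def _mad_scale_sq(x):
    return (1.482602218505602 * np.median(np.abs(x - np.median(x)))) ** 2


class TestSelectReference:
    def test_identical_poses_score_subsample_size(self, rng):
        pose = rng.standard_normal((5, 3))
        ds = sp.PoseDataset(np.repeat(pose[None], 12, axis=0))
        cfg = sp.FitConfig(seed=0, n_ransac_iter=5, subsample_frac=0.5,
                           neighbour_threshold=0.1)
        idx, score = select_reference_pose(ds, cfg)
        assert score == 6  # ceil(0.5 * 12)

    def test_zero_threshold_counts_exact_duplicates(self, rng):
        pose = rng.standard_normal((5, 3))
        coords = np.repeat(pose[None], 12, axis=0)
        coords[6:] += rng.standard_normal(coords[6:].shape)  # distinct poses
        ds = sp.PoseDataset(coords)
        cfg = sp.FitConfig(seed=1, n_ransac_iter=10, subsample_frac=1.0,
                           neighbour_threshold=0.0)
        idx, score = select_reference_pose(ds, cfg)
        assert idx < 6
        assert score == 6

    def test_prefers_inlier_reference(self):
        # 35 rigid motions of one shape + 15 wild poses: the winner must be
        # an inlier (exhaustive check over scores is implied by RANSAC with
        # enough iterations and full subsampling)
        rng = np.random.default_rng(0)
        base = sp.make_shape("poly", d=3)
        coords = np.stack(
            [random_rigid(rng).apply(base + 0.01 * rng.standard_normal(base.shape))
             for _ in range(35)]
            + [rng.standard_normal(base.shape) * 5 for _ in range(15)]
        )
        ds = sp.PoseDataset(coords)
        cfg = sp.FitConfig(seed=3, n_ransac_iter=40, subsample_frac=1.0,
                           neighbour_threshold="auto", n_threshold_pairs=500)
        idx, score = select_reference_pose(ds, cfg)
        assert idx < 35
        assert score >= 30

    def test_requires_complete_pose(self, rng):
        coords = rng.standard_normal((12, 4, 3))
        coords[:, 0] = np.nan
        ds = sp.PoseDataset(coords)
        with pytest.raises(ShapePoseError):
            select_reference_pose(ds, sp.FitConfig(neighbour_threshold=1.0))

    def test_too_small_dataset(self, rng):
        ds = sp.PoseDataset(rng.standard_normal((5, 4, 3)))
        with pytest.raises(ShapePoseError):
            select_reference_pose(ds, sp.FitConfig(neighbour_threshold=1.0))


class TestEstimateMeanPose:
    def test_exact_recovery_noise_free(self):
        ds, truth = make_clean_dataset(n_poses=50, sigma_n=0.0, n_ep=2, seed=1)
        cfg = sp.FitConfig(seed=0, n_threshold_pairs=200)
        res = estimate_mean_pose(ds, cfg)
        mu_shape = res.mu.reshape(ds.n_points, ds.d)
        # the true mean shape, after aligning into the model frame
        _, _, resid = procrustes_align(truth.mean_shape, mu_shape)
        assert resid <= 0.2  # deformations average out at n=50
        # aligned poses match their noise-free deformed shapes up to the frame
        assert res.valid.all()

    def test_noise_scaling(self):
        # in the noise-dominated regime (no deformation, mean refinement on)
        # the mean error shrinks roughly as O(1/sqrt(n))
        rng = np.random.default_rng(7)
        base = sp.make_shape("poly", d=3)
        errs = []
        for n in (50, 200, 800):
            coords = np.stack(
                [random_rigid(rng).apply(base + 0.02 * rng.standard_normal(base.shape))
                 for _ in range(n)]
            )
            ds = sp.PoseDataset(coords)
            res = estimate_mean_pose(
                ds, sp.FitConfig(seed=0, n_threshold_pairs=150, refine_to_mean=True)
            )
            _, _, resid = procrustes_align(base, res.mu.reshape(ds.n_points, ds.d))
            errs.append(resid)
        slope = np.polyfit(np.log([50, 200, 800]), np.log(errs), 1)[0]
        assert slope < -0.25

    def test_majority_shape_wins(self):
        # 75% one shape, 25% a distant second shape: mu tracks the majority
        rng = np.random.default_rng(2)
        base = sp.make_shape("poly", d=3)
        other = sp.make_shape("plus", d=3)[: base.shape[0]] * 3.0
        coords = np.stack(
            [random_rigid(rng).apply(base + 0.02 * rng.standard_normal(base.shape))
             for _ in range(45)]
            + [random_rigid(rng).apply(other + 0.02 * rng.standard_normal(other.shape))
               for _ in range(15)]
        )
        ds = sp.PoseDataset(coords)
        cfg = sp.FitConfig(seed=1, n_ransac_iter=50, n_threshold_pairs=500)
        res = estimate_mean_pose(ds, cfg)
        _, _, resid_major = procrustes_align(
            base, res.mu.reshape(ds.n_points, ds.d)
        )
        mix = 0.75 * base + 0.25 * other
        _, _, resid_mix = procrustes_align(mix, res.mu.reshape(ds.n_points, ds.d))
        assert resid_major < resid_mix
        assert resid_major <= 0.35  # well within 0.05 * shape scale (radius 3)

    def test_unalignable_pose_flagged_not_dropped(self, rng):
        ds, _ = make_clean_dataset(n_poses=20, seed=3)
        ds.coords[4, :-2] = np.nan
        ds.missing_mask[4, :-2] = True
        res = estimate_mean_pose(ds, sp.FitConfig(seed=0, n_threshold_pairs=100))
        assert not res.valid[4]
        assert res.valid.sum() == 19
        assert len(res.transforms) == 20


class TestKnnImpute:
    def test_identical_poses_exact(self, rng):
        pose = rng.standard_normal((5, 3))
        coords = np.repeat(pose[None], 8, axis=0)
        coords[2, 3] = np.nan
        ds = sp.PoseDataset(coords)
        out = knn_impute(ds, k=5)
        np.testing.assert_allclose(out.coords[2, 3], pose[3], atol=1e-12)
        assert out.n_missing() == 0

    def test_observed_entries_untouched(self, rng):
        ds, _ = make_clean_dataset(n_poses=15, seed=4, translation_scale=0.0)
        ds.coords[3, 1] = np.nan
        ds.missing_mask[3, 1] = True
        before = ds.coords.copy()
        out = knn_impute(ds, k=3)
        obs = ~ds.missing_mask
        np.testing.assert_array_equal(out.coords[obs], before[obs])

    def test_matches_hand_enumeration(self):
        # 10 poses in a common frame (no nuisance motion); brute-force oracle
        rng = np.random.default_rng(9)
        base = sp.make_shape("poly", d=3)
        coords = base[None] + 0.05 * rng.standard_normal((10, *base.shape))
        target = 0
        coords_missing = coords.copy()
        coords_missing[target, 2] = np.nan
        ds = sp.PoseDataset(coords_missing)
        out = knn_impute(ds, k=3)
        # oracle: align each candidate to the target, rank by RMS distance
        # over the target's observed points, average nearest 3 at the gap
        cands = []
        for j in range(1, 10):
            aligned, _, resid = procrustes_align(
                coords[j], coords_missing[target],
                target_mask=ds.missing_mask[target],
            )
            cands.append((resid, aligned[2]))
        cands.sort(key=lambda c: c[0])
        expected = np.mean([c[1] for c in cands[:3]], axis=0)
        np.testing.assert_allclose(out.coords[target, 2], expected, atol=1e-10)

    def test_k_capped_at_available(self, rng):
        pose = rng.standard_normal((5, 3))
        coords = np.repeat(pose[None], 4, axis=0)
        coords[0, 1] = np.nan
        ds = sp.PoseDataset(coords)
        out = knn_impute(ds, k=50)
        np.testing.assert_allclose(out.coords[0, 1], pose[1], atol=1e-12)

    def test_no_recovering_pose_errors(self, rng):
        coords = rng.standard_normal((4, 4, 3))
        coords[:, 2] = np.nan  # point 2 missing everywhere
        ds = sp.PoseDataset(coords)
        with pytest.raises(ShapePoseError, match="recovering"):
            knn_impute(ds, k=2)


class TestOgkCovariance:
    def test_univariate_reduction(self, rng):
        x = rng.standard_normal(500) * 2.0 + 1.0
        c = ogk_covariance(x[:, None], reweight=False)
        np.testing.assert_allclose(c[0, 0], _mad_scale_sq(x), rtol=1e-10)

    def test_gaussian_consistency(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((6, 6))
        sigma0 = a @ a.T + np.eye(6)
        x = rng.multivariate_normal(np.zeros(6), sigma0, size=10000)
        c = ogk_covariance(x)
        rel = np.linalg.norm(c - sigma0) / np.linalg.norm(sigma0)
        assert rel <= 0.1
        sample = np.cov(x.T)
        assert np.linalg.norm(c - sample) / np.linalg.norm(sigma0) <= 0.05

    def test_robust_to_gross_contamination(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((5, 5))
        sigma0 = a @ a.T + np.eye(5)
        n = 4000
        x = rng.multivariate_normal(np.zeros(5), sigma0, size=n)
        n_bad = int(0.2 * n)
        x[:n_bad] = 50.0 * np.sqrt(np.diag(sigma0)) * rng.standard_normal((n_bad, 5))
        c = ogk_covariance(x)
        rel = np.linalg.norm(c - sigma0) / np.linalg.norm(sigma0)
        assert rel <= 0.15
        sample_rel = np.linalg.norm(np.cov(x.T) - sigma0) / np.linalg.norm(sigma0)
        assert sample_rel > 1.0

    def test_deterministic(self, rng):
        x = rng.standard_normal((200, 4))
        np.testing.assert_array_equal(ogk_covariance(x), ogk_covariance(x))

    def test_zero_mad_column_warns(self, rng):
        x = rng.standard_normal((100, 3))
        x[:, 1] = 7.0
        with pytest.warns(RuntimeWarning):
            c = ogk_covariance(x, reweight=False)
        assert np.isfinite(c).all()

    def test_requires_complete_data(self):
        x = np.ones((10, 3))
        x[0, 0] = np.nan
        with pytest.raises(ShapePoseError):
            ogk_covariance(x)


class TestPpcaRegularize:
    def test_identity_case(self):
        v, evals, s2 = ppca_regularize(np.eye(5), "fixed_r", 2)
        assert s2 == 1.0
        np.testing.assert_allclose(evals, [1.0, 1.0])

    def test_diagonal_exact_sigma2(self):
        c = np.diag([5.0, 4.0, 1.0, 1.0, 1.0, 1.0])
        v, evals, s2 = ppca_regularize(c, "fixed_r", 2)
        assert s2 == 1.0
        np.testing.assert_allclose(evals, [5.0, 4.0])

    def test_trace_conservation(self, rng):
        a = rng.standard_normal((8, 8))
        c = a @ a.T
        for r in (1, 3, 6):
            v, evals, s2 = ppca_regularize(c, "fixed_r", r)
            np.testing.assert_allclose(
                evals.sum() + (8 - r) * s2, np.trace(c), rtol=1e-12
            )

    def test_variance_fraction_rank(self):
        c = np.diag([8.0, 1.0, 0.5, 0.3, 0.2])
        v, evals, s2 = ppca_regularize(c, "variance_fraction", 0.79)
        assert v.shape[1] == 1
        v2, _, _ = ppca_regularize(c, "variance_fraction", 0.95)
        assert v2.shape[1] == 3

    def test_full_rank_errors(self):
        with pytest.raises(ModelError):
            ppca_regularize(np.eye(4), "fixed_r", 4)

    def test_regularized_matrix_spd(self, rng):
        a = rng.standard_normal((6, 6))
        c = a @ a.T
        v, evals, s2 = ppca_regularize(c, "fixed_r", 2)
        model = sp.ShapeModel(np.zeros(6), v, evals, s2, d=2)
        model.validate()


class TestFitSsm:
    def test_deterministic(self):
        ds, _ = make_clean_dataset(n_poses=60, n_ep=2, seed=5)
        cfg = sp.FitConfig(seed=11, r=2, n_threshold_pairs=150)
        a = sp.fit_ssm(ds, cfg)
        b = sp.fit_ssm(ds, cfg)
        np.testing.assert_array_equal(a.model.mu, b.model.mu)
        np.testing.assert_array_equal(a.model.eigenposes, b.model.eigenposes)
        np.testing.assert_array_equal(a.model.eigenvalues, b.model.eigenvalues)
        assert a.model.sigma2 == b.model.sigma2

    def test_clean_recovery(self):
        ds, truth = make_clean_dataset(n_poses=600, n_ep=3, sigma_n=0.02, seed=6)
        cfg = sp.FitConfig(seed=0, r=3, n_threshold_pairs=500)
        fit = sp.fit_ssm(ds, cfg)
        assert sp.model_similarity(truth, fit.model).min() >= 0.99

    def test_covariance_spd_invariant(self):
        ds, _ = make_clean_dataset(n_poses=60, n_ep=2, seed=7)
        fit = sp.fit_ssm(ds, sp.FitConfig(seed=0, r=2, n_threshold_pairs=100))
        np.linalg.cholesky(fit.model.covariance())
        fit.model.validate()

    def test_equivariance_under_global_motion(self, rng):
        ds, _ = make_clean_dataset(n_poses=80, n_ep=2, seed=8)
        cfg = sp.FitConfig(seed=4, r=2, n_threshold_pairs=150)
        fit0 = sp.fit_ssm(ds, cfg)
        t = random_rigid(rng)
        moved = sp.PoseDataset(t.apply(ds.coords), ds.missing_mask.copy())
        fit1 = sp.fit_ssm(moved, cfg)
        # OGK is only asymptotically rotation-equivariant (pairwise robust
        # scales are coordinate-wise), so exact equality cannot hold
        np.testing.assert_allclose(
            fit0.model.eigenvalues, fit1.model.eigenvalues, rtol=0.25
        )
        np.testing.assert_allclose(fit0.model.sigma2, fit1.model.sigma2, rtol=0.25)
        assert sp.model_pair_similarity(fit0.model, fit1.model).min() >= 0.97

    def test_eigenvalue_consistency_trend(self):
        # eigenvalue estimates approach the truth as n grows
        errs = []
        truth_evals = sp.default_b_scales(2) ** 2 + 0.01 ** 2
        for n in (300, 1200):
            ds, truth = make_clean_dataset(n_poses=n, n_ep=2, sigma_n=0.01, seed=9)
            fit = sp.fit_ssm(ds, sp.FitConfig(seed=0, r=2, n_threshold_pairs=200))
            errs.append(
                np.abs(fit.model.eigenvalues - truth_evals).max() / truth_evals[0]
            )
        assert errs[1] < errs[0] + 0.02

    def test_fit_with_missing_data_uses_knn(self):
        ds, _ = make_clean_dataset(n_poses=80, n_ep=2, seed=10)
        mask = np.random.default_rng(0).random(ds.missing_mask.shape) < 0.05
        ds.coords[mask] = np.nan
        ds = sp.PoseDataset(ds.coords)
        fit = sp.fit_ssm(ds, sp.FitConfig(seed=1, r=2, n_threshold_pairs=150))
        fit.model.validate()

    def test_report_contents(self):
        ds, _ = make_clean_dataset(n_poses=40, n_ep=2, seed=11)
        fit = sp.fit_ssm(ds, sp.FitConfig(seed=2, r=2, n_threshold_pairs=100))
        rep = fit.report
        assert rep["rank"] == 2
        assert 0 <= rep["reference_index"] < 40
        assert rep["neighbour_threshold"] > 0
        assert len(rep["explained_variance"]) == ds.n_coords
        assert rep["config"]["seed"] == 2
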