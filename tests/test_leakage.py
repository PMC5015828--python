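"""Leakage analyses: ROI reconstruction, searchlight mapping, smoothing."""

import numpy as np
import pytest

import decnef as dn
from decnef.leakage import (
    LassoConfig,
    build_spheres,
    full_fit_targets,
    inner_target_estimates,
    roi_leak,
    roi_leak_table,
    searchlight_decoder_stage,
    searchlight_induction_stage,
    select_lambda,
    smooth_map,
    SearchlightMap,
)
from decnef.preprocess import SampleMatrix


@pytest.fixture(scope="module")
def leak_setup():
    """Target estimates plus coupled/null region samples, sample-level."""
    gt = dn.make_ground_truth(
        n_other_rois=3,
        roi_voxels=15,
        target_voxels=18,
        coupling={"R01": 0.9, "R02": 0.5, "R03": 0.0},
        noise_sd=1.0,
        seed=41,
    )
    pool = dn.select_faces(dn.generate_face_pool(300, gt, seed=1), seed=2)
    runs, _ = dn.simulate_rating_session(gt, pool, n_runs=6, trials_per_run=20, seed=3)
    sm = dn.extract_session(runs, period="rating", mode="offline")
    target = sm.select_voxels(gt.target_indices)
    dec = dn.fit_sparse_decoder(*dn.normalize_train_test(target, target)[:1], target.ratings)
    estimates = dn.predict_rating(dec, dn.normalize_train_test(target, target)[0].samples, clip=False)
    regions = dn.couple_rois(target, gt, seed=4)
    regions[gt.target_roi] = target
    return gt, target, np.asarray(estimates), regions


class TestRoiLeak:
    def test_target_region_is_the_positive_control(self, leak_setup):
        gt, target, estimates, regions = leak_setup
        table = roi_leak_table(regions, estimates, n_perm=200, seed=0)
        zs = table.set_index("region")["mean_z"]
        assert zs["CC"] == zs.max()
        assert zs["CC"] > zs["R03"] + 0.5

    def test_reconstruction_tracks_coupling_strength(self, leak_setup):
        gt, target, estimates, regions = leak_setup
        z = {
            name: roi_leak(estimates, regions[name], region=name).mean_z
            for name in ("R01", "R02", "R03")
        }
        assert z["R01"] > z["R02"] > z["R03"]

    def test_zero_coupling_region_is_not_significant(self, leak_setup):
        gt, target, estimates, regions = leak_setup
        table = roi_leak_table(regions, estimates, n_perm=300, seed=1)
        row = table[table.region == "R03"].iloc[0]
        assert abs(row["perm_z"]) < 3

    def test_empty_region_is_an_error(self, leak_setup):
        gt, target, estimates, _ = leak_setup
        empty = SampleMatrix(
            samples=np.empty((target.n_trials, 0)),
            run_labels=target.run_labels,
            period="rating",
            window_volumes=3,
        )
        with pytest.raises(ValueError, match="no voxels"):
            roi_leak(estimates, empty, region="hollow")

    def test_bias_is_the_mean_of_target_estimates(self, leak_setup):
        gt, target, estimates, regions = leak_setup
        res = roi_leak(estimates, regions["R01"], region="R01")
        assert res.bias == pytest.approx(estimates.mean())

    def test_coupling_monotonicity_across_replicates(self):
        """Fisher z of the reconstruction is non-decreasing in coupling."""
        zs = {c: [] for c in (0.0, 0.5, 1.0)}
        for seed in range(6):
            gt = dn.make_ground_truth(
                n_other_rois=3, roi_voxels=12, target_voxels=14,
                coupling={"R01": 0.0, "R02": 0.5, "R03": 1.0},
                noise_sd=1.0, seed=100 + seed,
            )
            pool = dn.select_faces(dn.generate_face_pool(300, gt, seed=seed), seed=seed)
            runs, _ = dn.simulate_rating_session(gt, pool, n_runs=4, trials_per_run=20, seed=seed)
            sm = dn.extract_session(runs, period="rating", mode="offline")
            target = sm.select_voxels(gt.target_indices)
            estimates = target.samples @ gt.true_weights  # ideal read-out
            regions = dn.couple_rois(target, gt, seed=seed)
            for roi, c in (("R01", 0.0), ("R02", 0.5), ("R03", 1.0)):
                zs[c].append(roi_leak(estimates, regions[roi], region=roi).mean_z)
        means = {c: np.mean(v) for c, v in zs.items()}
        assert means[0.0] < means[0.5] < means[1.0], means


class TestBuildSpheres:
    def test_zero_radius_gives_singletons(self):
        spheres = build_spheres((4, 4, 4), (3.0, 3.0, 3.5), radius_mm=0.0)
        assert len(spheres) == 64
        for center, members in spheres.items():
            assert members.tolist() == [center]

    def test_interior_sphere_matches_brute_force_enumeration(self):
        grid, dims = (11, 11, 9), (3.0, 3.0, 3.5)
        spheres = build_spheres(grid, dims, radius_mm=15.0)
        center = (5, 5, 4)
        flat = int(np.ravel_multi_index(center, grid))
        # independent oracle: scan every voxel's physical distance
        expected = set()
        for x in range(grid[0]):
            for y in range(grid[1]):
                for z in range(grid[2]):
                    d = np.sqrt(
                        ((x - center[0]) * dims[0]) ** 2
                        + ((y - center[1]) * dims[1]) ** 2
                        + ((z - center[2]) * dims[2]) ** 2
                    )
                    if d <= 15.0:
                        expected.add(int(np.ravel_multi_index((x, y, z), grid)))
        assert set(spheres[flat].tolist()) == expected

    def test_counts_shrink_at_mask_edges(self):
        grid, dims = (11, 11, 9), (3.0, 3.0, 3.5)
        spheres = build_spheres(grid, dims, radius_mm=15.0)
        interior = int(np.ravel_multi_index((5, 5, 4), grid))
        corner = int(np.ravel_multi_index((0, 0, 0), grid))
        assert len(spheres[corner]) < len(spheres[interior])
        # corner members are a subset of what an uncropped sphere would hold
        assert set(spheres[corner]) <= set(
            m for s in spheres.values() for m in s
        )

    def test_gray_mask_restricts_centers_and_members(self):
        grid = (4, 4, 2)
        mask = np.zeros(grid, dtype=bool)
        mask[:2] = True
        spheres = build_spheres(grid, (3.0, 3.0, 3.5), radius_mm=10.0, gray_mask=mask)
        gray_flat = set(np.flatnonzero(mask.ravel()).tolist())
        assert set(spheres) == gray_flat
        for members in spheres.values():
            assert set(members.tolist()) <= gray_flat

    def test_bad_voxel_dims_are_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_spheres((4, 4, 4), (3.0, 0.0, 3.5))


@pytest.fixture(scope="module")
def searchlight_setup():
    """Full-grid decoder-stage samples with one coupled and one silent ROI."""
    gt = dn.make_ground_truth(
        n_other_rois=2,
        roi_voxels=24,
        target_voxels=24,
        coupling={"R01": 0.9, "R02": 0.0},
        noise_sd=1.0,
        gap=3,  # spheres must not straddle two regions
        seed=51,
    )
    pool = dn.select_faces(dn.generate_face_pool(300, gt, seed=5), seed=6)
    runs, _ = dn.simulate_rating_session(gt, pool, n_runs=6, trials_per_run=20, seed=7)
    sm = dn.extract_session(runs, period="rating", mode="offline")
    rng = np.random.default_rng(52)
    all_spheres = build_spheres(gt.grid_shape, gt.voxel_dims_mm, radius_mm=7.5)
    spheres = {}
    for roi, idx in gt.roi_layout.items():
        for c in rng.choice(np.asarray(idx), 6, replace=False):
            spheres[int(c)] = all_spheres[int(c)]
    cfg = LassoConfig(lam=0.3)
    return gt, sm, spheres, cfg


def _roi_center_values(m, gt, roi):
    vals = m.values[np.asarray(gt.roi_layout[roi])]
    return vals[np.isfinite(vals)]


class TestSearchlightDecoderStage:
    def test_target_spheres_outscore_silent_spheres(self, searchlight_setup):
        gt, sm, spheres, cfg = searchlight_setup
        target = sm.select_voxels(gt.target_indices)
        estimates = inner_target_estimates(target, sm.ratings)
        m = searchlight_decoder_stage(
            sm, estimates, spheres, cfg, grid_shape=gt.grid_shape
        )
        cc = _roi_center_values(m, gt, "CC")
        silent = _roi_center_values(m, gt, "R02")
        assert cc.mean() > silent.mean() + 0.3
        assert np.nanmin(m.values[np.asarray(gt.roi_layout["CC"])]) > np.percentile(silent, 50)

    def test_coupled_region_lights_up_during_decoder_stage(self, searchlight_setup):
        gt, sm, spheres, cfg = searchlight_setup
        target = sm.select_voxels(gt.target_indices)
        estimates = inner_target_estimates(target, sm.ratings)
        m = searchlight_decoder_stage(sm, estimates, spheres, cfg, grid_shape=gt.grid_shape)
        coupled = _roi_center_values(m, gt, "R01")
        silent = _roi_center_values(m, gt, "R02")
        assert coupled.mean() > silent.mean() + 0.3

    def test_empty_sphere_set_leaves_nan_map(self, searchlight_setup):
        gt, sm, _, cfg = searchlight_setup
        m = searchlight_decoder_stage(sm, np.zeros(sm.n_trials), {}, cfg, grid_shape=gt.grid_shape)
        assert np.isnan(m.values).all()


class TestSearchlightInductionStage:
    @staticmethod
    def _induction_samples(gt, n=60, seed=8):
        """Grid-level induction-stage samples: target pattern plus coupling.

        Samples emulate 3-volume averages (noise sd / sqrt(3)) with induced
        shifts spread like the decoder-stage rating deviations.
        """
        rng = np.random.default_rng(seed)
        shifts = rng.normal(0.5, 0.8, n)
        X = rng.normal(0.0, gt.noise_sd / np.sqrt(3), (n, gt.n_voxels))
        pattern = np.outer(shifts, gt.encode_pattern_unit)
        X[:, gt.target_indices] += pattern
        from decnef.synth import _coupling_map

        for roi, c in gt.coupling.items():
            if c > 0:
                M = _coupling_map(gt, roi)
                X[:, np.asarray(gt.roi_layout[roi])] += c * (pattern @ M.T)
        sm = SampleMatrix(
            samples=X, run_labels=np.repeat(np.arange(4), n // 4),
            period="induction", window_volumes=3,
        )
        estimates = X[:, gt.target_indices] @ gt.true_weights
        return sm, estimates

    def test_only_target_and_coupled_spheres_reconstruct(self, searchlight_setup):
        gt, sm, spheres, cfg = searchlight_setup
        target = sm.select_voxels(gt.target_indices)
        targets = full_fit_targets(target, sm.ratings)
        ind_sm, ind_est = self._induction_samples(gt)
        m = searchlight_induction_stage(
            sm, targets, ind_sm, ind_est, spheres, cfg, grid_shape=gt.grid_shape
        )
        cc = _roi_center_values(m, gt, "CC")
        coupled = _roi_center_values(m, gt, "R01")
        silent = _roi_center_values(m, gt, "R02")
        assert cc.mean() > silent.mean() + 0.3
        assert coupled.mean() > silent.mean() + 0.3

    def test_training_never_sees_induction_data(self, searchlight_setup):
        """Permuting the induction samples permutes the reconstructions."""
        gt, sm, spheres, cfg = searchlight_setup
        target = sm.select_voxels(gt.target_indices)
        targets = full_fit_targets(target, sm.ratings)
        ind_sm, ind_est = self._induction_samples(gt)
        perm = np.random.default_rng(9).permutation(ind_sm.n_trials)
        ind_perm = SampleMatrix(
            samples=ind_sm.samples[perm], run_labels=ind_sm.run_labels,
            period="induction", window_volumes=3,
        )
        m1 = searchlight_induction_stage(sm, targets, ind_sm, ind_est, spheres, cfg, grid_shape=gt.grid_shape)
        m2 = searchlight_induction_stage(sm, targets, ind_perm, ind_est[perm], spheres, cfg, grid_shape=gt.grid_shape)
        np.testing.assert_allclose(m1.values, m2.values, equal_nan=True, atol=1e-10)

    def test_missing_induction_log_is_an_error(self, searchlight_setup):
        gt, sm, spheres, cfg = searchlight_setup
        ind_sm, _ = self._induction_samples(gt)
        with pytest.raises(ValueError, match="induction"):
            searchlight_induction_stage(sm, np.zeros(sm.n_trials), ind_sm, np.array([]), spheres, cfg)


class TestSelectLambda:
    def test_degenerate_grid_returns_its_only_value(self, searchlight_setup):
        gt, sm, spheres, _ = searchlight_setup
        few = dict(list(spheres.items())[:3])
        cfg = LassoConfig(lam=0.1, lambda_grid=(0.1,))
        assert select_lambda(sm, sm.ratings, few, cfg) == 0.1

    def test_infinite_penalty_is_never_selected_when_signal_exists(self, searchlight_setup):
        gt, sm, spheres, _ = searchlight_setup
        cc_spheres = {c: m for c, m in spheres.items() if c in set(gt.roi_layout["CC"])}
        few = dict(list(cc_spheres.items())[:3])
        cfg = LassoConfig(lam=0.1, lambda_grid=(0.05, 1e6))
        lam, scores = select_lambda(sm, sm.ratings, few, cfg, return_scores=True)
        assert lam == 0.05
        # all weights zero: any residual score is fold-intercept noise near 0
        assert scores[1e6] < 0.1
        assert scores[0.05] > scores[1e6] + 0.2

    def test_selection_matches_exhaustive_evaluation(self, searchlight_setup):
        gt, sm, spheres, _ = searchlight_setup
        few = dict(list(spheres.items())[:2])
        cfg = LassoConfig(lam=0.1, lambda_grid=(0.02, 0.1, 0.5))
        lam, scores = select_lambda(sm, sm.ratings, few, cfg, return_scores=True)
        assert lam == max(scores, key=lambda k: scores[k])

    def test_empty_grid_is_an_error(self, searchlight_setup):
        gt, sm, spheres, _ = searchlight_setup
        cfg = LassoConfig(lam=0.1, lambda_grid=())
        with pytest.raises(ValueError, match="empty"):
            select_lambda(sm, sm.ratings, spheres, cfg)


class TestSmoothMap:
    @staticmethod
    def _map(values, grid=(9, 9, 9), dims=(3.0, 3.0, 3.0)):
        return SearchlightMap(
            values=values, grid_shape=grid, voxel_dims_mm=dims,
            radius_mm=15.0, stage="decoder_construction",
        )

    def test_constant_map_is_unchanged(self):
        vals = np.full(9 * 9 * 9, 1.7)
        vals[::7] = np.nan  # scattered invalid centers
        out = smooth_map(self._map(vals), fwhm_mm=4.0)
        valid = np.isfinite(vals)
        np.testing.assert_allclose(out.values[valid], 1.7, atol=1e-9)
        assert np.isnan(out.values[~valid]).all()

    def test_delta_kernel_mass_is_conserved_in_the_interior(self):
        vals = np.zeros(9 * 9 * 9)
        center = np.ravel_multi_index((4, 4, 4), (9, 9, 9))
        vals[center] = 1.0
        out = smooth_map(self._map(vals), fwhm_mm=4.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_kernel_width_follows_the_fwhm_sigma_relation(self):
        # ratio of the smoothed delta at a 3 mm neighbor to its peak is
        # exp(-d^2 / 2 sigma^2) with sigma = FWHM / 2.3548 (discrete kernel)
        vals = np.zeros(9 * 9 * 9)
        grid = (9, 9, 9)
        center = (4, 4, 4)
        vals[np.ravel_multi_index(center, grid)] = 1.0
        out = smooth_map(self._map(vals), fwhm_mm=4.0)
        vol = out.volume()
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        assert sigma == pytest.approx(1.6986, abs=1e-4)
        ratio = vol[5, 4, 4] / vol[4, 4, 4]
        assert ratio == pytest.approx(np.exp(-(3.0**2) / (2 * sigma**2)), rel=0.05)

    def test_negative_fwhm_is_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            smooth_map(self._map(np.zeros(9 * 9 * 9)), fwhm_mm=-1.0)
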