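import numpy as np
import pytest

import scanqa as sq
from scanqa.bold import FWHM_TO_SD, drift_basis


def _img4d(data, tr=2.5, voxel_dims=(1, 1, 1)):
    return sq.Image4D(np.asarray(data, float), np.eye(4), voxel_dims, tr)


class TestDiscard:
    def test_244_minus_4(self):
        img = _img4d(np.random.default_rng(0).normal(size=(4, 4, 2, 244)))
        out = sq.discard_initial_volumes(img, 4)
        assert out.n_volumes == 240
        np.testing.assert_array_equal(out.voxels, img.voxels[..., 4:])

    def test_zero_is_identity(self):
        img = _img4d(np.ones((3, 3, 2, 10)))
        assert sq.discard_initial_volumes(img, 0) is img

    def test_too_many_rejected(self):
        img = _img4d(np.ones((3, 3, 2, 10)))
        with pytest.raises(ValueError):
            sq.discard_initial_volumes(img, 10)


class TestBrainMask:
    def test_phantom_support_recovered(self):
        spec = sq.StructuralPhantomSpec(
            shape=(24, 24, 24),
            regions=[sq.EllipsoidRegion(1, (12, 12, 12), (8, 7, 6), 1000.0)],
            background_intensity=0.0, background_noise_sd=0.0,
        )
        img, labels = sq.make_structural_phantom(spec, 0)
        mask = sq.make_brain_mask(img)
        np.testing.assert_array_equal(mask.mask(), labels.mask())

    def test_largest_component_kept(self):
        vox = np.zeros((20, 20, 20))
        vox[2:5, 2:5, 2:5] = 100.0  # 27 voxels
        vox[10:18, 10:18, 10:18] = 100.0  # 512 voxels
        mask = sq.make_brain_mask(sq.Image3D(vox, np.eye(4), (1, 1, 1)))
        assert mask.mask()[12, 12, 12]
        assert not mask.mask()[3, 3, 3]

    def test_threshold_monotonic(self):
        rng = np.random.default_rng(4)
        from scipy import ndimage as ndi

        vox = ndi.gaussian_filter(rng.uniform(size=(20, 20, 20)), 3)
        img = sq.Image3D(vox, np.eye(4), (1, 1, 1))
        sizes = [
            int(sq.make_brain_mask(img, f).mask().sum()) for f in (0.2, 0.25, 0.3)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_constant_image_rejected(self):
        img = sq.Image3D(np.ones((5, 5, 5)), np.eye(4), (1, 1, 1))
        with pytest.raises(ValueError):
            sq.make_brain_mask(img)


class TestSmoothing:
    def test_fwhm_zero_identity(self):
        img = _img4d(np.random.default_rng(0).normal(size=(6, 6, 6, 4)))
        out = sq.smooth_gaussian(img, 0.0)
        np.testing.assert_array_equal(out.voxels, img.voxels)

    def test_constant_volume_preserved(self):
        img = _img4d(np.full((10, 10, 10, 3), 7.0))
        out = sq.smooth_gaussian(img, 5.0)
        np.testing.assert_allclose(out.voxels, 7.0, rtol=1e-7)

    def test_impulse_response_matches_closed_form(self):
        n = 31
        vox = np.zeros((n, n, n, 2))
        vox[15, 15, 15, 0] = 1.0
        out = sq.smooth_gaussian(_img4d(vox), 5.0)
        sd = 5.0 * FWHM_TO_SD
        x = np.arange(n) - 15.0
        g1 = np.exp(-(x**2) / (2 * sd**2))
        g1 /= g1.sum()
        expected_center_line = g1 * g1[15] * g1[15]
        np.testing.assert_allclose(out.voxels[:, 15, 15, 0], expected_center_line, atol=1e-6)


class TestHighpass:
    def test_slow_sine_removed(self):
        tr, n = 2.5, 240
        t = np.arange(n) * tr
        sine = np.sin(2 * np.pi * t / 300.0)
        img = _img4d(np.tile(sine, (2, 2, 1, 1)), tr=tr)
        out = sq.highpass_temporal(img, 150.0)
        assert np.abs(out.voxels[0, 0, 0]).max() < 0.05 * 1.0

    def test_fast_sine_passes(self):
        tr, n = 2.5, 240
        t = np.arange(n) * tr
        sine = np.sin(2 * np.pi * t / 10.0)
        img = _img4d(sine.reshape(1, 1, 1, n), tr=tr)
        out = sq.highpass_temporal(img, 150.0)
        amp_ratio = np.abs(out.voxels[0, 0, 0]).max() / np.abs(sine).max()
        assert amp_ratio > 0.95

    def test_mean_preserved_on_noise(self):
        rng = np.random.default_rng(2)
        img = _img4d(rng.normal(50, 3, size=(3, 3, 2, 100)), tr=2.0)
        out = sq.highpass_temporal(img, 120.0)
        np.testing.assert_allclose(
            out.voxels.mean(axis=3), img.voxels.mean(axis=3), atol=1e-9
        )

    def test_cutoff_must_exceed_nyquist(self):
        img = _img4d(np.ones((2, 2, 2, 20)), tr=2.5)
        with pytest.raises(ValueError):
            sq.highpass_temporal(img, 4.0)

    def test_drift_basis_orthonormal(self):
        basis = drift_basis(240, 2.5, 150.0)
        assert basis.shape == (240, 8)
        np.testing.assert_allclose(basis.T @ basis, np.eye(8), atol=1e-12)


class TestNuisanceRegression:
    def test_exact_fit_leaves_constant(self):
        rng = np.random.default_rng(3)
        series = rng.normal(size=30)
        vox = np.tile(series + 10.0, (2, 2, 1, 1))
        img = _img4d(vox, tr=2.0)
        out = sq.nuisance_regress(img, (series - series.mean()).reshape(-1, 1))
        np.testing.assert_allclose(out.voxels[0, 0, 0], np.full(30, out.voxels[0, 0, 0].mean()), atol=1e-9)

    def test_rank_deficient_rejected(self):
        img = _img4d(np.random.default_rng(0).normal(size=(2, 2, 2, 20)), tr=2.0)
        with pytest.raises(ValueError):
            sq.nuisance_regress(img, np.zeros((20, 2)))

    def test_ols_oracle_recovery(self):
        rng = np.random.default_rng(8)
        n = 60
        motion = rng.normal(size=n)
        signal = 100.0 + np.sin(np.arange(n) * 0.7)
        contaminated = signal + 3.0 * motion
        img = _img4d(contaminated.reshape(1, 1, 1, n), tr=2.0)
        out = sq.nuisance_regress(img, motion.reshape(-1, 1))
        # OLS oracle: residual of explicit normal-equations fit plus the mean
        x = np.column_stack([np.ones(n), motion])
        beta = np.linalg.solve(x.T @ x, x.T @ contaminated)
        oracle = contaminated - x @ beta + contaminated.mean()
        np.testing.assert_allclose(out.voxels[0, 0, 0], oracle, atol=1e-8)
        rms = np.sqrt(np.mean((out.voxels[0, 0, 0] - signal) ** 2))
        # mean offset from the motion regressor's covariance with signal
        assert rms < np.sqrt(np.mean((contaminated - signal) ** 2))


class TestRoiTsnr:
    def test_programmed_magnitude(self):
        rng = np.random.default_rng(0)
        course = 700.0 + rng.normal(0, 1.0, size=200)
        img = _img4d(np.tile(course, (3, 3, 1, 1)), tr=2.5)
        res = sq.roi_tsnr(img, np.ones((3, 3, 1), bool))
        assert res.tsnr == pytest.approx(course.mean() / course.std(ddof=1), rel=1e-12)
        assert 500 < res.tsnr < 900  # the scale of healthy network tSNR

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        vox = rng.normal(100, 5, size=(4, 4, 2, 50))
        img = _img4d(vox, tr=2.0)
        mask = np.ones((4, 4, 2), bool)
        a = sq.roi_tsnr(img, mask).tsnr
        b = sq.roi_tsnr(_img4d(vox * 10, tr=2.0), mask).tsnr
        assert a == pytest.approx(b, rel=1e-12)

    def test_programmed_tsnr_recovered_in_sampling(self):
        spec = sq.BoldPhantomSpec(
            shape=(10, 10, 6), voxel_dims=(3, 3, 3), tr=2.5, n_volumes=204,
            rois=[sq.BoldRoiSpec(1, (15, 15, 9), (9, 9, 7), 600.0, 3.0)],
            voxel_noise_sd=0.5,
        )
        target = 200.0
        vals = []
        for seed in range(20):
            img, labels, _ = sq.make_bold_phantom(spec, seed)
            vals.append(sq.roi_tsnr(img, labels.mask(1)).tsnr)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - target) < 3 * max(se, 1.0)

    def test_constant_series_rejected(self):
        img = _img4d(np.ones((3, 3, 2, 20)), tr=2.0)
        with pytest.raises(ValueError):
            sq.roi_tsnr(img, np.ones((3, 3, 2), bool))


class TestPipeline:
    def test_pipeline_beats_raw_under_drift(self):
        spec = sq.BoldPhantomSpec(
            shape=(10, 10, 6), voxel_dims=(3, 3, 3), tr=2.5, n_volumes=120,
            rois=[sq.BoldRoiSpec(1, (15, 15, 9), (9, 9, 7), 500.0, 2.0)],
            drift_amplitude=6.0, drift_period_s=300.0, voxel_noise_sd=0.5,
        )
        img, labels, motion = sq.make_bold_phantom(spec, 0)
        raw = sq.roi_tsnr(sq.discard_initial_volumes(img, 4), labels.mask(1)).tsnr
        pre = sq.preprocess_bold(img, sq.PreprocConfig(), motion=motion)
        piped = sq.roi_tsnr(pre, labels.mask(1)).tsnr
        assert piped > raw

    def test_roi_mean_preserved_within_0p1_percent(self):
        # ROI embedded in tissue of the same mean level: the temporal steps
        # preserve the mean exactly and smoothing has no edge contrast to mix
        spec = sq.BoldPhantomSpec(
            shape=(10, 10, 6), voxel_dims=(3, 3, 3), tr=2.5, n_volumes=120,
            rois=[sq.BoldRoiSpec(1, (15, 15, 9), (9, 9, 7), 0.0, 2.0)],
            drift_amplitude=4.0, voxel_noise_sd=0.5, background_intensity=500.0,
        )
        img, labels, motion = sq.make_bold_phantom(spec, 1)
        pre = sq.preprocess_bold(img, sq.PreprocConfig(), motion=motion)
        raw_mean = sq.roi_tsnr(sq.discard_initial_volumes(img, 4), labels.mask(1)).mean
        pre_mean = sq.roi_tsnr(pre, labels.mask(1)).mean
        assert pre_mean == pytest.approx(raw_mean, rel=2e-3)


class TestDisplacement:
    def test_zero_trace(self):
        trace = sq.MotionTrace(np.zeros((10, 6)))
        assert sq.max_adjacent_displacement(trace).max_translation_mm == 0.0

    def test_3_4_5_triangle(self):
        params = np.zeros((2, 6))
        params[1, 3:] = [0.3, 0.0, 0.4]
        res = sq.max_adjacent_displacement(sq.MotionTrace(params))
        assert res.max_translation_mm == pytest.approx(0.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        params = rng.normal(scale=0.3, size=(25, 6))
        res = sq.max_adjacent_displacement(sq.MotionTrace(params))
        best = 0.0
        for i in range(1, 25):
            d = params[i, 3:] - params[i - 1, 3:]
            best = max(best, float(np.sqrt((d**2).sum())))
        assert res.max_translation_mm == pytest.approx(best, rel=1e-12)

    def test_single_volume_rejected(self):
        with pytest.raises(ValueError):
            sq.max_adjacent_displacement(sq.MotionTrace(np.zeros((1, 6))))
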