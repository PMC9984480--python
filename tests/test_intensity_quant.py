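"""Intensity normalization, superpixels, frequency maps and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from curvescape.intensity_quant import (
    IntensityRaster, build_frequency_map, intensity_heatmap,
    intensity_vs_distance, intensity_vs_kappa2_sign, mannwhitney_by_sign,
    max_intensity_projection, normalize_intensity, rasterize_superpixels,
    register_roi, roi_mean_intensity_compare)
from curvescape.projection_maps import DistanceMap


def make_dmap(delta, px=1.0):
    delta = np.asarray(delta, float)
    return DistanceMap(delta, delta, delta, px)


class TestNormalize:
    def test_constant_image_becomes_one(self):
        out = normalize_intensity(np.full((8, 8), 3.7))
        assert np.allclose(out, 1.0)

    def test_mean_two_halved_and_idempotent(self):
        img = np.array([[1.0, 3.0]])
        out = normalize_intensity(img)
        assert np.allclose(out, [[0.5, 1.5]])
        assert np.allclose(normalize_intensity(out), out)

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.zeros((4, 4)))


class TestSuperpixels:
    def test_size_one_is_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(rasterize_superpixels(img, 1).values, img)

    def test_checkerboard_blocks_average_to_one(self):
        img = np.indices((160, 160)).sum(axis=0) % 2 * 2.0
        r = rasterize_superpixels(img, 80)
        assert np.allclose(r.values, 1.0)

    def test_mean_conserved_for_divisible_shapes(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(160, 240))
        r = rasterize_superpixels(img, 80)
        assert np.isclose(r.values.mean(), img.mean())

    def test_partial_blocks_dropped(self):
        img = np.ones((85, 81))
        assert rasterize_superpixels(img, 80).shape == (1, 1)

    def test_oversized_block_rejected(self):
        with pytest.raises(ValueError):
            rasterize_superpixels(np.ones((10, 10)), 80)


class TestRegisterROI:
    def test_axis_aligned_pure_crop(self):
        img = np.arange(100.0).reshape(10, 10)
        roi = register_roi(img, (2, 3), (4, 3))
        assert np.array_equal(roi, img[2:6, 3:6])

    def test_wide_roi_transposed_to_vertical(self):
        img = np.arange(100.0).reshape(10, 10)
        roi = register_roi(img, (0, 0), (3, 8))
        assert roi.shape == (8, 3)

    def test_outside_image_rejected(self):
        with pytest.raises(ValueError):
            register_roi(np.ones((10, 10)), (5, 5), (10, 2))

    def test_registration_correlation_peaks_at_zero_offset(self):
        rng = np.random.default_rng(3)
        scene = rng.uniform(size=(64, 64))
        roi = register_roi(scene, (16, 16), (32, 32))
        # cross-correlate the crop against the scene: best match at (16,16)
        from scipy.signal import correlate2d
        c = correlate2d(scene - scene.mean(), roi - roi.mean(), mode="valid")
        assert np.unravel_index(np.argmax(c), c.shape) == (16, 16)


class TestFrequencyMap:
    def test_single_unit_single_image_is_normalized_image(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 2, size=(50, 40))
        fm = build_frequency_map([img], unit_rows=50)
        assert np.allclose(fm.values, normalize_intensity(img))

    def test_k_identical_units_sum_linearly(self):
        unit = np.random.default_rng(1).uniform(1, 2, size=(20, 30))
        img = np.tile(unit, (4, 1))
        fm = build_frequency_map([img], unit_rows=20)
        assert np.allclose(fm.values, 4 * normalize_intensity(img)[:20])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        imgs = [rng.uniform(1, 2, size=(40, 30)) for _ in range(3)]
        a = build_frequency_map(imgs, 20).values
        b = build_frequency_map(imgs[::-1], 20).values
        assert np.allclose(a, b)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        imgs = [rng.uniform(1, 2, size=(40, 30)) for _ in range(2)]
        a = build_frequency_map(imgs, 20).values
        b = build_frequency_map([7.5 * im for im in imgs], 20).values
        assert np.allclose(a, b)

    def test_hotspot_at_fixed_phase_dominates(self):
        rng = np.random.default_rng(5)
        imgs = []
        for _ in range(5):
            im = rng.uniform(0.5, 1.0, size=(60, 20))
            for k in range(3):
                im[k * 20 + 12:k * 20 + 16, 8:12] += 5.0  # same phase each unit
            imgs.append(im)
        fm = build_frequency_map(imgs, 20)
        iy, ix = np.unravel_index(np.argmax(fm.values), fm.values.shape)
        assert 12 <= iy < 16 and 8 <= ix < 12

    def test_incommensurate_unit_rejected_with_crop_hint(self):
        with pytest.raises(ValueError, match="crop to 40"):
            build_frequency_map([np.ones((45, 10))], 20)


class TestIntensityVsSign:
    def test_planted_concave_enrichment_detected(self):
        rng = np.random.default_rng(0)
        sign = rng.choice([-1, 0, 1], size=(40, 40))
        raster = IntensityRaster(
            1.0 + (sign == -1) + rng.normal(0, 0.1, sign.shape), 80)
        table = intensity_vs_kappa2_sign(raster, sign, n_samples=100, seed=0)
        med = table.groupby("sign")["intensity"].median()
        assert med[-1] > med[1]
        res = mannwhitney_by_sign(table)
        assert res.pvalue < 1e-6

    def test_type_one_error_calibrated(self):
        # identical distributions: the test should be non-significant at
        # alpha = 0.05 in at least 90% of seeded runs
        rng = np.random.default_rng(42)
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            sign = np.repeat([-1, 1], 200).reshape(20, 20)
            raster = IntensityRaster(rng.normal(1, 0.2, (20, 20)), 80)
            table = intensity_vs_kappa2_sign(raster, sign, n_samples=100,
                                             seed=rep)
            if mannwhitney_by_sign(table).pvalue < 0.05:
                rejections += 1
        assert rejections / n_reps <= 0.10

    def test_zero_samples_empty(self):
        raster = IntensityRaster(np.ones((4, 4)), 80)
        table = intensity_vs_kappa2_sign(raster, np.zeros((4, 4), int),
                                         n_samples=0)
        assert len(table) == 0

    def test_small_category_sampled_fully_with_warning(self):
        sign = np.zeros((4, 4), int)
        sign[0, 0] = -1
        raster = IntensityRaster(np.ones((4, 4)), 80)
        with pytest.warns(UserWarning):
            table = intensity_vs_kappa2_sign(raster, sign, n_samples=10)
        assert (table["sign"] == -1).sum() == 1

    def test_seeded_sampling_reproducible(self):
        rng = np.random.default_rng(1)
        raster = IntensityRaster(rng.uniform(size=(30, 30)), 80)
        sign = rng.choice([-1, 0, 1], size=(30, 30))
        a = intensity_vs_kappa2_sign(raster, sign, seed=7)
        b = intensity_vs_kappa2_sign(raster, sign, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestHeatmap:
    def test_only_upper_half_plane_populated(self):
        rng = np.random.default_rng(0)
        k2 = rng.uniform(-1, 1, (30, 30))
        k1 = k2 + rng.uniform(0, 1, (30, 30))
        raster = IntensityRaster(rng.uniform(size=(30, 30)), 20)
        hm, e1, e2 = intensity_heatmap(raster, k1, k2, bins=10)
        c1 = 0.5 * (e1[:-1] + e1[1:])
        c2 = 0.5 * (e2[:-1] + e2[1:])
        occupied = np.argwhere(np.isfinite(hm))
        bw = max(e1[1] - e1[0], e2[1] - e2[0])
        assert all(c1[i] >= c2[j] - 2 * bw for i, j in occupied)

    def test_intensity_function_of_kappa2_gives_constant_rows(self):
        rng = np.random.default_rng(1)
        k2 = rng.uniform(-1, 1, (40, 40))
        k1 = k2 + rng.uniform(0, 2, (40, 40))
        raster = IntensityRaster(2.0 + np.sin(3 * k2), 20)
        hm, e1, e2 = intensity_heatmap(raster, k1, k2, bins=12)
        # within each kappa2 column the median must not vary with kappa1
        for j in range(hm.shape[1]):
            col = hm[:, j][np.isfinite(hm[:, j])]
            if col.size >= 2:
                lo = 2.0 + np.sin(3 * e2[j])
                hi = 2.0 + np.sin(3 * e2[j + 1])
                spread = abs(hi - lo) + 1e-9
                assert np.ptp(col) <= spread

    def test_single_curvature_substrate_occupies_one_cell_region(self):
        raster = IntensityRaster(np.ones((10, 10)), 20)
        hm, _, _ = intensity_heatmap(raster, np.full((10, 10), 1.0),
                                     np.full((10, 10), 1.0), bins=5)
        assert np.isfinite(hm).sum() == 1


class TestIntensityVsDistance:
    def test_noiseless_decay_gives_r_minus_one(self):
        rng = np.random.default_rng(0)
        delta = rng.uniform(0, 50, size=(40, 40))
        raster = IntensityRaster(np.exp(-delta / 20.0), 1)
        _, _, (rho, p) = intensity_vs_distance(raster, make_dmap(delta))
        assert rho == pytest.approx(-1.0)

    def test_null_small_r_at_n_1000(self):
        rng = np.random.default_rng(7)
        delta = rng.uniform(0, 50, size=(40, 25))
        raster = IntensityRaster(rng.normal(1, 0.1, (40, 25)), 1)
        _, _, (rho, p) = intensity_vs_distance(raster, make_dmap(delta))
        assert abs(rho) < 0.1

    def test_toy_spearman_half(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 1.0, 3.0])
        assert stats.spearmanr(x, y).statistic == pytest.approx(0.5)
        raster = IntensityRaster(y[None, :], 1)
        _, _, (rho, _) = intensity_vs_distance(raster, make_dmap(x[None, :]))
        assert rho == pytest.approx(0.5)

    def test_constant_intensity_r_undefined(self):
        raster = IntensityRaster(np.ones((5, 5)), 1)
        _, _, (rho, p) = intensity_vs_distance(
            raster, make_dmap(np.arange(25.0).reshape(5, 5)))
        assert np.isnan(rho)

    def test_binned_medians_track_decay(self):
        rng = np.random.default_rng(1)
        delta = rng.uniform(0, 60, size=(50, 50))
        raster = IntensityRaster(np.exp(-delta / 15.0), 1)
        _, binned, _ = intensity_vs_distance(raster, make_dmap(delta),
                                             bin_width=2.0)
        assert (np.diff(binned["median"]) < 0).mean() > 0.95

    def test_planted_decay_length_recovered(self):
        # exponential decay at SNR 5 over >= 500 superpixels: fitted decay
        # length within 20% of truth
        rng = np.random.default_rng(11)
        lam_true = 20.0
        delta = rng.uniform(0, 80, size=(25, 25))
        signal = np.exp(-delta / lam_true)
        noisy = signal * (1 + rng.normal(0, 0.2, delta.shape))
        raster = IntensityRaster(noisy, 1)
        pairs, _, _ = intensity_vs_distance(raster, make_dmap(delta))
        from scipy.optimize import curve_fit
        popt, _ = curve_fit(lambda d, a, lam: a * np.exp(-d / lam),
                            pairs["delta"], pairs["intensity"], p0=(1, 10))
        assert abs(popt[1] - lam_true) / lam_true < 0.2


class TestRoiCompare:
    def test_identical_rois_normalize_to_one(self):
        img = np.ones((50, 50))
        t = roi_mean_intensity_compare(img, [(0, 0, 10), (20, 20, 10)],
                                       ["neg", "pos"])
        assert np.allclose(t["intensity"], 1.0)

    def test_means_one_and_three_give_half_and_three_halves(self):
        img = np.zeros((40, 40))
        img[0:10, 0:10] = 1.0
        img[20:30, 20:30] = 3.0
        t = roi_mean_intensity_compare(img, [(0, 0, 10), (20, 20, 10)],
                                       ["a", "b"])
        assert np.allclose(sorted(t["intensity"]), [0.5, 1.5])

    def test_overlap_warns(self):
        with pytest.warns(UserWarning):
            roi_mean_intensity_compare(np.ones((20, 20)),
                                       [(0, 0, 10), (5, 5, 10)], ["a", "b"])

    def test_brighter_concave_rois_detected(self):
        rng = np.random.default_rng(0)
        img = rng.normal(1.0, 0.05, (200, 200))
        rois, labels = [], []
        for i in range(4):
            r, c = 10 + 45 * i, 10
            img[r:r + 20, c:c + 20] += 0.5      # concave-labeled, brighter
            rois.append((r, c, 20)); labels.append(-1)
            rois.append((r, c + 100, 20)); labels.append(1)
        t = roi_mean_intensity_compare(img, rois, labels)
        g = t.groupby("label")["intensity"].mean()
        assert g[-1] > g[1]

    def test_single_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_mean_intensity_compare(np.ones((10, 10)), [(0, 0, 5)], ["a"])


class TestProjection:
    def test_mip_of_stack(self):
        stack = np.zeros((3, 4, 4))
        stack[1, 2, 2] = 5.0
        assert max_intensity_projection(stack)[2, 2] == 5.0
        with pytest.raises(ValueError):
            max_intensity_projection(np.zeros((4, 4)))
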