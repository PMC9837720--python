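import numpy as np
import pandas as pd
import pytest

from osteoscan.image_io import GeometryError, VolumeGrid
from osteoscan.mri_bone_fat import (
    MriPair,
    bvtv_mri,
    classify_bone,
    estimate_noise_floor,
    estimate_threshold,
    fat_fraction,
    pooled_stats,
)
from osteoscan.roi import RoiSet


def make_pair(pdw, pdw_fs, spacing=(1.0, 1.0, 1.0)):
    return MriPair(
        pdw=VolumeGrid(np.asarray(pdw, dtype=np.float64), spacing, "MRI_PDW",
                       dtype_range=(0, 255)),
        pdw_fs=VolumeGrid(np.asarray(pdw_fs, dtype=np.float64), spacing, "MRI_PDW_FS",
                          dtype_range=(0, 255)),
    )


def full_roi(shape3d):
    masks = {k: np.ones(shape3d[1:], dtype=bool) for k in range(shape3d[0])}
    status = {k: "drawn" for k in range(shape3d[0])}
    return RoiSet(0, shape3d[0] - 1, masks=masks, status=status)


class TestClassifyBone:
    def test_exhaustive_3x3_enumeration(self):
        pdw = [[[10, 60, 40], [50, 49, 51], [0, 255, 30]]]
        fs = [[[45, 20, 60], [49, 50, 10], [0, 255, 49]]]
        pair = make_pair(pdw, fs)
        seg = classify_bone(pair, 50.0)
        expected = (np.array(pdw) < 50) & (np.array(fs) < 50)
        np.testing.assert_array_equal(seg.bone_mask.voxels.astype(bool), expected)

    def test_threshold_below_minimum_gives_empty_mask(self):
        pair = make_pair(np.full((1, 4, 4), 10.0), np.full((1, 4, 4), 20.0))
        assert classify_bone(pair, 5.0).bone_mask.voxels.sum() == 0

    def test_threshold_above_maximum_gives_full_mask(self):
        pair = make_pair(np.full((1, 4, 4), 10.0), np.full((1, 4, 4), 20.0))
        assert classify_bone(pair, 255.0).bone_mask.voxels.all()

    def test_monotone_in_threshold(self, rng):
        pair = make_pair(rng.random((2, 8, 8)) * 200, rng.random((2, 8, 8)) * 200)
        prev = classify_bone(pair, 10.0).bone_mask.voxels
        for t in (50.0, 100.0, 150.0, 200.0):
            cur = classify_bone(pair, t).bone_mask.voxels
            assert (prev <= cur).all()
            prev = cur

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            MriPair(
                pdw=VolumeGrid(np.zeros((2, 4, 4)), (1, 1, 1), "MRI_PDW"),
                pdw_fs=VolumeGrid(np.zeros((2, 4, 5)), (1, 1, 1), "MRI_PDW_FS"),
            )


class TestEstimateThreshold:
    def test_bimodal_histogram_threshold_between_modes(self, rng):
        lo = rng.normal(20, 25, 2048)
        hi = rng.normal(200, 25, 2048)
        img = np.clip(np.concatenate([lo, hi]).reshape(1, 64, 64), 0, 255)
        pair = make_pair(img, img)
        t = estimate_threshold(pair, "otsu_min")
        assert 60 <= t <= 160

    def test_fixed_returns_value(self):
        pair = make_pair(np.zeros((1, 4, 4)), np.zeros((1, 4, 4)))
        assert estimate_threshold(pair, "fixed", fixed_value=75.0) == 75.0

    def test_constant_image_rejected(self):
        pair = make_pair(np.full((1, 4, 4), 7.0), np.full((1, 4, 4), 7.0))
        with pytest.raises(ValueError):
            estimate_threshold(pair, "otsu_min")


class TestBvTv:
    def test_counting_oracle_one_slice(self):
        pdw = np.full((1, 4, 4), 100.0)
        pdw[0, :2, :2] = 10.0  # 4 bone pixels out of 16
        pair = make_pair(pdw, pdw)
        seg = classify_bone(pair, 50.0)
        res = bvtv_mri(seg, full_roi((1, 4, 4)))
        assert (res.bone_pixels, res.roi_pixels) == (4, 16)
        assert res.bvtv_percent == 25.0

    def test_pooled_counts_not_mean_of_percentages(self):
        # slices of unequal ROI size: 10/100 and 90/300 -> pooled 25.0%
        pdw = np.full((2, 20, 20), 100.0)
        pdw[0].flat[:10] = 0.0
        pdw[1].flat[:90] = 0.0
        pair = make_pair(pdw, pdw)
        seg = classify_bone(pair, 50.0)
        m0 = np.zeros((20, 20), dtype=bool)
        m0.flat[:100] = True
        m1 = np.zeros((20, 20), dtype=bool)
        m1.flat[:300] = True
        roi = RoiSet(0, 1, masks={0: m0, 1: m1}, status={0: "drawn", 1: "drawn"})
        res = bvtv_mri(seg, roi)
        assert res.bvtv_percent == 25.0
        per_slice = res.per_slice.set_index("slice")["bvtv_percent"]
        assert per_slice[0] == 10.0 and per_slice[1] == 30.0

    def test_bone_covers_roi_gives_100(self):
        pair = make_pair(np.zeros((1, 4, 4)), np.zeros((1, 4, 4)))
        seg = classify_bone(pair, 1.0)
        assert bvtv_mri(seg, full_roi((1, 4, 4))).bvtv_percent == 100.0

    def test_empty_roi_undefined(self):
        pair = make_pair(np.zeros((2, 4, 4)), np.zeros((2, 4, 4)))
        seg = classify_bone(pair, 1.0)
        roi = RoiSet(0, 0, masks={}, status={0: "empty"})
        with pytest.raises(ZeroDivisionError):
            bvtv_mri(seg, roi)


class TestFatFraction:
    def test_equal_scans_give_zero(self):
        pdw = np.full((1, 6, 6), 120.0)
        pair = make_pair(pdw, pdw.copy())
        seg = classify_bone(pair, 1.0)
        res = fat_fraction(pair, seg, full_roi((1, 6, 6)), noise_floor=1.0)
        assert res.sample_mean == 0.0 and res.sample_sd == 0.0

    def test_zero_water_gives_one(self):
        pair = make_pair(np.full((1, 6, 6), 120.0), np.zeros((1, 6, 6)))
        seg = classify_bone(pair, 1.0)
        res = fat_fraction(pair, seg, full_roi((1, 6, 6)), noise_floor=1.0)
        assert res.sample_mean == 1.0

    def test_single_pixel_arithmetic(self):
        pdw = np.full((1, 2, 2), 100.0)
        fs = np.full((1, 2, 2), 60.0)
        pair = make_pair(pdw, fs)
        seg = classify_bone(pair, 1.0)
        res = fat_fraction(pair, seg, full_roi((1, 2, 2)), noise_floor=1.0)
        assert res.sample_mean == pytest.approx(0.4)

    def test_pooling_matches_concatenation_small_case(self):
        # pixels {0.2, 0.4} on slice 0 and {0.8} on slice 1
        pdw = np.full((2, 1, 2), 100.0)
        fs = np.array([[[80.0, 60.0]], [[20.0, 0.0]]])
        m0 = np.array([[True, True]])
        m1 = np.array([[True, False]])
        pair = make_pair(pdw, fs)
        seg = classify_bone(pair, 1.0)
        roi = RoiSet(0, 1, masks={0: m0, 1: m1}, status={0: "drawn", 1: "drawn"})
        res = fat_fraction(pair, seg, roi, noise_floor=1.0)
        vals = np.array([0.2, 0.4, 0.8])
        assert res.sample_mean == pytest.approx(vals.mean(), abs=1e-12)
        assert res.sample_sd == pytest.approx(vals.std(), abs=1e-12)
        assert res.n_pixels == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_pooling_matches_concatenation_randomized(self, seed):
        rng = np.random.default_rng(seed)
        n_slices = rng.integers(2, 6)
        shape = (int(n_slices), 12, 12)
        pdw = rng.uniform(50, 200, shape)
        fs = pdw * rng.uniform(0.1, 0.9, shape)
        pair = make_pair(pdw, fs)
        seg = classify_bone(pair, 5.0)
        masks = {}
        status = {}
        for k in range(shape[0]):
            m = rng.random((12, 12)) > rng.uniform(0.2, 0.7)
            m.flat[0] = True  # keep every slice non-empty
            masks[k] = m
            status[k] = "drawn"
        roi = RoiSet(0, shape[0] - 1, masks=masks, status=status)
        res = fat_fraction(pair, seg, roi, noise_floor=0.0)
        concat = res.ff_map[np.isfinite(res.ff_map)]
        assert res.sample_mean == pytest.approx(concat.mean(), abs=1e-10)
        assert res.sample_sd == pytest.approx(concat.std(), abs=1e-10)

    def test_scale_invariance(self, rng):
        pdw = rng.uniform(50, 200, (2, 8, 8))
        fs = pdw * rng.uniform(0.2, 0.8, (2, 8, 8))
        roi = full_roi((2, 8, 8))
        c = 3.7
        res1 = fat_fraction(make_pair(pdw, fs), classify_bone(make_pair(pdw, fs), 5.0),
                            roi, noise_floor=10.0)
        big = make_pair(np.clip(pdw * c, 0, None), fs * c)
        res2 = fat_fraction(big, classify_bone(big, 5.0 * c), roi, noise_floor=10.0 * c)
        assert res2.sample_mean == pytest.approx(res1.sample_mean, abs=1e-12)
        assert res2.sample_sd == pytest.approx(res1.sample_sd, abs=1e-12)

    def test_noise_floor_exclusion_counted(self):
        pdw = np.array([[[100.0, 0.5], [100.0, 0.2]]])
        fs = pdw * 0.5
        pair = make_pair(pdw, fs)
        seg = classify_bone(pair, 0.1)
        res = fat_fraction(pair, seg, full_roi((1, 2, 2)), noise_floor=1.0)
        assert res.n_pixels == 2 and res.n_excluded_noise == 2

    def test_all_excluded_raises(self):
        pdw = np.full((1, 2, 2), 0.5)
        pair = make_pair(pdw, pdw * 0.5)
        seg = classify_bone(pair, 0.1)
        with pytest.raises(ValueError):
            fat_fraction(pair, seg, full_roi((1, 2, 2)), noise_floor=1.0)


class TestPooledStats:
    def test_matches_numpy_on_grouped_data(self, rng):
        groups = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(2, 40))
                  for _ in range(6)]
        per_slice = pd.DataFrame(
            [{"mean": g.mean(), "sd": g.std(), "n": g.size} for g in groups]
        )
        mean, sd, n = pooled_stats(per_slice)
        concat = np.concatenate(groups)
        assert n == concat.size
        assert mean == pytest.approx(concat.mean(), abs=1e-12)
        assert sd == pytest.approx(concat.std(), abs=1e-12)

    def test_sample_variance_variant(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(2, 2, 25)]
        per_slice = pd.DataFrame(
            [{"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size} for g in groups]
        )
        mean, sd, _ = pooled_stats(per_slice, variance="sample")
        concat = np.concatenate(groups)
        assert mean == pytest.approx(concat.mean(), abs=1e-12)
        assert sd == pytest.approx(concat.std(), abs=1e-12)


def test_noise_floor_from_background_patch():
    vol = np.full((2, 16, 16), 100.0)
    vol[0, :8, :8] = 2.0  # flat background corner -> MAD 0
    grid = VolumeGrid(vol, (1, 1, 1), "MRI_PDW")
    assert estimate_noise_floor(grid, patch_px=8) == pytest.approx(2.0)
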