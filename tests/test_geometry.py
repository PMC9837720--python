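import math

import numpy as np
import pytest

from osteoscan.image_io import GeometryError, VolumeGrid
from osteoscan.geometry import (
    DetectionError,
    RigidTransform2D,
    apply_rigid,
    downscale_volume,
    fit_capillary_axis,
    register_slices,
    rotate_volume,
    slices_per_slice,
)


def grid(data, spacing=(1.0, 1.0, 1.0), modality="CT"):
    return VolumeGrid(np.asarray(data), spacing, modality)


class TestDownscale:
    def test_constant_volume_stays_constant(self):
        out = downscale_volume(grid(np.full((10, 10, 10), 7.0)), 5)
        np.testing.assert_allclose(out.voxels, 7.0)
        assert out.shape == (2, 2, 2)
        assert out.spacing_um == (5.0, 5.0, 5.0)

    def test_block_mean_against_loop_oracle(self, rng):
        data = rng.integers(0, 255, (6, 8, 4)).astype(np.float64)
        out = downscale_volume(grid(data), 2)
        for s in range(3):
            for r in range(4):
                for c in range(2):
                    block = data[2 * s : 2 * s + 2, 2 * r : 2 * r + 2, 2 * c : 2 * c + 2]
                    assert out.voxels[s, r, c] == pytest.approx(block.mean())

    def test_trailing_partial_blocks_dropped(self):
        out = downscale_volume(grid(np.zeros((11, 11, 11))), 5)
        assert out.shape == (2, 2, 2)

    def test_voxel_count_reduction_exact_on_multiples(self, rng):
        data = rng.random((8, 8, 8))
        out = downscale_volume(grid(data), 2)
        assert out.voxels.size * 8 == data.size

    def test_factor_too_large(self):
        with pytest.raises(GeometryError):
            downscale_volume(grid(np.zeros((3, 10, 10))), 5)


class TestSliceCorrespondence:
    @pytest.mark.parametrize(
        "thick,gap,pitch,expected",
        [
            (270.0, 90.0, 18.0, 20),  # main paired protocol
            (360.0, 360.0, 90.0, 8),  # axial localizer vs 5x-downscaled CT
            (100.0, 0.0, 100.0, 1),
        ],
    )
    def test_integer_ratios(self, thick, gap, pitch, expected):
        assert slices_per_slice(thick, gap, pitch).fine_per_coarse == expected

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(GeometryError):
            slices_per_slice(270.0, 90.0, 17.0)

    def test_half_open_mapping(self):
        corr = slices_per_slice(270.0, 90.0, 18.0)
        assert list(corr.fine_slices_for(0)) == list(range(0, 20))
        assert list(corr.fine_slices_for(3)) == list(range(60, 80))


class TestRigidTransform:
    def test_identity_is_noop(self, rng):
        img = rng.random((32, 32))
        np.testing.assert_allclose(apply_rigid(img, RigidTransform2D()), img)

    def test_pure_translation_matches_roll(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[5:9, 2:6] = 1
        out = apply_rigid(mask, RigidTransform2D(0.0, 3.0, 0.0), "nearest")
        np.testing.assert_array_equal(out, np.roll(mask, 3, axis=1))

    def test_rotation_roundtrip_smooth_image(self, rng):
        from scipy import ndimage

        img = ndimage.gaussian_filter(rng.random((40, 40)), 3)
        back = apply_rigid(
            apply_rigid(img, RigidTransform2D(angle_deg=90.0)),
            RigidTransform2D(angle_deg=-90.0),
        )
        assert np.abs(back[2:-2, 2:-2] - img[2:-2, 2:-2]).max() < 1e-6

    def test_rotation_sign_single_pixel(self):
        # CCW-positive viewed with rows downward: a pixel right of centre
        # moves up (to lower row index) under a +90 deg rotation
        img = np.zeros((11, 11))
        img[5, 8] = 1.0
        out = apply_rigid(img, RigidTransform2D(angle_deg=90.0), "nearest")
        assert out[2, 5] == 1.0 and out.sum() == 1.0

    def test_nearest_preserves_binary(self, rng):
        mask = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        out = apply_rigid(mask, RigidTransform2D(17.0, 1.2, -0.7), "nearest")
        assert set(np.unique(out)) <= {0, 1}

    @pytest.mark.parametrize("seed", range(5))
    def test_compose_inverse_is_identity(self, seed):
        r = np.random.default_rng(seed)
        t = RigidTransform2D(r.uniform(-180, 180), r.uniform(-9, 9), r.uniform(-9, 9))
        ident = t.compose(t.inverse())
        assert abs(ident.angle_deg) < 1e-9
        assert abs(ident.tx) < 1e-9 and abs(ident.ty) < 1e-9

    def test_json_roundtrip(self, tmp_path):
        t = RigidTransform2D(-3.5, 1.25, 0.5)
        t.to_json(tmp_path / "t.json")
        assert RigidTransform2D.from_json(tmp_path / "t.json") == t


class TestRotateVolume:
    def test_zero_angle_identity(self, rng):
        v = grid(rng.random((3, 16, 16)))
        np.testing.assert_allclose(rotate_volume(v, 0.0).voxels, v.voxels)

    def test_roundtrip_away_from_border(self, rng):
        from scipy import ndimage

        data = ndimage.gaussian_filter(rng.random((2, 32, 32)), 2)
        v = grid(data)
        back = rotate_volume(rotate_volume(v, 25.0), -25.0)
        core = (slice(None), slice(4, -4), slice(4, -4))
        # two bilinear resamplings smooth the image slightly
        np.testing.assert_allclose(back.voxels[core], data[core], atol=0.02)

    def test_counter_rotation_convention(self):
        # the overlay angle N_R is undone: passing +90 applies a -90 rotation,
        # so a pixel right of centre moves DOWN (row index increases)
        data = np.zeros((1, 11, 11))
        data[0, 5, 8] = 1.0
        out = rotate_volume(grid(data), 90.0, "nearest")
        assert out.voxels[0, 8, 5] == 1.0


class TestCapillaryAxis:
    def test_aligned_capillary_near_zero_tilt(self):
        from osteoscan.phantom import PhantomSpec, generate_trabecular, simulate_mri_pair

        spec = PhantomSpec(seed=5)
        pair = simulate_mri_pair(generate_trabecular(spec), spec)
        axis = fit_capillary_axis(pair.pdw, "bright")
        assert abs(axis.tilt_row_deg) < 0.1
        assert abs(axis.tilt_col_deg) < 0.1
        assert axis.n_slices_detected == spec.shape[0]

    def test_ct_dark_walls_detection(self):
        from osteoscan.phantom import PhantomSpec, generate_trabecular, simulate_ct

        spec = PhantomSpec(seed=5)
        ct = simulate_ct(generate_trabecular(spec), spec)
        axis = fit_capillary_axis(ct, "dark_walls")
        assert abs(axis.tilt_row_deg) < 0.1
        assert abs(axis.tilt_col_deg) < 0.1

    def test_known_tilt_recovered(self):
        from osteoscan.phantom import PhantomSpec, generate_trabecular, simulate_mri_pair

        spec = PhantomSpec(seed=5, shape=(32, 80, 80), capillary_tilt_row_deg=3.0)
        pair = simulate_mri_pair(generate_trabecular(spec), spec)
        axis = fit_capillary_axis(pair.pdw, "bright")
        assert axis.tilt_row_deg == pytest.approx(3.0, abs=0.2)
        assert axis.tilt_col_deg == pytest.approx(0.0, abs=0.2)

    def test_noise_only_raises(self, rng):
        vol = grid(rng.normal(10, 1, (16, 32, 32)), modality="MRI_PDW")
        with pytest.raises(DetectionError):
            fit_capillary_axis(vol, "bright")


class TestRegistration:
    def _smooth(self, rng, shape=(96, 96), sigma=3):
        from scipy import ndimage

        return ndimage.gaussian_filter(rng.random(shape), sigma)

    def test_self_registration_is_identity(self, rng):
        img = self._smooth(rng)
        t, score = register_slices(img, img)
        assert (t.angle_deg, t.tx, t.ty) == (0.0, 0.0, 0.0)
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_known_transform_recovered(self, rng):
        t0 = RigidTransform2D(7.0, 4.0, -2.0)
        img = self._smooth(rng)
        fixed = apply_rigid(img, t0)
        rec, score = register_slices(img, fixed)
        assert rec.angle_deg == pytest.approx(7.0, abs=1.0)
        assert rec.tx == pytest.approx(4.0, abs=1.0)
        assert rec.ty == pytest.approx(-2.0, abs=1.0)
        assert score > 0.9

    def test_inverse_consistency_on_phantom_structures(self, misaligned_bundle):
        from osteoscan.geometry import register_stacks
        from osteoscan.pipeline import ct_structure_slice, mri_structure_slice

        bu = misaligned_bundle
        ks = [6, 12, 18]
        ct_imgs = [ct_structure_slice(bu.ct.voxels[k]) for k in ks]
        mri_imgs = [
            mri_structure_slice(bu.mri.pdw.voxels[k], bu.mri.pdw_fs.voxels[k])
            for k in ks
        ]
        fwd, _ = register_stacks(ct_imgs, mri_imgs)
        bwd, _ = register_stacks(mri_imgs, ct_imgs)
        resid = fwd.compose(bwd)
        assert abs(resid.angle_deg) < 1.0
        assert abs(resid.tx) < 1.0 and abs(resid.ty) < 1.0

    def test_uncorrelated_noise_scores_low(self, rng, caplog):
        a = rng.normal(size=(64, 64))
        b = rng.normal(size=(64, 64))
        _, score = register_slices(a, b)
        assert score < 0.2

    def test_empty_bounds_rejected(self, rng):
        img = self._smooth(rng, (32, 32))
        with pytest.raises(ValueError):
            register_slices(img, img, angle_bounds=(5.0, -5.0))
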