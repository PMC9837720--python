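"""Synthetic co-registered CT / dual-MRI trabecular phantoms.

The generator produces everything the pipeline consumes, with known ground
truth: a binary trabecular network at a target bone-volume fraction, a
simulated 8-bit micro-CT stack (bone bright, marrow dark, bright-walled
water-filled capillary fiducial), a simulated PDw / PDw-FS pair (bone =
signal void; marrow PDw = fat + water, PDw-FS = water only; capillary
bright in both), additive noise at a stated SNR, an in-plane fat-shift
displacement of the fat component, and a known rigid in-plane misalignment
between the modalities.

The trabecular network is a thresholded Gaussian random field: white noise
smoothed by an isotropic Gaussian kernel of width ``correlation_length``
and cut at the empirical ``1 − target_bvtv`` quantile, which pins the
realized bone fraction to the target to within one voxel.  It reproduces
the interleaved plate/rod texture and controllable volume fraction of
trabecular bone, not its anisotropy or connectivity statistics.

All outputs are deterministic functions of the spec (including its seed).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_io import VolumeGrid, write_stack
from .geometry import RigidTransform2D, apply_rigid
from .roi import RoiSet, interpolate_rois, save_roi_set

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "sample_mask",
    "generate_trabecular",
    "simulate_ct",
    "simulate_mri_pair",
    "make_misaligned_pair",
    "write_bundle",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic sample.

    Intensities follow the contrast model of the modalities: CT bone 200 vs
    marrow 30 on the 8-bit scale (the standard 75–255 bone window separates
    them cleanly), capillary glass walls saturated at 255 with a visible
    water column, MRI marrow PDw signal 180 with bone as a signal void and
    capillary water at 255.  ``snr`` is foreground signal (CT bone / MRI
    marrow PDw) divided by the additive noise SD; ``math.inf`` disables
    noise.  ``fat_shift_px`` displaces the fat component along the readout
    (column) axis, emulating the chemical-shift artifact at the bandwidth
    used in practice (~1.5 px).
    """

    shape: tuple[int, int, int] = (24, 80, 80)
    spacing_um: tuple[float, float, float] = (90.0, 90.0, 90.0)
    target_bvtv: float = 0.25
    correlation_length: float = 4.0
    marrow_ff: float = 0.6
    ct_bone: float = 200.0
    ct_marrow: float = 30.0
    ct_capillary_wall: float = 255.0
    ct_capillary_water: float = 110.0
    mri_marrow_pdw: float = 180.0
    mri_capillary: float = 255.0
    snr: float = 20.0
    noise_model: str = "gaussian"
    fat_shift_px: float = 1.5
    misalignment: RigidTransform2D = field(default_factory=RigidTransform2D)
    sample_radius_frac: float = 0.33
    capillary_radius_px: float = 4.0
    capillary_wall_px: float = 1.5
    capillary_center: tuple[float, float] = (13.0, 64.0)
    capillary_tilt_row_deg: float = 0.0
    capillary_tilt_col_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_bvtv < 1.0:
            raise ValueError("target_bvtv must be in (0, 1)")
        if not 0.0 <= self.marrow_ff <= 1.0:
            raise ValueError("marrow_ff must be in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


def _rng(spec: PhantomSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def sample_mask(spec: PhantomSpec) -> VolumeGrid:
    """The cylindrical sample region (tissue plug in air), as a MASK volume."""
    _, r, c = spec.shape
    rows = np.arange(r)[:, None]
    cols = np.arange(c)[None, :]
    disk = np.hypot(rows - (r - 1) / 2.0, cols - (c - 1) / 2.0) <= (
        spec.sample_radius_frac * min(r, c)
    )
    vox = np.broadcast_to(disk, spec.shape).astype(np.uint8)
    return VolumeGrid(vox.copy(), spec.spacing_um, "MASK", (0, 1))


def generate_trabecular(spec: PhantomSpec) -> VolumeGrid:
    """Ground-truth bone mask from a thresholded Gaussian random field.

    The field is cut at its empirical ``1 − target_bvtv`` quantile *within
    the cylindrical sample region*, so the realized bone fraction of the
    sample matches the target to within one voxel; everything outside the
    sample is air (neither bone nor marrow).
    """
    rng = _rng(spec, 0)
    fld = ndimage.gaussian_filter(
        rng.standard_normal(spec.shape), sigma=spec.correlation_length
    )
    inside = sample_mask(spec).voxels.astype(bool)
    cut = np.quantile(fld[inside], 1.0 - spec.target_bvtv)
    bone = (fld > cut) & inside
    return VolumeGrid(
        voxels=bone.astype(np.uint8),
        spacing_um=spec.spacing_um,
        modality="MASK",
        dtype_range=(0, 1),
    )


def _capillary_geometry(spec: PhantomSpec):
    """Per-slice capillary centre and in-plane radial distance field."""
    s, r, c = spec.shape
    rows = np.arange(r)[:, None]
    cols = np.arange(c)[None, :]
    mid = (s - 1) / 2.0
    drift_r = math.tan(math.radians(spec.capillary_tilt_row_deg)) * spec.spacing_um[0] / spec.spacing_um[1]
    drift_c = math.tan(math.radians(spec.capillary_tilt_col_deg)) * spec.spacing_um[0] / spec.spacing_um[2]
    for k in range(s):
        r0 = spec.capillary_center[0] + (k - mid) * drift_r
        c0 = spec.capillary_center[1] + (k - mid) * drift_c
        yield k, np.hypot(rows - r0, cols - c0)


def _add_noise(img: np.ndarray, sd: float, rng: np.random.Generator, model: str) -> np.ndarray:
    if sd == 0 or not np.isfinite(sd):
        return img
    if model == "rician":
        return np.hypot(img + rng.normal(0, sd, img.shape), rng.normal(0, sd, img.shape))
    return img + rng.normal(0, sd, img.shape)


def simulate_ct(bone: VolumeGrid, spec: PhantomSpec) -> VolumeGrid:
    """8-bit CT stack: bone bright, marrow dark, air black, bright-walled capillary."""
    inside = sample_mask(spec).voxels.astype(bool)
    img = np.where(bone.voxels > 0, spec.ct_bone, np.where(inside, spec.ct_marrow, 0.0))
    rad = spec.capillary_radius_px
    for k, dist in _capillary_geometry(spec):
        img[k][dist <= rad] = spec.ct_capillary_water
        img[k][(dist > rad) & (dist <= rad + spec.capillary_wall_px)] = spec.ct_capillary_wall
    sd = spec.ct_bone / spec.snr if np.isfinite(spec.snr) else 0.0
    img = _add_noise(img, sd, _rng(spec, 1), spec.noise_model)
    return VolumeGrid(
        voxels=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        spacing_um=bone.spacing_um,
        modality="CT",
        dtype_range=(0, 255),
    )


def simulate_mri_pair(bone: VolumeGrid, spec: PhantomSpec):
    """PDw / PDw-FS pair on the same grid as the bone mask.

    Marrow PDw signal splits into water ``(1 − marrow_ff)`` and fat
    ``marrow_ff`` components; the fat component is displaced by
    ``fat_shift_px`` along columns before summation; bone contributes no
    signal; the capillary water column is bright in both scans.  Returns an
    :class:`osteoscan.mri_bone_fat.MriPair`.
    """
    from .mri_bone_fat import MriPair  # local import to avoid a cycle

    marrow = (bone.voxels == 0) & sample_mask(spec).voxels.astype(bool)
    water = np.where(marrow, spec.mri_marrow_pdw * (1.0 - spec.marrow_ff), 0.0)
    fat = np.where(marrow, spec.mri_marrow_pdw * spec.marrow_ff, 0.0)
    if spec.fat_shift_px != 0.0:
        fat = ndimage.shift(
            fat, (0.0, 0.0, spec.fat_shift_px), order=1, mode="constant", cval=0.0
        )
    pdw = water + fat
    pdw_fs = water.copy()
    rad = spec.capillary_radius_px
    for k, dist in _capillary_geometry(spec):
        inside = dist <= rad
        pdw[k][inside] = spec.mri_capillary
        pdw_fs[k][inside] = spec.mri_capillary
    sd = spec.mri_marrow_pdw / spec.snr if np.isfinite(spec.snr) else 0.0
    pdw = _add_noise(pdw, sd, _rng(spec, 2), spec.noise_model)
    pdw_fs = _add_noise(pdw_fs, sd, _rng(spec, 3), spec.noise_model)
    mk = lambda v, mod: VolumeGrid(
        voxels=np.clip(v, 0.0, None).astype(np.float32),
        spacing_um=bone.spacing_um,
        modality=mod,
        dtype_range=(0.0, 255.0),
    )
    return MriPair(pdw=mk(pdw, "MRI_PDW"), pdw_fs=mk(pdw_fs, "MRI_PDW_FS"))


def _truth_roi(spec: PhantomSpec) -> RoiSet:
    """Circular ROI centred in the sample, clear of the capillary.

    Drawn on two anchor slices near the stack ends, interpolated between,
    empty terminators just outside — the same bookkeeping a hand-drawn ROI
    set uses.
    """
    s, r, c = spec.shape
    rows = np.arange(r)[:, None]
    cols = np.arange(c)[None, :]
    # keep the conventional >= 0.5 mm margin from the sample edge
    margin_px = math.ceil(500.0 / spec.spacing_um[1]) + 1
    radius = spec.sample_radius_frac * min(r, c) - margin_px
    if radius < 3:
        raise ValueError("phantom too small for an ROI with a 0.5 mm edge margin")
    disk = np.hypot(rows - (r - 1) / 2.0, cols - (c - 1) / 2.0) <= radius
    first, last = 2, s - 3
    if last <= first:
        raise ValueError("phantom too thin for an ROI (need >= 6 slices)")
    return interpolate_rois(
        {first: disk, last: disk},
        empty_bounds=(first - 1, last + 1),
        pixel_pitch_um=spec.spacing_um[1],
    )


@dataclass
class PhantomBundle:
    """One misaligned phantom sample with its ground truth.

    ``ct`` carries the in-plane misalignment ``true_transform`` relative to
    the MRI pair (which sits on the truth grid); ``roi_ct`` is the truth ROI
    expressed in CT coordinates, as if drawn on the CT stack.  ``manifest``
    records the realized BV/TV inside the ROI, the volume-wide bone
    fraction, and the marrow fat fraction.
    """

    spec: PhantomSpec
    bone_truth: VolumeGrid
    ct: VolumeGrid
    mri: "MriPair"  # noqa: F821
    roi_truth: RoiSet
    roi_ct: RoiSet
    true_transform: RigidTransform2D
    manifest: dict


def make_misaligned_pair(spec: PhantomSpec) -> PhantomBundle:
    """Generate a full co-registered-but-misaligned CT/MRI phantom sample."""
    bone = generate_trabecular(spec)
    mri = simulate_mri_pair(bone, spec)
    ct_aligned = simulate_ct(bone, spec)
    t0 = spec.misalignment
    moved = np.stack(
        [apply_rigid(sl, t0, "bilinear") for sl in ct_aligned.voxels.astype(np.float64)]
    )
    ct = ct_aligned.copy_with(voxels=np.clip(np.rint(moved), 0, 255).astype(np.uint8))
    roi_truth = _truth_roi(spec)
    masks = {}
    status = {}
    for k in roi_truth.slices():
        status[k] = roi_truth.status[k]
        if status[k] != "empty":
            masks[k] = apply_rigid(
                roi_truth.masks[k].astype(np.uint8), t0, "nearest"
            ).astype(bool)
    roi_ct = RoiSet(
        roi_truth.first_slice,
        roi_truth.last_slice,
        masks=masks,
        status=status,
        pixel_pitch_um=roi_truth.pixel_pitch_um,
    )
    roi_bone = 0
    roi_total = 0
    for k in roi_truth.nonempty_slices():
        m = roi_truth.masks[k]
        roi_bone += int(bone.voxels[k][m].sum())
        roi_total += int(m.sum())
    manifest = {
        "bvtv_roi_percent": 100.0 * roi_bone / roi_total,
        "bvtv_volume_percent": 100.0 * float(bone.voxels.mean()),
        "marrow_ff": spec.marrow_ff,
        "true_transform": {"angle_deg": t0.angle_deg, "tx": t0.tx, "ty": t0.ty},
        "seed": spec.seed,
    }
    return PhantomBundle(
        spec=spec,
        bone_truth=bone,
        ct=ct,
        mri=mri,
        roi_truth=roi_truth,
        roi_ct=roi_ct,
        true_transform=t0,
        manifest=manifest,
    )


def write_bundle(bundle: PhantomBundle, out_dir: str | os.PathLike) -> Path:
    """Write a phantom bundle (TIFF stacks, ROI sets, manifest JSON) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(bundle.ct, out / "ct.tif")
    write_stack(bundle.mri.pdw, out / "pdw.tif")
    write_stack(bundle.mri.pdw_fs, out / "pdw_fs.tif")
    write_stack(bundle.bone_truth, out / "bone_truth.tif")
    save_roi_set(bundle.roi_truth, out / "roi_truth.tif")
    save_roi_set(bundle.roi_ct, out / "roi_ct.tif")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1))
    bundle.true_transform.to_json(out / "true_transform.json")
    return out


def replace_spec(spec: PhantomSpec, **kwargs) -> PhantomSpec:
    """Convenience wrapper over dataclasses.replace for frozen specs."""
    return replace(spec, **kwargs)
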