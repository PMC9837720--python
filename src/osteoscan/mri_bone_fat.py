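"""Bone segmentation, BV/TV and proton-density fat fraction from paired MRI.

The method works on a pair of matched proton-density-weighted turbo
spin-echo scans acquired with identical settings except the fat-suppression
module: the PDw image carries fat + water signal, the PDw-FS image water
only, and solid bone is a signal void in both.  Two consequences drive the
analysis:

* **Bone**: a pixel is trabecular bone iff it is darker than a threshold in
  *both* images.  Requiring both scans removes the ambiguity of fat-bright
  pixels that go dark under fat suppression.  BV/TV is the fraction of ROI
  pixels classified as bone, pooled over all ROI slices.
* **Fat fraction**: on soft-tissue pixels (the complement of bone within
  the ROI), the fat signal is the subtraction image PDw − PDw-FS, and the
  proton-density fat fraction is FF = (PDw − PDw-FS) / PDw ∈ [0, 1].
  Sample-level mean and SD are pooled from per-slice summaries with the
  combined-variance identity, which is exact when per-slice variances are
  population (n-weighted) variances — ROI size varies between slices, so
  naive averaging of per-slice means would be biased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .image_io import GeometryError, VolumeGrid
from .roi import RoiSet

logger = logging.getLogger(__name__)

__all__ = [
    "MriPair",
    "BoneSegmentation",
    "BvTvResult",
    "FatFractionResult",
    "classify_bone",
    "estimate_threshold",
    "estimate_noise_floor",
    "bvtv_from_mask",
    "bvtv_mri",
    "fat_fraction",
    "pooled_stats",
]


@dataclass
class MriPair:
    """Co-registered PDw (fat+water) and PDw-FS (water-only) volumes.

    The second scan must be acquired with automatic adjustments (reference
    power, receiver gain) disabled so the two intensity scales match; this
    class checks geometry, not gain.
    """

    pdw: VolumeGrid
    pdw_fs: VolumeGrid

    def __post_init__(self) -> None:
        if self.pdw.shape != self.pdw_fs.shape:
            raise GeometryError(
                f"PDw shape {self.pdw.shape} != PDw-FS shape {self.pdw_fs.shape}"
            )
        if not np.allclose(self.pdw.spacing_um, self.pdw_fs.spacing_um):
            raise GeometryError("PDw and PDw-FS spacing differ")
        if self.pdw.voxels.min() < 0 or self.pdw_fs.voxels.min() < 0:
            raise ValueError("MRI magnitude volumes must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pdw.shape


@dataclass
class BoneSegmentation:
    """A binary bone mask with the threshold and rule that produced it."""

    bone_mask: VolumeGrid
    threshold: float
    rule: str = "pdw < t AND pdw_fs < t"


@dataclass
class BvTvResult:
    """Bone-volume fraction of a region of interest, pooled over slices."""

    bone_pixels: int
    roi_pixels: int
    bvtv_percent: float
    per_slice: pd.DataFrame = field(repr=False, default=None)


@dataclass
class FatFractionResult:
    """Voxel-wise fat-fraction map with pooled sample statistics.

    ``ff_map`` is NaN outside the evaluated (soft-tissue, above-noise, ROI)
    pixels.  ``sample_mean``/``sample_sd`` pool the per-slice summaries
    exactly as if all pixels were concatenated.
    """

    ff_map: np.ndarray = field(repr=False)
    sample_mean: float
    sample_sd: float
    n_pixels: int
    n_excluded_noise: int
    per_slice: pd.DataFrame = field(repr=False, default=None)


def classify_bone(pair: MriPair, threshold: float) -> BoneSegmentation:
    """Classify bone as pixels strictly darker than ``threshold`` in both scans.

    The strict inequality makes the rule reproducible bit-for-bit; the mask
    is monotone non-decreasing in the threshold.
    """
    lo, hi = pair.pdw.dtype_range
    if not (lo <= threshold <= hi):
        raise ValueError(f"threshold {threshold} outside intensity range [{lo}, {hi}]")
    mask = (pair.pdw.voxels < threshold) & (pair.pdw_fs.voxels < threshold)
    vol = VolumeGrid(
        voxels=mask.astype(np.uint8),
        spacing_um=pair.pdw.spacing_um,
        modality="MASK",
        dtype_range=(0, 1),
    )
    return BoneSegmentation(bone_mask=vol, threshold=float(threshold))


def estimate_threshold(
    pair: MriPair,
    method: str = "otsu_min",
    fixed_value: float | None = None,
    foreground: np.ndarray | None = None,
) -> float:
    """Choose the bone/soft-tissue intensity threshold.

    ``otsu_min`` (default) takes the smaller of the Otsu thresholds of the
    two scans — a pilot-scan-free stand-in for a threshold normally tuned on
    pilot data; the conservative minimum avoids eating into soft tissue on
    the fat-suppressed image.  ``fixed`` returns ``fixed_value`` unchanged.
    An optional boolean ``foreground`` restricts the histogram.
    """
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method requires fixed_value")
        return float(fixed_value)
    if method != "otsu_min":
        raise ValueError(f"unknown threshold method {method!r}")
    thresholds = []
    for grid in (pair.pdw, pair.pdw_fs):
        vals = grid.voxels[foreground] if foreground is not None else grid.voxels
        if np.ptp(vals) == 0:
            raise ValueError("cannot estimate a threshold on a constant image")
        thresholds.append(float(threshold_otsu(np.asarray(vals).ravel())))
    t = min(thresholds)
    logger.info("otsu_min threshold: pdw=%.3f pdw_fs=%.3f -> %.3f", *thresholds, t)
    return t


def estimate_noise_floor(
    volume: VolumeGrid, patch_px: int = 8, k: float = 2.0
) -> float:
    """Noise floor from the robust SD of a background corner patch.

    Takes the corner patch (first slice, top-left ``patch_px`` square) as
    air, estimates its SD as 1.4826 × MAD, and returns ``k`` times that (the
    patch median is added so a nonzero background offset is covered).
    """
    patch = volume.voxels[0, :patch_px, :patch_px].astype(np.float64).ravel()
    med = np.median(patch)
    mad = np.median(np.abs(patch - med))
    return float(med + k * 1.4826 * mad)


def _check_roi_in_volume(roi: RoiSet, volume: VolumeGrid) -> None:
    ks = roi.nonempty_slices()
    if ks and (ks[0] < 0 or ks[-1] >= volume.n_slices):
        raise GeometryError(
            f"ROI slices [{ks[0]}, {ks[-1]}] not contained in volume of "
            f"{volume.n_slices} slices"
        )


def bvtv_from_mask(mask: VolumeGrid, roi: RoiSet) -> BvTvResult:
    """BV/TV of a binary bone mask over an ROI set (pooled pixel counts).

    Counts are summed over all non-empty ROI slices before dividing, so
    slices with larger ROIs weigh proportionally more — the pooled fraction,
    not a mean of per-slice percentages.
    """
    _check_roi_in_volume(roi, mask)
    rows = []
    bone = 0
    total = 0
    for k in roi.nonempty_slices():
        m = roi.masks[k]
        b = int((mask.voxels[k].astype(bool) & m).sum())
        n = int(m.sum())
        rows.append({"slice": k, "bone_pixels": b, "roi_pixels": n,
                     "bvtv_percent": 100.0 * b / n if n else np.nan})
        bone += b
        total += n
    if total == 0:
        raise ZeroDivisionError("ROI contains no pixels; BV/TV is undefined")
    return BvTvResult(
        bone_pixels=bone,
        roi_pixels=total,
        bvtv_percent=100.0 * bone / total,
        per_slice=pd.DataFrame(rows, columns=["slice", "bone_pixels", "roi_pixels", "bvtv_percent"]),
    )


def bvtv_mri(seg: BoneSegmentation, roi: RoiSet) -> BvTvResult:
    """BV/TV of an MRI bone segmentation over an ROI set."""
    return bvtv_from_mask(seg.bone_mask, roi)


def pooled_stats(per_slice: pd.DataFrame, variance: str = "population") -> tuple[float, float, int]:
    """Combine per-slice (mean, sd, n) into sample mean and SD.

    Uses the combined-variance identity with n-weighted (population)
    per-slice variances:

        m = Σ nᵢ mᵢ / Σ nᵢ
        s² = [Σ nᵢ (sᵢ² + mᵢ²)] / Σ nᵢ − m²

    which reproduces the statistics of the concatenated pixels exactly.
    Set ``variance="sample"`` if the per-slice ``sd`` column holds n−1
    (sample) standard deviations; they are converted before pooling.
    """
    if variance not in ("population", "sample"):
        raise ValueError("variance must be 'population' or 'sample'")
    n = per_slice["n"].to_numpy(dtype=np.float64)
    m = per_slice["mean"].to_numpy(dtype=np.float64)
    s = per_slice["sd"].to_numpy(dtype=np.float64)
    if variance == "sample":
        s = np.sqrt(s**2 * np.where(n > 0, (n - 1) / np.maximum(n, 1), 0.0))
    ntot = n.sum()
    if ntot == 0:
        raise ValueError("no pixels to pool")
    mean = float((n * m).sum() / ntot)
    var = float((n * (s**2 + m**2)).sum() / ntot - mean**2)
    return mean, float(np.sqrt(max(var, 0.0))), int(ntot)


def fat_fraction(
    pair: MriPair,
    seg: BoneSegmentation,
    roi: RoiSet,
    noise_floor: float | None = None,
) -> FatFractionResult:
    """Voxel-wise proton-density fat fraction on soft-tissue ROI pixels.

    FF = (PDw − PDw-FS) / PDw, clipped to [0, 1]: the PDw image is all
    available (fat + water) signal and the subtraction image isolates fat.
    Bone pixels are excluded (FF is meaningless in a signal void), as are
    pixels with PDw at or below ``noise_floor`` where the ratio is unstable;
    their count is reported.  ``noise_floor=None`` estimates it from a
    background corner patch of the PDw scan.
    """
    if seg.bone_mask.shape != pair.shape:
        raise GeometryError("segmentation does not match the MRI pair")
    _check_roi_in_volume(roi, pair.pdw)
    if noise_floor is None:
        noise_floor = estimate_noise_floor(pair.pdw)
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")

    pdw = pair.pdw.voxels.astype(np.float64)
    pdw_fs = pair.pdw_fs.voxels.astype(np.float64)
    ff_map = np.full(pair.shape, np.nan)
    rows = []
    excluded = 0
    for k in roi.nonempty_slices():
        m = roi.masks[k]
        soft = m & ~seg.bone_mask.voxels[k].astype(bool)
        valid = soft & (pdw[k] > noise_floor)
        excluded += int(soft.sum() - valid.sum())
        ff = np.clip((pdw[k] - pdw_fs[k]) / np.where(pdw[k] > 0, pdw[k], 1.0), 0.0, 1.0)
        ff_map[k][valid] = ff[valid]
        nk = int(valid.sum())
        if nk:
            vals = ff[valid]
            rows.append({"slice": k, "mean": float(vals.mean()),
                         "sd": float(vals.std()), "n": nk})  # population sd
        else:
            rows.append({"slice": k, "mean": np.nan, "sd": np.nan, "n": 0})
    per_slice = pd.DataFrame(rows, columns=["slice", "mean", "sd", "n"])
    usable = per_slice[per_slice["n"] > 0]
    if usable.empty:
        raise ValueError("all ROI pixels were bone or below the noise floor")
    mean, sd, ntot = pooled_stats(usable)
    return FatFractionResult(
        ff_map=ff_map,
        sample_mean=mean,
        sample_sd=sd,
        n_pixels=ntot,
        n_excluded_noise=excluded,
        per_slice=per_slice,
    )
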