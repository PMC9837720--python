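"""Micro-CT binarization and bone-volume-fraction measurement.

Micro-CT is the reference modality: bone attenuates, marrow and fluid do
not, so a fixed intensity window on the 8-bit reconstruction separates the
trabeculae.  The conventional window is the closed interval [75, 255].
BV/TV over an ROI set shares its implementation with the MRI path so the
two modalities are compared on identical pooling arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image_io import VolumeGrid
from .mri_bone_fat import BvTvResult, bvtv_from_mask
from .roi import RoiSet

__all__ = ["binarize_ct", "bvtv_ct"]


def binarize_ct(
    volume: VolumeGrid,
    lo: float = 75,
    hi: float = 255,
    min_component_voxels: int = 0,
) -> VolumeGrid:
    """Threshold a CT volume to a bone mask: ``lo <= value <= hi`` inclusive.

    Defaults reproduce the standard 75–255 window for 8-bit reconstructions.
    No cleanup is applied by default; ``min_component_voxels`` optionally
    removes 3D connected components smaller than the given size
    (despeckling).
    """
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    mask = (volume.voxels >= lo) & (volume.voxels <= hi)
    if min_component_voxels > 0:
        labels, _ = ndimage.label(mask)
        counts = np.bincount(labels.ravel())
        keep = counts >= min_component_voxels
        keep[0] = False
        mask = keep[labels]
    return VolumeGrid(
        voxels=mask.astype(np.uint8),
        spacing_um=volume.spacing_um,
        modality="MASK",
        dtype_range=(0, 1),
    )


def bvtv_ct(mask: VolumeGrid, roi: RoiSet) -> BvTvResult:
    """BV/TV of a binarized CT volume over an ROI set (pooled counts)."""
    if mask.modality != "MASK":
        raise ValueError("bvtv_ct expects a binarized MASK volume; see binarize_ct")
    return bvtv_from_mask(mask, roi)
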