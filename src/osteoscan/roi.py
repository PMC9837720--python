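"""Regions of interest: per-slice masks, inter-slice interpolation, transfer.

An :class:`RoiSet` mirrors how trabecular ROIs are delineated in slice-based
bone analysis: a mask is drawn by hand on a few anchor slices, intermediate
slices are tagged "interpolated" and filled in by shape morphing, and the
first slice beyond each end of the drawn span is tagged "empty" to terminate
the volume of interest.  ROI sets drawn on the (rotation-corrected) CT stack
are transferred to the MRI grid by collapsing each group of fine CT slices
to one coarse MRI slice, downscaling in-plane, and applying the in-plane
rigid transform found during alignment.

The interpolation between drawn masks is linear interpolation of their
signed Euclidean distance transforms — the standard reproducible equivalent
of viewer "interpolated" ROI shapes for nested convex outlines.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .image_io import GeometryError, VolumeGrid
from .geometry import RigidTransform2D, SliceCorrespondence, apply_rigid

__all__ = [
    "RoiSet",
    "DEFAULT_DRAWN_OFFSETS",
    "DEFAULT_EMPTY_OFFSETS",
    "default_schedule",
    "interpolate_rois",
    "check_edge_margin",
    "transfer_roi",
    "save_roi_set",
    "load_roi_set",
]

STATUSES = ("drawn", "interpolated", "empty")

# A typical anchor-slice template, in fine-grid slices relative to the
# middle slice N: hand-drawn at N, N±20, N±40 and N−60, terminated by empty
# shapes at N−61 and N+41.  A template, not a rule — pass your own offsets.
DEFAULT_DRAWN_OFFSETS = (-60, -40, -20, 0, 20, 40)
DEFAULT_EMPTY_OFFSETS = (-61, 41)


def default_schedule(middle_slice: int) -> tuple[tuple[int, ...], tuple[int, int]]:
    """Anchor and terminator slice indices for a given middle slice."""
    drawn = tuple(middle_slice + o for o in DEFAULT_DRAWN_OFFSETS)
    lo, hi = DEFAULT_EMPTY_OFFSETS
    return drawn, (middle_slice + lo, middle_slice + hi)


@dataclass
class RoiSet:
    """Per-slice 2D binary masks over an inclusive slice range.

    Each slice in ``[first_slice, last_slice]`` carries a status: ``drawn``
    (hand-delineated), ``interpolated`` (morphed between drawn anchors) or
    ``empty``.  Drawn/interpolated masks are non-empty; empty slices have no
    mask.  Slices outside the range are implicitly empty.
    """

    first_slice: int
    last_slice: int
    masks: dict[int, np.ndarray] = field(default_factory=dict)
    status: dict[int, str] = field(default_factory=dict)
    pixel_pitch_um: float = 1.0

    def __post_init__(self) -> None:
        if self.last_slice < self.first_slice:
            raise ValueError("last_slice must be >= first_slice")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        for k in range(self.first_slice, self.last_slice + 1):
            st = self.status.get(k, "empty")
            if st not in STATUSES:
                raise ValueError(f"slice {k}: unknown status {st!r}")
            self.status[k] = st
            if st == "empty":
                self.masks.pop(k, None)
            else:
                if k not in self.masks:
                    raise ValueError(f"slice {k} has status {st!r} but no mask")
                m = np.asarray(self.masks[k]).astype(bool)
                if not m.any():
                    raise ValueError(f"slice {k}: {st!r} mask is empty")
                self.masks[k] = m

    @property
    def slice_range(self) -> tuple[int, int]:
        return (self.first_slice, self.last_slice)

    def slices(self) -> list[int]:
        return list(range(self.first_slice, self.last_slice + 1))

    def nonempty_slices(self) -> list[int]:
        return [k for k in self.slices() if self.status[k] != "empty"]

    def mask_or_empty(self, k: int, shape: tuple[int, int]) -> np.ndarray:
        m = self.masks.get(k)
        return m if m is not None else np.zeros(shape, dtype=bool)

    def area_pixels(self) -> int:
        return int(sum(m.sum() for m in self.masks.values()))


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive inside the mask, negative outside (Euclidean, in pixels)."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def interpolate_rois(
    drawn: dict[int, np.ndarray],
    empty_bounds: tuple[int, int],
    pixel_pitch_um: float = 1.0,
) -> RoiSet:
    """Build an RoiSet from drawn anchor masks plus empty terminators.

    Slices strictly between two drawn anchors get status ``interpolated``
    and a mask thresholded at 0 from the slice-index-linear interpolation of
    the bracketing anchors' signed distance transforms.  Slices between the
    outermost anchors and the empty bounds are left empty.
    """
    if len(drawn) < 2:
        raise ValueError("need at least 2 drawn slices to interpolate")
    anchors = sorted(drawn)
    lo, hi = empty_bounds
    if not (lo < anchors[0] and hi > anchors[-1]):
        raise ValueError(
            f"empty bounds {empty_bounds} must lie strictly outside drawn span "
            f"[{anchors[0]}, {anchors[-1]}]"
        )
    shape = np.asarray(drawn[anchors[0]]).shape
    masks: dict[int, np.ndarray] = {}
    status: dict[int, str] = {}
    sdt = {k: _signed_distance(np.asarray(drawn[k]).astype(bool)) for k in anchors}
    for k in anchors:
        if np.asarray(drawn[k]).shape != shape:
            raise ValueError("all drawn masks must share a shape")
        masks[k] = np.asarray(drawn[k]).astype(bool)
        status[k] = "drawn"
    for a, b in zip(anchors[:-1], anchors[1:]):
        for k in range(a + 1, b):
            w = (k - a) / (b - a)
            blend = (1 - w) * sdt[a] + w * sdt[b]
            m = blend >= 0
            if not m.any():  # degenerate: distant tiny anchors may pinch off
                raise ValueError(f"interpolated mask at slice {k} is empty")
            masks[k] = m
            status[k] = "interpolated"
    status[lo] = "empty"
    status[hi] = "empty"
    return RoiSet(lo, hi, masks=masks, status=status, pixel_pitch_um=pixel_pitch_um)


def check_edge_margin(
    roi: RoiSet, sample_mask: VolumeGrid, min_margin_um: float = 500.0
) -> "pd.DataFrame":
    """Distance from each slice's ROI to the sample edge, with flags.

    ROIs are conventionally kept at least 0.5 mm inside the sample boundary
    to avoid fluid infiltration artefacts at the margins.  For every
    non-empty ROI slice, reports the minimum Euclidean distance (μm) from an
    ROI pixel to the background of ``sample_mask``; ROI pixels outside the
    sample count as margin 0.
    """
    import pandas as pd

    if sample_mask.modality != "MASK":
        raise ValueError("sample_mask must be a MASK volume")
    rows = []
    in_plane = sample_mask.spacing_um[1]
    for k in roi.nonempty_slices():
        if not (0 <= k < sample_mask.n_slices):
            raise GeometryError(f"ROI slice {k} outside sample mask volume")
        sample = sample_mask.voxels[k].astype(bool)
        dist = ndimage.distance_transform_edt(sample) * in_plane
        m = roi.masks[k]
        margin = float(dist[m].min()) if m.any() else np.nan
        rows.append(
            {
                "slice": k,
                "min_margin_um": margin,
                "flagged": bool(margin < min_margin_um),
            }
        )
    return pd.DataFrame(rows, columns=["slice", "min_margin_um", "flagged"])


def _block_majority(mask: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return mask.astype(bool)
    r, c = mask.shape[0] // factor, mask.shape[1] // factor
    v = mask[: r * factor, : c * factor].reshape(r, factor, c, factor)
    return v.mean(axis=(1, 3)) >= 0.5


def _fit_shape(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    r = min(shape[0], mask.shape[0])
    c = min(shape[1], mask.shape[1])
    out[:r, :c] = mask[:r, :c]
    return out


def transfer_roi(
    roi: RoiSet,
    transform: RigidTransform2D,
    correspondence: SliceCorrespondence,
    target_shape: tuple[int, int],
    inplane_factor: int = 1,
) -> RoiSet:
    """Carry a fine-grid (CT) ROI set onto the coarse (MRI) grid.

    Each group of ``correspondence.fine_per_coarse`` consecutive CT slices
    (anchored at ``roi.first_slice``) collapses to one MRI slice by
    pixel-wise majority vote (ties count as inside); the result is
    downscaled in-plane by block majority, rigidly transformed with nearest
    interpolation, and cropped/padded to ``target_shape``.  Group status is
    ``drawn`` if any member slice was drawn, else ``interpolated`` if any
    was, else ``empty``.
    """
    n = correspondence.fine_per_coarse
    span = roi.last_slice - roi.first_slice + 1
    if span % n != 0:
        raise GeometryError(
            f"ROI span {span} is not a whole number of groups of {n} fine slices"
        )
    shape = next(iter(roi.masks.values())).shape if roi.masks else target_shape
    out_masks: dict[int, np.ndarray] = {}
    out_status: dict[int, str] = {}
    n_groups = span // n
    for g in range(n_groups):
        members = [roi.first_slice + g * n + j for j in range(n)]
        statuses = [roi.status[k] for k in members]
        votes = np.zeros(shape, dtype=np.int32)
        for k in members:
            votes += roi.mask_or_empty(k, shape).astype(np.int32)
        collapsed = votes * 2 >= n  # majority, ties toward inclusion
        collapsed = _block_majority(collapsed, inplane_factor)
        moved = apply_rigid(collapsed.astype(np.uint8), transform, "nearest") > 0
        moved = _fit_shape(moved, target_shape)
        if "drawn" in statuses and moved.any():
            out_status[g] = "drawn"
        elif "interpolated" in statuses and moved.any():
            out_status[g] = "interpolated"
        else:
            out_status[g] = "empty"
        if out_status[g] != "empty":
            out_masks[g] = moved
    return RoiSet(
        0,
        n_groups - 1,
        masks=out_masks,
        status=out_status,
        pixel_pitch_um=roi.pixel_pitch_um * inplane_factor,
    )


def save_roi_set(roi: RoiSet, path: str | os.PathLike) -> Path:
    """Write an ROI set as an 8-bit mask TIFF stack plus a JSON sidecar."""
    path = Path(path)
    slices = roi.slices()
    if roi.masks:
        shape = next(iter(roi.masks.values())).shape
    else:
        shape = (1, 1)
    stack = np.stack(
        [roi.mask_or_empty(k, shape).astype(np.uint8) for k in slices]
    )
    tifffile.imwrite(str(path), stack, photometric="minisblack")
    meta = {
        "first_slice": roi.first_slice,
        "last_slice": roi.last_slice,
        "status": [roi.status[k] for k in slices],
        "pixel_pitch_um": roi.pixel_pitch_um,
    }
    path.with_suffix(path.suffix + ".roi.json").write_text(json.dumps(meta, indent=1))
    return path


def load_roi_set(path: str | os.PathLike) -> RoiSet:
    """Inverse of :func:`save_roi_set` (lossless roundtrip)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".roi.json")
    try:
        meta = json.loads(sidecar.read_text())
        first = int(meta["first_slice"])
        last = int(meta["last_slice"])
        statuses = list(meta["status"])
        pitch = float(meta["pixel_pitch_um"])
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise OSError(f"corrupt or missing ROI sidecar {sidecar}: {exc}") from exc
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[np.newaxis, ...]
    if len(statuses) != last - first + 1 or stack.shape[0] != len(statuses):
        raise OSError(f"ROI sidecar {sidecar} inconsistent with mask stack")
    masks = {}
    status = {}
    for i, st in enumerate(statuses):
        k = first + i
        status[k] = st
        if st != "empty":
            masks[k] = stack[i].astype(bool)
    return RoiSet(first, last, masks=masks, status=status, pixel_pitch_um=pitch)
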