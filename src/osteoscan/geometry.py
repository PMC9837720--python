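"""Resolution matching and rigid in-plane geometry for CT↔MRI alignment.

The alignment workflow this module supports is fiducial-guided and manual
at heart: a water-filled capillary taped to the sample tube is visible in
both modalities, the CT stack is first rotated so the capillary is parallel
to the stacking axis, downscaled to the MRI pixel pitch, overlaid on an MRI
slice and manually rotated/translated until bone edge and capillary agree.
The overlay angle (``N_R``) is then undone on the CT stack.  Every function
here accepts an explicit user transform; the grid-search registration is an
automated convenience, not a replacement for the manual step.

Conventions
-----------
* Slices are viewed with the row index increasing downward; rotation angles
  are counter-clockwise positive in that view, about the slice centre.
* Translations ``(tx, ty)`` are in pixels of the target grid, ``tx`` along
  columns and ``ty`` along rows.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.registration import phase_cross_correlation

from .image_io import GeometryError, VolumeGrid

__all__ = [
    "RigidTransform2D",
    "SliceCorrespondence",
    "FiducialAxis",
    "DetectionError",
    "downscale_volume",
    "slices_per_slice",
    "apply_rigid",
    "rotate_volume",
    "fit_capillary_axis",
    "register_slices",
    "register_stacks",
]


class DetectionError(RuntimeError):
    """The capillary fiducial could not be located."""


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid transform: rotation about the slice centre, then shift.

    ``angle_deg`` is counter-clockwise positive when the slice is viewed
    with rows increasing downward.  ``tx`` (columns) and ``ty`` (rows) are
    applied after the rotation, in pixels.
    """

    angle_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def _matrix(self) -> np.ndarray:
        # Rotation acting on (x=col, y=row-down) coordinates.  CCW in the
        # displayed image is CW in y-down maths, hence the sign pattern.
        th = math.radians(self.angle_deg)
        return np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])

    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``first``, then ``self``."""
        r = self._matrix()
        t = r @ np.array([first.tx, first.ty]) + np.array([self.tx, self.ty])
        return RigidTransform2D(self.angle_deg + first.angle_deg, float(t[0]), float(t[1]))

    def inverse(self) -> "RigidTransform2D":
        rinv = RigidTransform2D(-self.angle_deg)._matrix()
        t = -(rinv @ np.array([self.tx, self.ty]))
        return RigidTransform2D(-self.angle_deg, float(t[0]), float(t[1]))

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = json.dumps(
            {"angle_deg": self.angle_deg, "tx": self.tx, "ty": self.ty}, indent=1
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | os.PathLike) -> "RigidTransform2D":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(float(d["angle_deg"]), float(d["tx"]), float(d["ty"]))


@dataclass(frozen=True)
class SliceCorrespondence:
    """How many fine-grid (CT) slices one coarse-grid (MRI) slice spans.

    Coarse slice ``k`` maps to fine slices ``[k*n, k*n + n)`` (half-open),
    anchored so that fine slice 0 sits at the front edge of coarse slice 0
    — the front edge of the capillary water column in the acquisition this
    emulates.
    """

    fine_per_coarse: int

    def __post_init__(self) -> None:
        if self.fine_per_coarse < 1:
            raise GeometryError("fine_per_coarse must be >= 1")

    def fine_slices_for(self, coarse_index: int) -> range:
        n = self.fine_per_coarse
        return range(coarse_index * n, coarse_index * n + n)


def slices_per_slice(
    coarse_thickness_um: float, coarse_gap_um: float, fine_pitch_um: float
) -> SliceCorrespondence:
    """Fine slices spanned by one coarse slice: (thickness + gap) / pitch.

    The acquisition is expected to choose resolutions as integer multiples
    of the fine pitch, so a non-integer ratio is a geometry error.  The main
    paired protocol gives (270 + 90)/18 = 20; the axial localizer against
    5×-downscaled CT gives (360 + 360)/90 = 8.
    """
    if min(coarse_thickness_um, fine_pitch_um) <= 0 or coarse_gap_um < 0:
        raise GeometryError("slice thickness and pitch must be positive, gap non-negative")
    ratio = (coarse_thickness_um + coarse_gap_um) / fine_pitch_um
    n = round(ratio)
    if n < 1 or abs(ratio - n) > 1e-6 * max(1.0, ratio):
        raise GeometryError(
            f"coarse pitch {coarse_thickness_um}+{coarse_gap_um} μm is not an integer "
            f"multiple of the fine pitch {fine_pitch_um} μm (ratio {ratio:.6f})"
        )
    return SliceCorrespondence(int(n))


def downscale_volume(volume: VolumeGrid, factor: int) -> VolumeGrid:
    """Block-mean downsample by ``factor`` in all three axes.

    Emulates viewer-style resolution reduction while preserving mean
    intensity.  Trailing voxels that do not fill a complete ``factor³``
    block are dropped; spacing is multiplied by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise GeometryError("factor must be >= 1")
    if any(d < factor for d in volume.shape):
        raise GeometryError(f"factor {factor} exceeds a volume dimension {volume.shape}")
    if factor == 1:
        return volume.copy_with(voxels=volume.voxels.copy())
    s, r, c = (d // factor for d in volume.shape)
    v = volume.voxels[: s * factor, : r * factor, : c * factor].astype(np.float64)
    v = v.reshape(s, factor, r, factor, c, factor).mean(axis=(1, 3, 5))
    out = v.astype(volume.voxels.dtype) if np.issubdtype(volume.voxels.dtype, np.floating) else v
    return VolumeGrid(
        voxels=out,
        spacing_um=tuple(sp * factor for sp in volume.spacing_um),
        modality=volume.modality if volume.modality != "MASK" else "CT",
        dtype_range=volume.dtype_range,
    )


def _inverse_map(transform: RigidTransform2D, shape: tuple[int, int]):
    """(matrix, offset) for scipy affine_transform: output (r,c) → input (r,c)."""
    th = math.radians(transform.angle_deg)
    cos, sin = math.cos(th), math.sin(th)
    rc = (shape[0] - 1) / 2.0
    cc = (shape[1] - 1) / 2.0
    # Forward: [c'; r'] = [[cos, sin], [-sin, cos]] @ [c-cc; r-rc] + [cc+tx; rc+ty]
    # Inverted and rearranged to (row, col) order:
    matrix = np.array([[cos, sin], [-sin, cos]])
    offset = np.array(
        [
            rc - cos * (rc + transform.ty) - sin * (cc + transform.tx),
            cc + sin * (rc + transform.ty) - cos * (cc + transform.tx),
        ]
    )
    return matrix, offset


def apply_rigid(
    slice_image: np.ndarray,
    transform: RigidTransform2D,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Rotate a 2D slice about its centre, then translate.

    ``interpolation`` is ``"bilinear"`` for intensity images or
    ``"nearest"`` for masks (binary-ness is preserved).  Pixels mapped from
    outside the field of view are 0.
    """
    img = np.asarray(slice_image)
    if img.ndim != 2:
        raise ValueError("apply_rigid expects a single 2D slice")
    if not np.isfinite(img).all():
        raise ValueError("slice contains non-finite values")
    orders = {"bilinear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValueError(f"interpolation must be one of {sorted(orders)}")
    matrix, offset = _inverse_map(transform, img.shape)
    out = ndimage.affine_transform(
        img.astype(np.float64), matrix, offset=offset,
        order=orders[interpolation], mode="constant", cval=0.0,
    )
    if interpolation == "nearest" or np.issubdtype(img.dtype, np.integer):
        return np.rint(out).astype(img.dtype)
    return out.astype(img.dtype, copy=False)


def rotate_volume(
    volume: VolumeGrid, overlay_angle_deg: float, interpolation: str = "bilinear"
) -> VolumeGrid:
    """Undo the overlay rotation angle on every slice of a stack.

    The manual alignment step finds the angle ``N_R`` by rotating a CT slice
    over an MRI slice; the stack is then counter-rotated by ``-N_R`` so its
    slices match the MRI orientation.  This function applies that
    counter-rotation: pass the overlay angle as written down.
    """
    t = RigidTransform2D(angle_deg=-overlay_angle_deg)
    out = np.stack([apply_rigid(sl, t, interpolation) for sl in volume.voxels])
    return volume.copy_with(voxels=out)


@dataclass(frozen=True)
class FiducialAxis:
    """A fitted 3D capillary axis with stack-alignment correction angles.

    ``point_um``/``direction`` describe the total-least-squares line through
    the per-slice fiducial centroids in physical (slice, row, col)
    micrometre coordinates.  ``tilt_row_deg``/``tilt_col_deg`` are the
    rotations (about the column and row axes respectively) that would make
    the axis parallel to the slice-stacking axis — what a viewer's
    sagittal/coronal rotations correct.  ``residual_rms_um`` is the RMS
    distance of centroids from the line.
    """

    point_um: tuple[float, float, float]
    direction: tuple[float, float, float]
    tilt_row_deg: float
    tilt_col_deg: float
    residual_rms_um: float
    n_slices_detected: int


def fit_capillary_axis(
    volume: VolumeGrid,
    polarity: str = "bright",
    threshold: float | None = None,
    min_area_px: int = 9,
    min_detected_fraction: float = 0.5,
) -> FiducialAxis:
    """Locate the capillary fiducial and fit its 3D axis.

    The capillary appears as a bright water column on MRI (``polarity
    "bright"``) and as bright glass walls around a resolvable column on an
    overexposed CT reconstruction (``"dark_walls"``; the wall annulus is
    filled before centroiding).  Per slice, the image is lightly smoothed,
    thresholded (default: 90% of the robust volume maximum), and the most
    compact sufficiently-large component is taken as the capillary cross
    section; a second pass keeps, per slice, the component nearest the
    median centroid.  The centroids, in physical coordinates, are fit by
    total least squares (SVD) to a line.
    """
    if polarity not in ("bright", "dark_walls"):
        raise ValueError("polarity must be 'bright' or 'dark_walls'")
    vox = volume.voxels.astype(np.float64)
    if threshold is None:
        # The fiducial (water column / glass walls) is the brightest
        # structure in the stack; cut 85% of the way from the median to a
        # robust maximum so the full cross-section survives the noise.
        hi = np.percentile(vox, 99.9)
        lo = np.percentile(vox, 50.0)
        threshold = lo + 0.85 * (hi - lo)
    centroids: dict[int, tuple[float, float]] = {}
    candidates: dict[int, list] = {}
    for k in range(vox.shape[0]):
        binary = vox[k] > threshold
        if polarity == "dark_walls":
            binary = ndimage.binary_fill_holes(binary)
        labels = measure.label(binary)
        regions = [r for r in measure.regionprops(labels) if r.area >= min_area_px]
        if not regions:
            continue
        candidates[k] = [(r.solidity, r.area, r.centroid) for r in regions]
        best = max(candidates[k], key=lambda t: (t[0], t[1]))
        centroids[k] = best[2]
    if len(centroids) < min_detected_fraction * vox.shape[0]:
        raise DetectionError(
            f"fiducial detected in only {len(centroids)}/{vox.shape[0]} slices"
        )
    med = np.median(np.array(list(centroids.values())), axis=0)
    for k, cands in candidates.items():
        centroids[k] = min(cands, key=lambda t: np.hypot(t[2][0] - med[0], t[2][1] - med[1]))[2]

    sp = volume.spacing_um
    pts = np.array([[k * sp[0], rc[0] * sp[1], rc[1] * sp[2]] for k, rc in centroids.items()])
    centre = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centre, full_matrices=False)
    direction = vt[0]
    if direction[0] < 0:
        direction = -direction
    resid = (pts - centre) - np.outer((pts - centre) @ direction, direction)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    # Tilt of the axis away from the stacking direction, per in-plane axis.
    tilt_row = math.degrees(math.atan2(direction[1], direction[0]))
    tilt_col = math.degrees(math.atan2(direction[2], direction[0]))
    return FiducialAxis(
        point_um=tuple(centre),
        direction=tuple(direction),
        tilt_row_deg=tilt_row,
        tilt_col_deg=tilt_col,
        residual_rms_um=rms,
        n_slices_detected=len(centroids),
    )


def _as_slice_list(x) -> list:
    """Accept a 2D slice, a 3D stack, or a list of 2D slices."""
    arr = np.asarray(x) if not isinstance(x, (list, tuple)) else None
    if arr is not None:
        return [arr] if arr.ndim == 2 else list(arr)
    return list(x)


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    if mask.sum() < 16:
        return -1.0
    x = a[mask].astype(np.float64)
    y = b[mask].astype(np.float64)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return -1.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def register_stacks(
    moving: list[np.ndarray] | np.ndarray,
    fixed: list[np.ndarray] | np.ndarray,
    angle_bounds: tuple[float, float] = (-15.0, 15.0),
    shift_bounds: tuple[float, float] = (-20.0, 20.0),
    angle_step: float = 0.5,
    score_warn_threshold: float = 0.2,
) -> tuple[RigidTransform2D, float]:
    """Grid-search one rigid in-plane transform over paired slice lists.

    The same transform is scored jointly on every (moving, fixed) slice
    pair; passing several slices sharpens the rotation estimate, which on a
    single slice has a small lever arm.  See :func:`register_slices` for the
    search strategy.
    """
    moving = [np.asarray(m, dtype=np.float64) for m in _as_slice_list(moving)]
    fixed = [np.asarray(f, dtype=np.float64) for f in _as_slice_list(fixed)]
    if len(moving) != len(fixed) or not moving:
        raise ValueError("need equal, non-empty moving and fixed slice lists")
    for m, f in zip(moving, fixed):
        if m.shape != f.shape:
            raise ValueError("moving and fixed must share a shape (same pixel pitch)")
    if angle_bounds[0] > angle_bounds[1] or shift_bounds[0] > shift_bounds[1]:
        raise ValueError("empty search bounds")

    from skimage.feature import match_template

    rows, cols = fixed[0].shape
    footprint_src = np.ones((rows, cols))
    dy = np.arange(rows) - rows // 2
    dx = np.arange(cols) - cols // 2
    in_bounds = (
        (dy[:, None] >= shift_bounds[0]) & (dy[:, None] <= shift_bounds[1])
        & (dx[None, :] >= shift_bounds[0]) & (dx[None, :] <= shift_bounds[1])
    )

    def score_at(t: RigidTransform2D) -> float:
        mask = apply_rigid(footprint_src, t, "nearest") > 0
        return float(np.mean([
            _masked_ncc(apply_rigid(m, t), f, mask) for m, f in zip(moving, fixed)
        ]))

    def evaluate(angle: float) -> tuple[float, RigidTransform2D]:
        # translation from the dense normalized cross-correlation map
        # averaged over slices and restricted to the admissible shifts
        surf = 0.0
        for m, f in zip(moving, fixed):
            rot = apply_rigid(m, RigidTransform2D(angle_deg=angle))
            surf = surf + match_template(f, rot, pad_input=True)
        surf = np.where(in_bounds, surf, -np.inf)
        iy, ix = np.unravel_index(np.argmax(surf), surf.shape)
        t = RigidTransform2D(angle, float(dx[ix]), float(dy[iy]))
        return score_at(t), t

    coarse = np.arange(angle_bounds[0], angle_bounds[1] + angle_step / 2, angle_step)
    best_score, best_t = max((evaluate(a) for a in coarse), key=lambda st: st[0])
    fine = best_t.angle_deg + np.arange(-angle_step, angle_step + 1e-9, angle_step / 10)
    fine = fine[(fine >= angle_bounds[0]) & (fine <= angle_bounds[1])]
    for a in fine:
        score, t = evaluate(float(a))
        if score > best_score:
            best_score, best_t = score, t
    # sub-pixel translation polish at the chosen angle
    shift, _, _ = phase_cross_correlation(
        fixed[0], apply_rigid(moving[0], RigidTransform2D(angle_deg=best_t.angle_deg)),
        upsample_factor=20,
    )
    cand = RigidTransform2D(
        best_t.angle_deg,
        float(np.clip(shift[1], *shift_bounds)),
        float(np.clip(shift[0], *shift_bounds)),
    )
    cand_score = score_at(cand)
    if cand_score > best_score:
        best_score, best_t = cand_score, cand
    if best_score < score_warn_threshold:
        import logging

        logging.getLogger(__name__).warning(
            "registration score %.3f below warning threshold %.3f — images may be unrelated",
            best_score, score_warn_threshold,
        )
    return best_t, best_score


def register_slices(
    moving: np.ndarray,
    fixed: np.ndarray,
    angle_bounds: tuple[float, float] = (-15.0, 15.0),
    shift_bounds: tuple[float, float] = (-20.0, 20.0),
    angle_step: float = 0.5,
    score_warn_threshold: float = 0.2,
) -> tuple[RigidTransform2D, float]:
    """Grid-search rigid registration of one slice onto another.

    Returns the transform ``T`` maximizing the masked normalized
    cross-correlation of ``apply_rigid(moving, T)`` with ``fixed``, and the
    achieved score.  For each candidate angle the best translation is taken
    from the bounded full cross-correlation surface; the angle is then
    refined on a 10× finer grid around the coarse optimum and the
    translation polished to sub-pixel precision by phase correlation.  This
    automates a manual overlay step; a user-supplied transform should be
    preferred whenever one exists.  A score below ``score_warn_threshold``
    signals that the images likely share no structure.
    """
    if np.asarray(moving).ndim != 2 or np.asarray(fixed).ndim != 2:
        raise ValueError("register_slices expects single 2D slices")
    return register_stacks(
        [moving], [fixed], angle_bounds, shift_bounds, angle_step,
        score_warn_threshold,
    )
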