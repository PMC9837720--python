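"""Image-stack I/O and scan-geometry bookkeeping.

Volumes are carried as :class:`VolumeGrid`: a 3D array indexed
``(slice, row, col)``, 0-based, origin at the top-left of each slice, plus
voxel spacing in micrometres.  The slice spacing is the slice *pitch*
(slice thickness + interslice gap) so that slice-correspondence arithmetic
between modalities works directly on spacings.

Stacks are stored as multi-page grayscale TIFF (8/16-bit integer or 32-bit
float) or NIfTI-1.  TIFF carries no reliable spacing metadata, so spacing is
supplied by the caller and persisted in a JSON sidecar
(``<stack>.meta.json``).  Intensities are never rescaled on read: downstream
thresholds (e.g. the 75–255 CT binarization window) operate on raw values.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

MODALITIES = ("CT", "MRI_PDW", "MRI_PDW_FS", "MASK")

__all__ = [
    "VolumeGrid",
    "ScanGeometry",
    "GeometryError",
    "read_stack",
    "write_stack",
    "projection_count",
]


class GeometryError(ValueError):
    """Inconsistent scan-geometry parameters."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing and modality metadata.

    Parameters
    ----------
    voxels :
        3D array indexed ``(slice, row, col)``.
    spacing_um :
        ``(slice_pitch, row, col)`` voxel spacing in micrometres.  The slice
        entry is the pitch: slice thickness plus any interslice gap.
    modality :
        One of ``CT``, ``MRI_PDW``, ``MRI_PDW_FS``, ``MASK``.
    dtype_range :
        Nominal intensity range, e.g. ``(0, 255)`` for 8-bit CT.  Defaults to
        the full range of integer dtypes and the data min/max for floats.
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]
    modality: str = "CT"
    dtype_range: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError(
                f"voxels must be a non-empty 3D (slice,row,col) array, got shape {self.voxels.shape}"
            )
        self.spacing_um = tuple(float(s) for s in self.spacing_um)  # type: ignore[assignment]
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing_um must be 3 positive values, got {self.spacing_um}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.modality == "MASK":
            vals = np.unique(self.voxels)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("MASK volumes may contain only {0, 1}")
        if self.dtype_range is None:
            if np.issubdtype(self.voxels.dtype, np.integer):
                info = np.iinfo(self.voxels.dtype)
                self.dtype_range = (float(info.min), float(info.max))
            else:
                self.dtype_range = (float(self.voxels.min()), float(self.voxels.max()))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def copy_with(self, voxels: np.ndarray | None = None, **kwargs) -> "VolumeGrid":
        """Return a new grid sharing metadata, optionally replacing fields."""
        return VolumeGrid(
            voxels=self.voxels if voxels is None else voxels,
            spacing_um=kwargs.get("spacing_um", self.spacing_um),
            modality=kwargs.get("modality", self.modality),
            dtype_range=kwargs.get("dtype_range", self.dtype_range),
        )


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition-geometry constants used for correspondence arithmetic.

    Defaults mirror a typical paired acquisition: 18 μm isotropic micro-CT
    (198° range, 0.4° step) and 90 μm in-plane micro-MRI with 270 μm slices
    plus a 90 μm gap, the CT being downscaled 5× in-plane for alignment.
    """

    angular_range_deg: float = 198.0
    angular_step_deg: float = 0.4
    ct_voxel_um: float = 18.0
    mri_inplane_um: float = 90.0
    mri_slice_um: float = 270.0
    mri_gap_um: float = 90.0
    downscale_factor: int = 5

    def __post_init__(self) -> None:
        if self.downscale_factor < 1:
            raise GeometryError("downscale_factor must be >= 1")
        if self.angular_step_deg <= 0:
            raise GeometryError("angular_step must be positive")
        ratio = self.angular_range_deg / self.angular_step_deg
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
            raise GeometryError(
                f"angular_step {self.angular_step_deg} does not divide range {self.angular_range_deg}"
            )


def projection_count(geometry: ScanGeometry) -> int:
    """Number of projection images from the rotation range and step.

    For a 198° range at a 0.4° rotational shift this is 495.
    """
    ratio = geometry.angular_range_deg / geometry.angular_step_deg
    n = round(ratio)
    if abs(ratio - n) > 1e-9 * max(1.0, ratio):
        raise GeometryError("angular range is not an integer multiple of the step")
    return int(n)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_stack(volume: VolumeGrid, path: str | os.PathLike) -> Path:
    """Write a volume losslessly as multi-page TIFF or NIfTI-1.

    The format is chosen from the extension (``.nii``/``.nii.gz`` → NIfTI,
    anything else → TIFF).  A JSON sidecar stores spacing, modality and
    nominal intensity range so that :func:`read_stack` can restore them.
    """
    path = Path(path)
    data = volume.voxels
    if data.dtype == np.float64:
        data = data.astype(np.float32)  # TIFF float stacks are stored as 32-bit
    try:
        if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
            affine = np.diag(
                [volume.spacing_um[2] / 1000.0, volume.spacing_um[1] / 1000.0,
                 volume.spacing_um[0] / 1000.0, 1.0]
            )
            # NIfTI axis order is (x=col, y=row, z=slice)
            nib.save(nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine), str(path))
        else:
            tifffile.imwrite(str(path), data, photometric="minisblack")
    except OSError as exc:
        raise OSError(f"cannot write stack to {path}: {exc}") from exc
    meta = {
        "spacing_um": list(volume.spacing_um),
        "modality": volume.modality,
        "dtype_range": list(volume.dtype_range) if volume.dtype_range else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(
    path: str | os.PathLike,
    spacing_um: tuple[float, float, float] | None = None,
    modality: str | None = None,
) -> VolumeGrid:
    """Read a multi-page grayscale TIFF or NIfTI volume.

    ``spacing_um``/``modality`` override the sidecar when given; one of the
    two sources must provide them.  Page 0 of a TIFF becomes slice 0.
    Intensities are returned exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
        except json.JSONDecodeError as exc:
            raise OSError(f"corrupt metadata sidecar {sidecar}: {exc}") from exc
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
        zooms = img.header.get_zooms()[:3]  # (x, y, z) in mm
        nifti_spacing = (zooms[2] * 1000.0, zooms[1] * 1000.0, zooms[0] * 1000.0)
        spacing = spacing_um or meta.get("spacing_um") or nifti_spacing
        if spacing is not None and not np.allclose(nifti_spacing, spacing, rtol=0.01):
            logger.warning(
                "NIfTI header spacing %s differs from supplied spacing %s by more than 1%%",
                nifti_spacing, tuple(spacing),
            )
    else:
        try:
            with tifffile.TiffFile(str(path)) as tif:
                photometric = tif.pages[0].photometric
                samples = tif.pages[0].samplesperpixel
                data = tif.asarray()
        except (tifffile.TiffFileError, ValueError) as exc:
            raise OSError(f"unreadable TIFF stack {path}: {exc}") from exc
        if samples != 1 or photometric not in (
            tifffile.PHOTOMETRIC.MINISBLACK, tifffile.PHOTOMETRIC.MINISWHITE,
        ):
            raise ValueError(
                f"{path}: RGB/multichannel TIFF is unsupported; expected a "
                "grayscale stack"
            )
        if data.ndim == 2:
            data = data[np.newaxis, ...]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a grayscale stack, got shape {data.shape}")
        spacing = spacing_um or meta.get("spacing_um")
    if spacing is None:
        raise ValueError(f"{path}: no spacing supplied and no usable sidecar metadata")
    modality = modality or meta.get("modality") or "CT"
    return VolumeGrid(
        voxels=data,
        spacing_um=tuple(spacing),
        modality=modality,
        dtype_range=tuple(meta["dtype_range"]) if meta.get("dtype_range") else None,
    )
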