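# Methods

This note records the models, conventions and numerical choices behind
`osteoscan`, and what its synthetic-phantom validation does and does not
demonstrate.

## Coordinate and intensity conventions

All stacks are `(slice, row, col)` arrays, 0-based, origin at the top-left
of each displayed slice. Rotation angles are counter-clockwise positive
when viewing a slice with the row index increasing downward, about the
slice centre; translations `(tx, ty)` act on (columns, rows) in target-grid
pixels, after the rotation. Spacing is carried as metadata in μm, with the
slice entry equal to the slice *pitch* (thickness + interslice gap) so that
slice-correspondence arithmetic — e.g. (270 + 90)/18 = 20 CT slices per
MRI slice — operates directly on spacings. Intensities are never rescaled
on read: the CT bone window (75–255 on the 8-bit scale) and any MRI
threshold apply to raw stored values.

## Bone classification from the PDw / PDw-FS pair

A pixel is bone iff it is *strictly* darker than the threshold in both
scans. The strict `<` makes results bit-for-bit reproducible; the mask is
monotone non-decreasing in the threshold. Classification runs volume-wide
and is intersected with the ROI afterwards; the two orders give identical
BV/TV and the volume-wide mask is reusable across ROI sets.

The threshold is ideally fixed from pilot data (`fixed`). Two automatic
estimators exist:

* `otsu_pdw` — Otsu on the PDw histogram. The PDw image always separates
  the marrow (bright) from bone and air (dark) regardless of fat content,
  and the dual-scan AND rule already supplies the fat insensitivity, so
  this is the estimator the pipeline uses by default.
* `otsu_min` — minimum of the two scans' Otsu thresholds. More
  conservative, but when fat suppression removes most of the marrow signal
  (fat fraction ≳ 0.7) the PDw-FS histogram collapses toward the noise
  floor and the minimum undershoots, eroding the bone mask.

## Fat-fraction mapping

FF = (PDw − PDw-FS)/PDw on soft-tissue ROI pixels, clipped to [0, 1]
(negative numerators are noise where suppression overshoots; values above 1
cannot arise physically). Pixels with PDw at or below a noise floor are
excluded and counted: a ratio with a near-zero denominator is meaningless.
The default noise floor is the patch median plus 2 × 1.4826 × MAD of an
8 × 8 air corner patch of the first PDw slice — a robust 2σ background
cut; pass an explicit value when the corner is not air.

Per-slice (mean, sd, n) summaries are pooled with the combined-variance
identity

  m = Σ nᵢmᵢ / Σ nᵢ,  s² = [Σ nᵢ(sᵢ² + mᵢ²)]/Σ nᵢ − m²,

which is exact when sᵢ are population (n-divisor) SDs; that variant is
therefore the default, with sample-SD input supported via
`pooled_stats(..., variance="sample")`. Pooling this way weights slices by
their pixel count, which matters because ROI area varies slice to slice.

## Alignment

The workflow is manual-first: every stage accepts an explicit
`RigidTransform2D` (JSON `{angle_deg, tx, ty}`) measured by a human
overlaying slices, and automation is a convenience layered on top.

* **Capillary axis** (`fit_capillary_axis`): per slice, the stack is
  thresholded at 85% of the way from the median to a robust (99.9th
  percentile) maximum — the fiducial is the brightest structure by
  construction (water column on MRI; glass walls on an overexposed CT
  reconstruction, whose annulus is hole-filled into a disk). The most
  compact (highest-solidity) component of sufficient area is the
  candidate; a second pass keeps, per slice, the component nearest the
  median centroid. Centroids in physical coordinates are fit by total
  least squares (SVD); the reported tilt angles about the row/column axes
  are what a viewer's sagittal/coronal rotations must undo, and the
  residual RMS flags bent or badly detected fiducials. Detection in fewer
  than half the slices is an error, not a warning.
* **In-plane registration** (`register_slices` / `register_stacks`):
  exhaustive angle grid (default ±15° in 0.5° steps, refined 10× around
  the optimum); per angle the translation comes from the dense normalized
  cross-correlation map (`match_template`) restricted to the shift bounds,
  and the final translation is polished to sub-pixel precision by phase
  correlation. The score is the masked Pearson correlation within the
  warped footprint; scores below 0.2 log a warning, as uncorrelated images
  do not exceed ≈0.1. An unnormalized correlation surface was rejected:
  on binary structure images its argmax systematically favours
  large-overlap configurations over the true alignment.
* **Cross-modality structure images** (`register_ct_to_mri`): CT and MRI
  cannot be correlated directly (opposite bone contrast, no CT soft
  tissue). The CT structure is simply the bone window ≥ 75. The MRI
  structure takes the largest bright PDw component as marrow, its convex
  hull as the sample silhouette (osteochondral plugs are cylindrical, so
  the cross-section is convex — hole-filling fails whenever trabecular
  voids touch the boundary), bone as the dark complement of the *water-only
  PDw-FS* image inside the hull, and keeps detached bright components as
  the capillary. Deriving bone from PDw-FS rather than PDw avoids the
  chemical-shift displacement of the fat signal, which otherwise biases
  the recovered translation by up to the fat-shift amplitude (~1.5 px).
  Several slices are scored jointly: the misalignment is a single in-plane
  transform, and one slice alone gives the rotation a short lever arm.

## ROI handling

ROI sets store per-slice masks tagged `drawn`, `interpolated` or `empty`,
with the first slice beyond each end of the drawn span explicitly `empty`.
The anchor template (middle slice N, then N±20, N±40, N−60, empty at N−61
and N+41) is a configurable default reflecting one acquisition geometry,
not a rule. Interpolation between anchors is linear blending of signed
Euclidean distance transforms thresholded at zero — reproducible, exact at
the anchors, area-monotone for nested convex shapes. It cannot morph
between anchors whose supports never overlap (the blend pinches off); this
is raised as an error rather than silently producing an empty slice.

CT→MRI transfer collapses each group of `fine_per_coarse` consecutive CT
masks by per-pixel majority vote with ties counted as inside (a symmetric,
slightly inclusive convention), downscales in-plane by block majority, and
applies the rigid transform with nearest-neighbour interpolation so masks
stay binary. The edge-margin check reports the minimum distance from ROI
pixels to the sample boundary (default threshold 500 μm, the conventional
guard against fluid infiltration at the sample margin).

## Micro-CT path

Binarization is the closed interval [75, 255] — both bounds inclusive,
matching the usual reading of a "between 75 and 255" window. No despeckle
by default; a minimum-component-size filter is available behind a flag.
BV/TV shares its pooled-count implementation with the MRI path so the two
modalities differ only in how the bone mask is obtained.

## Agreement statistics

Differences are fixed as CT − MRI (reference minus new method) and the
orientation string is carried in every report. Limits of agreement use the
classical 1.96 multiplier with the n−1 SD; the t test is two-sided with no
multiplicity correction (one prespecified comparison); Shapiro–Wilk uses
the standard Royston approximation (scipy). A zero-variance difference
vector is reported as degenerate rather than producing an infinite t.

## The synthetic phantom

The phantom emulates, on one voxel grid: a trabecular network (Gaussian
random field, isotropic kernel σ = `correlation_length`, default 4 voxels
— plausible texture at 80–128 px cross-sections), thresholded at the
empirical (1 − BV/TV) quantile *within* a cylindrical sample (radius 0.33
of the in-plane extent) so the realized fraction matches the target to
within one voxel; air outside the sample; CT contrast bone 200 / marrow
30 / air 0 with a saturated-wall capillary; MRI contrast marrow PDw 180
split into water (1 − FF) and fat (FF) components with the fat component
displaced by a configurable fat shift (default 1.5 px along the readout
axis), bone and air as signal voids, a bright water-filled capillary; and
additive Gaussian noise (Rician optional) at SNR = foreground signal /
noise SD, default 20. The capillary (radius 4 px, offset outside the
sample near a corner) may be tilted to exercise axis fitting. A known
in-plane rigid misalignment is applied to the CT stack, and bundles carry
the ground-truth ROI, transform and a manifest of realized BV/TV and FF.

What passing phantom tests show: the measurement chain is unbiased to
within ±3 BV/TV points and ±0.05 FF at SNR 20 under this contrast model,
and exact in the noiseless limit. What they do not show: robustness to
partial-volume mixing between grids of different resolution (the default
bundle uses matched grids; the 5×/20× resolution disparity of real
acquisitions is exercised by the correspondence and transfer arithmetic,
not by the end-to-end simulation), to anisotropic or plate-like trabecular
architecture, to B1/receive-field inhomogeneity, to imperfect gain
matching between the two scans, or to Rician noise floors at low SNR.

## Problem sizes and determinism

Default phantoms are 24 × 80 × 80 voxels — large enough for ~10
trabecular correlation lengths across the sample and stable registration,
small enough that the full suite (310 tests) runs in well under a minute.
All generators are deterministic functions of their spec, with independent
seed streams per component (field, CT noise, PDw noise, PDw-FS noise), so
every reported number is reproducible bit-for-bit from (inputs, config,
seed).

## Known limitations

* The two-scan subtraction is proton-density-based only: no T1/T2*
  correction, no multi-echo Dixon separation, no fat spectral modelling.
* Registration automation assumes the fiducial and a roughly convex sample
  cross-section; it is a fallback for the manual overlay, not a general
  multimodal registrar (mutual-information or deformable methods are out
  of scope by design).
* The "interpolated" ROI convention of proprietary viewers is unspecified;
  signed-distance blending is a reproducible stand-in that matches the
  visible behaviour for nested convex outlines but need not match other
  tools pixel-for-pixel.
* The bundled ten-sample dataset supports the agreement statistics only;
  its per-sample BV/TV values derive from patient scans that are not
  distributed and cannot be recomputed here.
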