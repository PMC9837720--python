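# osteoscan

Paired micro-MRI / micro-CT analysis of subchondral trabecular bone:
bone-volume-fraction (BV/TV) quantification from a dual proton-density MRI
acquisition, voxel-wise proton-density fat-fraction (PDFF) mapping of the
bone marrow, fiducial-guided rigid alignment and ROI transfer between
micro-CT and micro-MRI stacks, micro-CT BV/TV, and Bland–Altman
method-agreement statistics.

It is written for researchers studying osteoarthritis and other joint
disorders who want quantitative trabecular bone structure from MRI — which
sees marrow but not bone — validated against micro-CT, the gold standard
that sees bone but not soft tissue.

## The method

**Bone from two scans.** Two proton-density-weighted turbo spin-echo scans
are acquired with identical settings except the fat-suppression module:
PDw carries fat + water signal, PDw-FS water only, and mineralized bone is
a signal void in both. A pixel is classified as bone iff it is darker than
a threshold *t* in **both** images:

    bone(p)  ⇔  PDw(p) < t  and  PDw-FS(p) < t

Requiring both scans makes the classification insensitive to marrow fat
content (a fat-bright pixel goes dark under fat suppression but stays
bright in PDw). BV/TV is the pooled fraction of ROI pixels classified as
bone across all analyzed slices:

    BV/TV = 100 · Σᵢ |boneᵢ ∩ ROIᵢ| / Σᵢ |ROIᵢ|

**Marrow fat fraction.** On soft-tissue pixels (the complement of bone
within the ROI), the fat signal is the subtraction image and

    FF = (SI_PDw − SI_PDw-FS) / SI_PDw  =  SI_fat / SI_fat+water  ∈ [0, 1].

Sample-level mean and SD pool the per-slice summaries with the
combined-variance identity (exact for n-weighted variances), honouring the
varying ROI size per slice.

**CT↔MRI correspondence.** A water-filled capillary taped to the sample
tube is visible in both modalities and anchors the alignment: the CT stack
is rotated until the capillary is parallel to the stacking axis, downscaled
to the MRI pixel pitch (block mean), and overlaid on an MRI slice to find
the in-plane rotation and shift. Scan resolutions are integer multiples of
each other (90 μm in-plane MRI vs 18 μm CT; 270 + 90 μm MRI slice pitch =
20 CT slices), so ROI sets drawn on CT collapse onto the MRI grid by
majority vote and block majority without interpolation ambiguity.

**Agreement.** Paired per-sample BV/TV values from the two modalities are
compared with Bland–Altman analysis (bias = mean difference CT − MRI, 95%
limits of agreement = bias ± 1.96 SD), Shapiro–Wilk normality of the
differences, and a two-sided one-sample t test of the bias against zero.

A synthetic-phantom module generates co-registered ground-truth bundles —
thresholded-Gaussian-random-field trabecular networks in a cylindrical
sample, simulated CT and PDw/PDw-FS contrast, capillary fiducial, noise,
fat-shift artifact and a known rigid misalignment — so the entire chain is
testable without scanner data.

## Worked example

The package bundles the paired per-sample measurements of ten human
femoral-head osteochondral samples (micro-CT vs micro-MRI BV/TV, %):

```python
>>> from osteoscan import bland_altman, PairedMeasurements, load_paired_bvtv
>>> res = bland_altman(PairedMeasurements.from_frame(load_paired_bvtv()))
>>> print(f"bias (CT-MRI) = {res.mean_diff:.3f} pp, LoA [{res.loa_low:.2f}, {res.loa_high:.2f}]")
bias (CT-MRI) = 2.167 pp, LoA [-9.32, 13.65]
>>> print(f"Shapiro-Wilk p = {res.shapiro_p:.3f}; t({res.t_df}) = {res.t_stat:.3f}, p = {res.t_p:.3f}")
Shapiro-Wilk p = 0.642; t(9) = 1.170, p = 0.272
```

The micro-MRI method overestimates nothing systematic: the bias of 2.17
percentage points is not significantly different from zero (p = 0.272),
and the differences are compatible with normality. The same analysis is
available from the shell:

```sh
osteoscan agree pairs.csv --plot bland_altman.png
```

A full synthetic run — phantom generation, registration, ROI transfer,
BV/TV in both modalities, fat fraction, agreement:

```sh
osteoscan phantom --out-dir sample0 --seed 17
osteoscan ct-bvtv sample0/ct.tif --roi sample0/roi_ct.tif
# BV/TV = 24.855% (5846/23520 px)
osteoscan mri-bvtv sample0/pdw.tif sample0/pdw_fs.tif --roi sample0/roi_truth.tif
# threshold 90.522; BV/TV = 25.544% (6008/23520 px)
osteoscan fat-fraction sample0/pdw.tif sample0/pdw_fs.tif --roi sample0/roi_truth.tif
# FF mean 0.6006 sd 0.0857 over 17512 px (0 below noise floor)
```

against the phantom's manifest ground truth of ROI BV/TV 24.855% and
marrow fat fraction 0.6. Subcommands `align`, `transfer-roi` and `run`
cover the remaining pipeline stages; `run` drives everything from a
JSON/YAML config.

## Layout

| module | contents |
| --- | --- |
| `osteoscan.image_io` | `VolumeGrid`, TIFF/NIfTI stack I/O, scan-geometry bookkeeping |
| `osteoscan.geometry` | rigid 2D transforms, block-mean downscaling, slice correspondence, capillary-axis fitting, registration |
| `osteoscan.roi` | `RoiSet`, signed-distance ROI interpolation, edge-margin QC, CT→MRI ROI transfer |
| `osteoscan.mri_bone_fat` | dual-scan bone classification, BV/TV, fat-fraction mapping, pooled statistics |
| `osteoscan.ct_bone` | CT binarization (75–255 window) and BV/TV |
| `osteoscan.agreement` | Bland–Altman, Shapiro–Wilk, one-sample t test, plotting |
| `osteoscan.phantom` | synthetic ground-truth phantom bundles |
| `osteoscan.pipeline`, `osteoscan.cli` | config-driven runs and the `osteoscan` CLI |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
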