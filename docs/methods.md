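# Methods

## Segmentation model

The signal-intensity-threshold (SIT) rule operates inside a spherical ROI
given in world millimetres. A voxel belongs to the ROI when its **centre**
lies within the sphere (0-based indices, voxel-centre convention) — an
unambiguous, resolution-independent membership rule. Within the ROI the
intensity extremes `I_min`, `I_max` are taken as raw extremes, not
percentiles, and the mask is

```
mask = { v in ROI : C·(I_max − I_min) + I_min ≤ I(v) ≤ I_max }
```

with **inclusive** bounds, so `C = 0` selects the entire ROI and `C = 1`
selects exactly the argmax voxel(s). Inclusivity also yields the nesting
property `mask(C₂) ⊆ mask(C₁)` for `C₁ ≤ C₂`, hence volume is
non-increasing in `C` — a property the test suite checks on every phantom.

Connected-component cleanup is available (`keep_largest=True`: largest
26-connected component, ties broken by the lexicographically smallest seed
voxel) but **off by default**, since the plain threshold rule is the
model; textured backgrounds can admit speckle, which is why the safeguard
exists at all. A ROI whose sphere pokes past the image extent is clipped
with a `BoundaryROIWarning` (the air margin may be incomplete); a ROI
centred outside the image is an error. An empty mask is legal and returns
with an `EmptyMaskWarning`, never an exception.

The CT arm uses a declared surrogate segmenter — ROI voxels at or above a
fixed attenuation cut (default −400 HU, roughly halfway between air and
soft tissue), reduced to the largest connected component. It stands in for
a clinical semi-automatic lesion tool and makes no claim to emulate any
vendor's algorithm.

## Digital phantoms

Each phantom voxel grid carries one or more nodules of analytically known
volume. Supported shapes are the sphere and the hemisphere (default:
hemisphere, flat face on the axial mid-plane — the molded-in-a-reservoir
geometry); radius follows from the requested volume.

**Rasterization.** Each voxel near the nodule is divided into
`supersample³` sub-cells. For `supersample = 1` the occupancy is a binary
point test (the "binary phantom" limit used by several exactness tests).
For `supersample ≥ 2` each sub-cell's inside fraction is computed by
resolving the surface linearly across the cell — fraction
`clip(0.5 − d/ℓ, 0, 1)` where `d` is the signed distance to the surface
and `ℓ` the cell's support length along the surface normal — with an
inward curvature correction `ℓ²/(12r)` that cancels the planar ramp's
convexity excess (`≈ π r ℓ²/3` in volume). At the default
`supersample = 4` the occupancy-sum volume agrees with the closed form to
better than 0.1% for radii ≥ 2 voxels (the suite enforces ≤ 0.5%); a
plain point test would plateau near 1% at small radii and fail entirely on
the hemisphere's flat face.

**Composition.** The image is

```
blur_FWHM( background_field + (S − b)·occupancy ) + noise
```

where `S` is the nodule plateau intensity and `b` the background mean, so
fully occupied voxels sit at `S` regardless of the background level (this
matters for the CT arm, where air is −1000 HU and the nodule +20 HU). The
background field is white noise smoothed to a 3 mm correlation length and
rescaled to the requested SD — a stand-in for foam/parenchyma texture —
optionally floored (at 0 for MRI magnitude images; unfloored for CT).
Blur is an isotropic-in-mm Gaussian of the stated FWHM. Noise is Rician
for the MRI arm (magnitude of a complex signal with iid Gaussian channel
noise) and additive Gaussian for CT. All randomness flows from one
`numpy` generator seeded by the `PhantomSpec`, so a fixed spec object
reproduces a bit-identical image.

**Arm defaults** (the study conditions; all overridable):

| parameter | MRI arm | CT arm |
|---|---|---|
| grid (voxels) | 96³ | 134 × 134 × 76 |
| spacing (mm) | 0.98 isotropic | 0.7 × 0.7 × 1.25 |
| nodule signal | 100 (arb.) | +20 HU |
| background mean | 20 (20% of signal) | −1000 HU |
| texture SD | 5 | 30 |
| blur FWHM (mm) | 1.2 | 1.5 |
| noise | Rician, SD 2 | Gaussian, SD 10 |

Per-nodule subgrids (one nodule centred per 96³ grid) rather than a single
512³ field of view keep the full experiment at desk scale; physically the
two are equivalent for volumetry because every ROI is local. The
anisotropic CT spacing deliberately exercises anisotropic voxel-volume
handling.

**Nodule set.** Volumes are log-uniform between the bounds (the
distribution across the decade-plus range is not otherwise determined;
log-uniform covers it evenly) with both endpoints forced, so the nominal
16–561 mm³ range is spanned exactly. The default study set is stratified:
22 nodules of which exactly 4 fall below the 50 mm³ analysis cutoff, for
every seed — this pins the manufactured/excluded/analyzed bookkeeping
(22/4/18) that the reporting layer checks as an invariant.

## Volumetry metrics

* `mask_volume` = member-voxel count × voxel volume (mm³).
* `equivalent_diameter` = (6V/π)^(1/3) — the sphere-equivalent size, an
  unambiguous volume-derived summary (labelled distinctly from the
  clinical average diameter).
* `average_diameter`: on the axial slice of maximal area (plane
  configurable), long axis = maximal Feret diameter over voxel-centre
  coordinates, short axis = maximal extent perpendicular to the long
  axis; each axis is widened by the mean in-plane spacing to account for
  the half-voxel footprint on each side, which makes a single-voxel mask
  measure exactly the mean of the in-plane spacings. Feret search is a
  brute-force pairwise scan (slices are small), deterministic under ties
  (first maximal pair in index order).
* `percent_difference` = 100·(V_test − V_ref)/V_ref; the reporting layer
  rounds half-away-from-zero to integer percent, raw values are retained.
* `assess_growth`: true iff the increase is at least 25% (boundary
  inclusive — "at least").
* `volume_doubling_time` = Δt·ln2 / ln(V₂/V₁); negative for shrinkage;
  V₂ = V₁ raises a dedicated exception rather than returning a number.
* `filter_min_volume`: keeps records with true volume ≥ 50 mm³ (boundary
  kept — the exclusion is "< 50").

## Agreement statistics

Lin's ρ_c uses population (1/n) moments — the original estimator — with a
`ddof=1` sample-moment variant behind a keyword. The decomposition
ρ_c = ρ·C_b is computed as C_b = ρ_c/ρ. Reduced major axis regression is
used for the X-Y plots because both measurements carry error; its slope is
sign(ρ)·s_y/s_x. Percent Bland-Altman differences are taken **relative to
the reference** (truth or CT) rather than the pair mean — matching how the
comparison is phrased clinically ("with respect to CT volume"); the
pair-mean textbook variant would shrink large relative differences and is
a one-line change if wanted. LoA multiplier is fixed at 1.96 with no
confidence intervals (none are reported downstream). Calibration selects
`argmax ρ_c` over the grid {0.20, 0.30, 0.40, 0.50}, breaking exact ties
toward the smaller (more inclusive) C; per-case segmentation failures are
recorded and the case is dropped from every C so pairings stay consistent.

## The experiment pipeline

`run_phantom_experiment`: sample the stratified nodule set → compose the
MRI and CT phantom per analyzed nodule (per-nodule sub-seeds derived from
the experiment seed via `SeedSequence`) → auto-ROI at 2× the
sphere-equivalent radius of the true volume (capped to the grid) → SIT
segmentation at each C and the CT surrogate → calibration table and
selected C → concordance + Bland-Altman for MRI-vs-truth and MRI-vs-CT.
The report serialises to canonical JSON (sorted keys) and is byte-identical
across reruns with the same seed; its bookkeeping invariant
(excluded + analyzed = manufactured) is enforced at construction. Nodules
below the cutoff are filtered on *true* volume before segmentation, as in
a screening protocol where sub-threshold nodules are not followed
volumetrically.

`run_single_case` is the in-vivo workflow: one image, one ROI, SIT at the
calibrated C (default 0.30, overridable — the synthetic arm typically
calibrates to 0.50, see below), volume + diameters, and percent difference
against a reference volume when given. Manual or external measurements
enter reports only as externally supplied volumes (`method="external"`);
nothing simulates a human rater.

## What the phantoms do and do not show

The generator reproduces the *structure* of the physical experiment —
known-volume nodules, partial-volume blur, textured background, modality
noise, anisotropic CT voxels — but not scanner physics (no k-space or UTE
trajectory, no CT kernels, no anthropomorphic anatomy, no motion).
Consequences to keep in mind:

* The optimal C is a property of the acquisition. Under the synthetic
  defaults the background is far dimmer relative to the nodule than in
  real parenchyma, and for a symmetric PSF the half-range threshold
  (C = 0.5) is nearly volume-preserving, so the sweep typically selects
  0.50 where the physical study selected 0.30. The *calibration
  machinery* — sweep, selection rule, agreement statistics — is what
  transfers, and the planted-optimum test shows the sweep recovers a known
  optimum at 0.30 exactly.
* With zero blur and zero noise the masks equal the occupancy threshold
  exactly, but measured volumes still scatter a few percent around the
  analytic truth: that residual is digitization (voxel-count volumetry of
  ~3-voxel-radius lesions), not a segmentation defect, and it bounds how
  tight the agreement statistics can be at this resolution. Mild blur in
  fact *reduces* the scatter by smoothing the partial-volume profile.
* Passing tests therefore demonstrate correctness of the operations and
  realistic-order agreement statistics, not clinical performance on
  scanner data.

## Numerical and scale choices

Default problem sizes keep the full study at desk scale: 18 analyzed
nodules × (one 96³ MRI grid + one 134×134×76 CT grid) × 4 thresholds
complete in a few seconds on one core, and the whole test suite in about
half a minute. Tolerances asserted in tests: rasterization ≤ 0.5%
relative (measured ≤ 0.1%); statistics vs direct-arithmetic oracles at
1e-10 relative; scaled-down study |bias| ≤ 5% and LoA half-width ≤ 15%
under the default degradation (chosen for these synthetic conditions, not
claims about hardware). Degenerate inputs are contracts, not crashes:
constant vectors make correlations undefined (raised), empty masks warn,
equal follow-up volumes make VDT undefined (raised), sub-voxel nodules
rasterize correctly via supersampling.
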