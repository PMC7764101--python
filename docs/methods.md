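# Methods

This note documents the models, conventions and design choices behind
`midparc`: what each stage computes, which knobs matter, what the phantom
does and does not emulate, and the numerical details a maintainer would
need to reproduce or extend the package.

## Coordinate conventions

All volumes are 3-D arrays with a RAS voxel-to-mm affine; the phantom uses
`mm = index × voxel_size` (voxel-center convention, 0-based indices,
isotropic 1 mm by default).  Nearest-voxel lookup is `rint(affine⁻¹ · x)`.
Non-isotropic or translated affines are accepted everywhere; step geometry
is always in mm through the affine.

## Orientation field

The per-voxel fiber orientation distribution is represented as a discrete
mixture of at most 4 (unit direction, weight) pairs, normalized to unit
total weight wherever any bundle passes and identically zero elsewhere
(propagation terminates there).  Direction sign carries no meaning; all
samplers canonicalize signs (first nonzero component positive) before use,
which makes every downstream quantity exactly invariant to flipping stored
directions.  Serialization is a 4-D NIfTI with `4N` volumes per voxel
(`dx, dy, dz, w` per slot).

## Phantom geometry

No quantitative bundle anatomy is available for the system being emulated,
so the phantom is parametric.  A bundle is a centerline polyline with a
rectangular perpendicular cross-section (per-axis half-widths); the voxel's
direction is the local centerline tangent.  The default layout, designed on
a 64³ grid and scaled linearly with the grid:

* **Striatum** (per side): a 12 × 8 × 24-voxel box partitioned into three
  8-voxel slabs along z (the ventro-dorsal topography axis): limbic,
  prefrontal, sensorimotor.
* **Cortical targets**: three boxes at larger y, stacked at matching z.
  Each striatal slab is connected to its target by a straight bundle along
  +y whose cross-section exactly covers the slab and does not touch its
  neighbors.
* **Midbrain** (SNc/VTA stand-in, per side): a 12 × 4 × 4-voxel box below
  the striatum, partitioned into three 4-voxel slabs along x (medio-lateral
  topography axis).  Each slab connects to the matching striatal territory
  through a curved bundle: a vertical leg along +z, a quarter arc of radius
  6 mm (turn rate ≈ 12° per 1.25 mm step, well inside the 30° limit), and a
  short horizontal leg entering the striatal slab from its anterior face.
  Arcs and legs of different bundles never overlap, so with
  `crossing_fraction = 0` every seed voxel carries exactly one direction.
* Left/right are mirror images about the mid-sagittal plane.

`crossing_fraction` adds a perpendicular secondary direction with that
relative weight in every bundle voxel; `angular_noise_deg` jitters each
stored direction by a Gaussian angle about a random perpendicular axis.
Both default to 0: the baseline condition is the clean three-territory
topography that the recovery checks assume.

Ground truth is the slab partition itself (every seed voxel belongs to
exactly one territory), persisted as integer label volumes.

### FA cohorts

Subject FA volumes are `fa_baseline` (+ `fa_group_offset` for the patient
group, default −0.036 with baseline 0.47, matching the magnitude of the
group difference the pipeline is meant to recover) plus iid per-voxel
Gaussian noise (`fa_noise_sd`, default 0.05), clipped to [0, 1].
`fa_subject_sd` optionally adds a between-subject Gaussian intercept
(default 0): with it at zero, the subject × side × parcel records entering
the ANOVA are approximately independent, which is the regime in which the
row-independent fixed-effects ANOVA is correctly calibrated.  Per-subject
seeds derive deterministically from the cohort master seed.

## Tracking

First-order probabilistic propagation on the discrete mixture: fixed step
(default 1.25 mm), per-step direction drawn from the current voxel's
mixture restricted to a cone (default 30°) around the incoming direction,
candidates sign-flipped into the incoming hemisphere.  This deliberately
replaces second-order FOD-amplitude integrators (iFOD2): the quantity of
interest — which bundle, hence which target, a streamline follows — does
not depend on the integrator's order on these phantoms.

Semantics fixed by the package:

* Seeding is volume-uniform over the seed ROI (uniform voxel choice +
  uniform position in the voxel); a per-voxel round-robin mode is a config
  switch.  The streamline budget (default 5000) counts *attempts*;
  non-reaching streamlines are retained in the tractogram but contribute to
  no density map.
* The initial direction is drawn with no cone constraint and random
  polarity; if the very first step already terminates (leaves the field
  without hitting a target), the opposite polarity is attempted once.
* Target inclusion: the streamline stops with the first point inside a
  target mask (nearest-voxel membership at the floating-point position);
  that point is its endpoint and the streamline counts for that target.  No
  partial steps, no exclusion masks.
* Termination statuses distinguish empty mixtures (`terminated_field`,
  including grid exit), empty cones (`terminated_angle`), and the safety
  step bound.

Propagation is batched across streamlines with NumPy (a 5000-streamline
tractogram on a 64³ grid takes well under a second), and is bit-for-bit
deterministic given the RNG seed.

## Parcellation

* **TDI**: per target, each reached streamline's full path is rasterized
  (points plus segment midpoints, so the effective 0.625 mm sampling cannot
  skip a 1 mm voxel between steps) with at most one increment per voxel per
  streamline; the count image is then masked by the binarized seed ROI.  An
  endpoints-only variant exists as a sensitivity switch.
* **Normalization**: each map is divided by its mean over *all* seed-ROI
  voxels (zeros included), so its seed-ROI mean is 1; this makes the
  subsequent argmax invariant to rescaling any single target's counts.  An
  all-zero map passes through flagged — it can never win a voxel.
* **Classification**: per-voxel argmax over the normalized maps; exact ties
  break to the lowest-index label in the fixed order (limbic, prefrontal,
  sensorimotor); voxels where every map is zero are `unclassified`.  The
  tie and unclassified conventions are package choices (the reference
  hard-segmentation utility does not document its own).
* **Two-step scheme**: step 2 uses the classified voxels of the step-1
  parcels as target masks, with independent RNG substreams for the two
  steps.  An empty striatal parcel is dropped from step 2 with a warning.
* **MPM**: per label, the count of subjects carrying that label per voxel;
  the thresholded map keeps voxels with count ≥ max(1, ⌈threshold·n⌉).
  The `max(1, ·)` makes threshold 0 the union and threshold 1 the
  intersection while "at least half" stays exact for even and odd n
  (12/24, 15/30).

## Metrics

`SDI = 100 · v_parcel / V_seed` in voxels of the common grid; by
construction `Σ SDI + 100 · unclassified_fraction = 100` to machine
precision.  Mean FA per parcel is sampled along freely propagated
streamlines (no targets) seeded from the parcel, default 10,000, with FA
interpolated trilinearly at every point and averaged over points pooled
across streamlines (per-streamline averaging and nearest-neighbor
interpolation are switches; pooling is the default because streamline
length then weights the average exactly as the point cloud does).

For cohort-level simulation studies the FA streamline geometry can be
tracked once per (side, parcel) from the phantom's ground-truth parcels and
shared across subjects (`shared_fa_tracks`): all subjects of one phantom
share the orientation field, so per-subject re-tracking only adds sampling
noise at ~50× the cost.  The default pipeline still tracks per subject.

## Statistics

Fixed-effects full-factorial ANOVA per measure with side, parcel and
diagnosis as crossed factors, fitted by OLS with sum-to-zero contrasts and
Type III sums of squares (well defined for the unbalanced 24/30 design;
the SS type is switchable).  Partial η² = SS_effect/(SS_effect+SS_error).
Observation rows (subject × side × parcel) are treated as independent,
matching the residual degrees of freedom of the reference design (e.g.,
324 rows − 12 model df = 312); a repeated-measures treatment is out of
scope.  Degenerate inputs are handled explicitly: with zero residual
variance, terms with positive SS report F = ∞, p = 0 and terms with zero
SS report F = 0, p = 1.

Post-hoc pairwise contrasts use the full model's residual mean square and
degrees of freedom (the classical error-term convention), two-sided t
tests, and Bonferroni adjustment (adjusted p = min(1, raw p × number of
pairs), α = 0.05).

### Power of the post-hoc pattern

With one independent observation per subject × side × parcel (108 rows per
parcel level) and an observation SD of ~10, a limbic-vs-prefrontal
difference of ~2 has noncentrality ≈ 1.6 against the Bonferroni threshold
|t| ≈ 2.41, so it is flagged in roughly 15–20% of replicate cohorts; the
joint pattern "both sensorimotor contrasts significant and
limbic-vs-prefrontal not" therefore occurs in about 80% of replicates, not
more.  Only a substantial between-subject variance share (intraclass
correlation ≳ 0.6, which inflates the pooled error term relative to the
effective within-subject noise) would push that probability above 90%;
since nothing constrains that split here, the package does not assume it,
and the corresponding acceptance test documents the shortfall rather than
masking it.

## What the phantom does not emulate

Raw DWI signal, acquisition noise, distortion and registration error,
response-function/FOD estimation, atlas-based ROI extraction, and any
anatomically realistic bundle geometry.  Passing recovery checks therefore
show that the pipeline's logic (counting, normalization, classification,
conservation, inference) is correct on data whose topography is known —
not that the pipeline would recover the same topography from clinical
diffusion data.

## Problem sizes

Defaults: 64³ grid, 5000 streamlines per seed ROI, 10,000 FA streamlines
per parcel, 24 + 30 subjects.  The test suite uses these sizes for the
recovery checks and smaller cohorts (6 + 6) with 400-streamline shared FA
geometry for the 200-replicate calibration study; the acceptance script
runs the full-size cohort end to end.
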