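# Methods

This note documents the models and procedures eatkit implements, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data experiments do and do not demonstrate.

## Attenuation compartments and EAT dispersion

Fat on CT occupies roughly [−195, −15] HU. The package classifies every
region-of-interest voxel into

- a **low** compartment, −195 ≤ HU ≤ −45,
- a **high** compartment, −45 < HU ≤ −15.

The two printed band labels in the literature ("−195 to −45" and "−44 to
−15") are integer labels for contiguous ranges; to leave no gap for
non-integer HU the implementation uses the half-open partition above, so
−45 itself belongs to the low compartment and every value in [−195, −15] is
classified exactly once. Compartment means are plain arithmetic means of
voxel HU; **dispersion** is `mean_high − mean_low` (reported positive, since
the low compartment lies below the high one). Volumes are voxel counts times
the voxel volume; a region with an empty compartment is not evaluable and
propagates as missing, with listwise exclusion downstream.

All attenuation analysis assumes HU normalized to a 120 kVp reference tube
voltage. Published normalizations are scanner-specific, so the correction is
a configurable per-voltage affine map `h → slope·h + intercept` whose entry
for 120 kVp must be the identity; no coefficients are invented by default
(volumes already at 120 kVp pass through unchanged).

## Geometry conventions

Voxel indices are 0-based; a voxel's physical center is
`origin + index · spacing` (voxel-center convention, matching the dominant
volumetric-format interpretation). Masks must share their volume's grid
exactly. HU outside [−1024, 3071] on file read are clamped with a warning
(reconstruction padding). Integer HU round-trip through NIfTI/NRRD as
signed 16-bit losslessly; non-integer HU fall back to float64.

### Pericoronary cylinders

A voxel belongs to the cylinder mask iff its center lies within the radius
of the centerline polyline **and** the arc-length parameter of its nearest
polyline point falls inside the window `[start, start + length]`. Nearest
points are computed against the whole polyline, with ties resolved to the
smaller segment index; no partial-volume weighting is applied — membership
is by voxel center, which keeps the operation deterministic and exactly
checkable against a brute-force oracle. Defaults: radius 4 mm, window length
40 mm, starting 10 mm from the ostium for the right coronary artery and at
the ostium for the left anterior descending and circumflex. The vessel
lumen/wall is *not* excluded: the HU bands subsequently select the adipose
voxels inside the cylinder.

### Sparse-contour interpolation

Workstations let readers outline a structure on 3–5 slices and interpolate.
The package implements shape-based interpolation: per annotated slice a
signed Euclidean distance transform (positive inside, physical in-plane
sampling), linear blending in slice index between bracketing annotations,
thresholded at zero. Annotated slices are reproduced exactly; slices outside
the annotated span stay empty. The blending scheme is this package's choice
(the workstation algorithm is unpublished); for concentric shapes it
interpolates the radius linearly. The "inserting the current interpolation
as a new annotation changes nothing" property is exact in the continuum but
can flip boundary pixels on a grid; the test suite bounds the symmetric
difference at 5% of the mask.

## Per-patient biomarkers

- **e-EAT** (enhancing EAT): `100 · (V_nc − V_ce) / V_nc`, where the V are
  total fat-band volumes of the same region on the noncontrast and
  contrast-enhanced scans. Negative values are possible (and warned about);
  a zero noncontrast volume leaves e-EAT undefined.
- **BSA indexing** uses Mosteller `sqrt(height_cm · weight_kg / 3600)`; the
  formula is the most common clinical default and is isolated in one
  function so another can be substituted.
- **Agatston score**: per axial slice, 8-connected lesions of voxels
  ≥ 130 HU with in-plane area ≥ 1 mm² contribute `area × weight` with
  weights 1/2/3/4 for peak HU 130–199/200–299/300–399/≥ 400; slice
  contributions are scaled by `slice_spacing / 3 mm`. The 1 mm² minimum
  lesion area is the canonical published rule and a documented default
  (workstations differ). Contrast-enhanced input is refused: iodinated
  blood crosses the threshold and would mimic calcium.

## Endpoint and cohort statistics

The endpoint is the first atrial-arrhythmia recurrence (> 30 s) in days
[90, 365] after ablation. Recurrences inside the 90-day blanking period are
ignored; patients without a qualifying event are censored at
`min(last follow-up, 365)`. The clock stays days-since-ablation (no
landmark re-zeroing) — the most literal reading of a "recurrence between
days 90 and 365" endpoint. Follow-up shorter than the blanking period is
flagged.

Continuous predictors enter models dichotomized **strictly above** the
cohort mean (ties go below). Kaplan–Meier curves are fit per group with
lifelines; the 1-year event rate is `1 − S(365)`. Cox models use lifelines'
partial likelihood with the Efron tie correction — day-granular times are
heavily tied — and report Wald 95% CIs and p-values; covariates can enter
raw, mean-dichotomized, threshold-dichotomized (e.g. age ≥ 70, BMI ≥ 30), or
as category indicators. The default multivariable adjustment set is
dispersion group, sex, age ≥ 70, BMI ≥ 30, AF type, and LA volume index;
an extended set adds e-EAT and the LA EAT volume index. Whether age and BMI
should enter continuous or dichotomized is genuinely ambiguous in the field;
both are expressible through covariate specs and the thresholded form is
the default. Missing values are deleted listwise per model with a logged
count.

The Mann–Whitney U test is exact for combined n ≤ 20 (full permutation
enumeration when ties invalidate the classical exact distribution) and uses
the tie-corrected normal approximation otherwise. Fisher's exact test
reports the two-sided hypergeometric p and the conditional ML odds ratio; a
zero margin yields p = 1 with an undefined odds ratio. The ICC is the
single-measure two-way mixed **consistency** form ICC(3,1)
`(MS_subjects − MS_error) / (MS_subjects + (k−1)·MS_error)`, with the
absolute-agreement form ICC(2,1) behind a flag — "two-way mixed" alone does
not pin the variant, and consistency matches the intended use (the same two
readers rate all cases). Agreement classes follow the Koo–Li bands
(< 0.5 poor, 0.5–0.75 moderate, 0.75–0.90 good, > 0.90 excellent).

## Synthetic data

### Phantom pairs

The phantom is geometrically minimal on purpose: an ellipsoidal blood pool,
a surrounding fat shell (the ROI, ~1.1·10⁵ voxels at defaults), three
bent-line coronary centerlines just outside the shell, each wrapped in a
6 mm perivascular fat sleeve with a painted 1.5 mm vessel tube, and one
small calcified plaque (peak 300 HU). Fat voxels are drawn from a
two-component mixture: with probability `pi_high` (default 0.2) uniform
around the high-band target, else uniform around the low-band target.
Uniform (not truncated-normal) within-band sampling makes the expected
compartment means equal the targets exactly, so recovery checks are
analytically clean. Defaults set the targets to the persistent-AF cohort
medians −79.2 / −26.6 HU (dispersion 52.6 HU). On the contrast phase an
independent fraction `f` of fat voxels (default 0.34, the cohort median
e-EAT) is resampled uniformly on [−14, 30] HU, emulating contrast
infiltration; because enhancement is independent of band membership, the
contrast-phase dispersion is unchanged in expectation and the measured
e-EAT converges to `f`.

What the phantom does **not** emulate: cardiac anatomy, scanner noise and
beam hardening, partial-volume mixing at fat boundaries, or registration
error between phases. Passing recovery tests therefore demonstrates the
correctness of the masking/metrics pipeline, not robustness to acquisition
physics.

### Simulated cohorts

Per patient: AF type ~ Bernoulli(0.35 persistent); LA dispersion ~
Normal(49.9 HU paroxysmal / 52.6 HU persistent, scale 2.9 HU — the scale
approximated from printed interquartile ranges and configurable); the
dispersion group is assigned at the **realized** cohort mean with the strict
`>` rule, mirroring the analysis (the cutoff is cohort-derived, not fixed);
recurrence ~ Bernoulli of the (AF type, group) probability, defaults
22 / 37 / 35 / 71%; event days uniform on [90, 365] (no timing information
is available to justify anything richer); 10% of patients get an additional
blanked recurrence on days [0, 89], which must not change any derived
endpoint; censoring is off by default (follow-up to day 365). Covariates
(age, sex, BMI, LA volume and fat-volume indices, e-EAT) are independent
normals per AF type around the published medians — their joint distribution
with dispersion is *not* modeled, so the simulated crude recurrence rate is
an emergent quantity, not a calibrated one.

The hazard-ratio recovery experiment simulates two equal groups with event
times `90 + Exponential` under proportional hazards (baseline 1-year risk
28%, true HR 2.3), administratively censored at day 365. Placing the
exponential clock after the blanking boundary means the blanking rule is
exercised without informatively censoring events, which would bias the
recovered HR; this is a design choice of the experiment, not of the
endpoint derivation.

## Problem sizes and determinism

All generators are pure functions of (spec, seed), using numpy's PCG64;
regenerating with the same seed is bit-identical. The recovery experiments
use the sizes at which their tolerances are statistically meaningful:
≥ 10⁵ fat voxels for phantom recoveries (compartment-mean standard errors
≲ 0.04 HU), n = 5,000 for hazard-ratio recovery (±10%), n = 50,000 for
stratum event rates (±1 point). Unit tests run the same machinery at
smaller sizes with proportionally wider, explicitly derived bands. The Cox
type-I-error calibration runs 1,000 null replicates at n = 200 per
replicate; at substantially smaller per-replicate sizes the Wald test is
visibly anti-conservative (a small-sample property of the test, not an
implementation artifact).

## Known limitations

- No automatic pericardium or centerline extraction; ROIs and centerlines
  are inputs.
- Noncontrast/contrast grids are assumed co-registered (or are analyzed
  independently); no registration is performed.
- No proportional-hazards diagnostics, competing risks, or imputation;
  missing data are excluded listwise.
- kVp-normalization coefficients must be supplied by the user; only the
  120 kVp identity is built in.
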