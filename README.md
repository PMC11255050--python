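# eatkit

Quantification of epicardial adipose tissue (EAT) on cardiac CT, and the
survival statistics used to relate it to atrial-fibrillation (AF) recurrence
after pulmonary vein isolation (PVI). It is aimed at cardiac-imaging
researchers who need reproducible, scriptable versions of measurements that
are usually locked inside clinical workstations.

## What it computes

EAT is the fat between the myocardium and the pericardium; on CT it occupies
the negative Hounsfield-unit (HU) range. Within a region of interest the fat
range [−195, −15] HU is split into two compartments,

- low: −195 ≤ HU ≤ −45,
- high: −45 < HU ≤ −15,

and **EAT dispersion** is the difference of the compartment means,

```
D = mean(HU | high band) − mean(HU | low band)   [HU]
```

a compact surrogate for fat heterogeneity (adipocyte hypertrophy pulls
voxels down-range; inflammation and fibrosis pull them up-range). Around it
the package provides:

- **imaging core** — NIfTI/NRRD volume and mask I/O (nibabel / SimpleITK),
  voxel-center geometry, configurable affine normalization of HU to a
  120 kVp reference tube voltage;
- **segmentation** — HU-band compartment masks; shape-based interpolation of
  sparse manual contours (signed-distance-transform blending); pericoronary
  cylinder masks of fixed radius over an arc-length window of a vessel
  centerline (default 4 mm radius, 40 mm window, starting 10 mm from the
  right-coronary ostium);
- **metrics** — compartment statistics and dispersion; enhancing-EAT
  fraction `e-EAT = 100 · (V_nc − V_ce) / V_nc` from paired
  noncontrast/contrast fat volumes; body-surface-area indexing (Mosteller);
  Agatston calcium score (130 HU threshold, 8-connected lesions ≥ 1 mm²,
  peak-HU weights, 3 mm slice normalization);
- **cohort statistics** — 1-year recurrence endpoint with a 90-day blanking
  period (events counted in days [90, 365] only), dichotomization of
  continuous predictors strictly above the cohort mean, Kaplan–Meier curves
  and 1-year event rates, Cox proportional-hazards models with Efron tie
  handling (lifelines), Mann–Whitney and Fisher exact tests, and two-way
  mixed-model ICC with Koo–Li agreement bands;
- **synthetic data** — CT phantom pairs with a known two-component fat
  attenuation mixture and enhancing fraction, and simulated AF cohorts with
  per-type dispersion distributions and stratum-level recurrence
  probabilities, so every stage is testable without patient data.

## Worked example

```bash
python examples/phantom_dispersion.py
```

```
in-band fat voxels      : 75827
mean low-band HU        :   -79.17   (target -79.2)
mean high-band HU       :   -26.63   (target -26.6)
EAT dispersion (HU)     :    52.54   (target 52.6)
total fat volume (mL)   :    42.65
```

The phantom draws fat voxels from uniform components centered at −79.2 and
−26.6 HU; the full masking-and-metrics path recovers their 52.6 HU
difference to within sampling error. The other scripts in `examples/` walk
through enhancing-EAT recovery, pericoronary sampling, Agatston scoring,
cohort survival analysis, sparse-contour interpolation, and rater-agreement
ICC, each printing the numbers it computes.

A thin CLI wraps the same library calls:

```bash
eatkit phantom --seed 1 --out scratch/phantom       # synthetic volumes
eatkit cohort-sim --seed 1 --n 208 --out cohort.csv # synthetic cohort
eatkit stats --cohort cohort.csv --out stats/       # KM + Cox + group tables
eatkit reproduce --seed 1 --out results.json        # recovery experiments
```

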