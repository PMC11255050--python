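"""Synthetic CT phantoms and simulated ablation cohorts.

No patient data ship with the package; everything downstream is exercised on
two generators whose defaults encode the study conditions the pipeline is
meant to reproduce:

* :func:`generate_phantom_pair` builds a paired noncontrast/contrast volume
  whose fat ROI voxels follow a two-component attenuation mixture (a
  low-band and a high-band uniform component, so the empirical compartment
  means converge to the configured targets without truncation bias). On the
  contrast phase an independent fraction ``f`` of fat voxels is pushed above
  -15 HU, emulating contrast infiltration; the enhancing-EAT fraction
  computed on the pair converges to ``f``. Geometry is deliberately simple:
  an ellipsoidal blood pool, a surrounding fat shell, three straight-ish
  coronary centerlines with painted vessel tubes, and a small calcified
  plaque for Agatston scoring.
* :func:`generate_cohort` simulates per-patient covariates, per-AF-type fat
  dispersion, and 1-year recurrence with a 90-day blanking structure: the
  dispersion group is assigned at the realized cohort mean (mirroring the
  analysis), the recurrence probability depends on (AF type, dispersion
  group), event days are uniform on [90, 365], and a configurable fraction
  of patients receives a blanked recurrence on days [0, 89].

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import CohortTable, PatientRecord
from .exceptions import SpecError
from .segmentation import CompartmentDefinition, pericoronary_cylinder_mask
from .volume import Centerline, CTVolume, Phase, VoxelMask

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom_pair", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameterization of a paired noncontrast/contrast fat phantom.

    Compartment targets default to the persistent-AF cohort medians
    (low -79.2 HU, high -26.6 HU, hence dispersion 52.6 HU) and the
    enhancing fraction to the cohort median e-EAT of 34%.
    """

    shape: tuple[int, int, int] = (96, 96, 72)
    spacing: tuple[float, float, float] = (0.75, 0.75, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_hu: float = 35.0
    blood_pool_hu: Mapping[str, float] = field(
        default_factory=lambda: {"noncontrast": 45.0, "contrast": 300.0}
    )
    low_mean: float = -79.2
    low_halfwidth: float = 15.0
    high_mean: float = -26.6
    high_halfwidth: float = 8.0
    pi_high: float = 0.2
    enhancing_fraction: float = 0.34
    enhanced_hu_range: tuple[float, float] = (-14.0, 30.0)
    inner_radii_mm: tuple[float, float, float] = (19.0, 19.0, 22.0)
    outer_radii_mm: tuple[float, float, float] = (27.0, 27.0, 32.0)
    vessel_radius_mm: float = 1.5
    perivascular_fat_radius_mm: float = 6.0
    vessel_hu: Mapping[str, float] = field(
        default_factory=lambda: {"noncontrast": 40.0, "contrast": 350.0}
    )
    plaque_peak_hu: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        comp = CompartmentDefinition()
        lo, hi = comp.low_band, comp.high_band
        if not (lo[0] <= self.low_mean - self.low_halfwidth
                and self.low_mean + self.low_halfwidth <= lo[1]):
            raise SpecError(
                f"low component {self.low_mean}+/-{self.low_halfwidth} leaves band {lo}"
            )
        if not (hi[0] < self.high_mean - self.high_halfwidth
                and self.high_mean + self.high_halfwidth <= hi[1]):
            raise SpecError(
                f"high component {self.high_mean}+/-{self.high_halfwidth} leaves band {hi}"
            )
        if not 0.0 <= self.pi_high <= 1.0:
            raise SpecError(f"pi_high must be in [0, 1], got {self.pi_high}")
        if not 0.0 <= self.enhancing_fraction < 1.0:
            raise SpecError(f"enhancing_fraction must be in [0, 1), got {self.enhancing_fraction}")
        if self.low_halfwidth <= 0 or self.high_halfwidth <= 0:
            raise SpecError("half-widths must be positive")


def generate_phantom_pair(
    spec: PhantomSpec = PhantomSpec(),
) -> tuple[CTVolume, CTVolume, VoxelMask, dict[str, Centerline]]:
    """Generate (noncontrast, contrast) volumes, the fat ROI, and centerlines."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    spacing = np.asarray(spec.spacing)
    origin = np.asarray(spec.origin)
    extent = (np.asarray(shape) - 1) * spacing
    center = origin + extent / 2.0

    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    mm = [origin[i] + coords[i] * spacing[i] for i in range(3)]

    def ellipsoid(radii):
        q = sum(((mm[i] - center[i]) / radii[i]) ** 2 for i in range(3))
        return q <= 1.0

    blood = ellipsoid(spec.inner_radii_mm)
    shell = ellipsoid(spec.outer_radii_mm) & ~blood

    nc = np.full(shape, spec.background_hu, dtype=float)
    ce = np.full(shape, spec.background_hu, dtype=float)
    nc[blood] = spec.blood_pool_hu["noncontrast"]
    ce[blood] = spec.blood_pool_hu["contrast"]

    # fat attenuation mixture, identical tissue on both phases
    n_eat = int(shell.sum())
    is_high = rng.random(n_eat) < spec.pi_high
    hu_eat = np.where(
        is_high,
        rng.uniform(spec.high_mean - spec.high_halfwidth,
                    spec.high_mean + spec.high_halfwidth, n_eat),
        rng.uniform(spec.low_mean - spec.low_halfwidth,
                    spec.low_mean + spec.low_halfwidth, n_eat),
    )
    nc[shell] = hu_eat
    hu_ce = hu_eat.copy()
    enhanced = rng.random(n_eat) < spec.enhancing_fraction
    hu_ce[enhanced] = rng.uniform(*spec.enhanced_hu_range, int(enhanced.sum()))
    ce[shell] = hu_ce

    # three coronary-like centerlines with a slight bend, running axially just
    # outside the fat shell, each wrapped in its own perivascular fat sleeve
    z0, z1 = origin[2] + 2.0, origin[2] + extent[2] - 2.0
    zm = (z0 + z1) / 2.0
    directions = {"rca": (1.0, 0.0), "lad": (-1.0, 0.0), "lcx": (0.0, 1.0)}
    shell_r = max(spec.outer_radii_mm[0], spec.outer_radii_mm[1])
    dist = shell_r + 2.0
    centerlines: dict[str, Centerline] = {}
    for name, (dx, dy) in directions.items():
        x, y = center[0] + dx * dist, center[1] + dy * dist
        pts = np.array([[x, y, z0], [x + 2.0, y, zm], [x, y, z1]])
        centerlines[name] = Centerline(pts)

    grid_ref = VoxelMask(np.zeros(shape, dtype=bool), tuple(spec.spacing), tuple(spec.origin))
    vessel_all = np.zeros(shape, dtype=bool)
    for name, cl in centerlines.items():
        sleeve = pericoronary_cylinder_mask(
            grid_ref, cl, radius=spec.perivascular_fat_radius_mm,
            start_offset=0.0, length=cl.total_length - 1e-9,
        ).voxels
        sleeve &= ~shell & ~blood  # do not disturb the paired LA fat voxels
        n_pv = int(sleeve.sum())
        pv_high = rng.random(n_pv) < spec.pi_high
        pv_hu = np.where(
            pv_high,
            rng.uniform(spec.high_mean - spec.high_halfwidth,
                        spec.high_mean + spec.high_halfwidth, n_pv),
            rng.uniform(spec.low_mean - spec.low_halfwidth,
                        spec.low_mean + spec.low_halfwidth, n_pv),
        )
        nc[sleeve] = pv_hu
        ce[sleeve] = pv_hu
        tube = pericoronary_cylinder_mask(
            grid_ref, cl, radius=spec.vessel_radius_mm,
            start_offset=0.0, length=cl.total_length - 1e-9,
        ).voxels
        nc[tube] = spec.vessel_hu["noncontrast"]
        ce[tube] = spec.vessel_hu["contrast"]
        vessel_all |= tube

    # one small calcified plaque next to the RCA (present on both phases)
    if spec.plaque_peak_hu >= 130:
        rca = centerlines["rca"].points
        pi_idx = np.round((rca[0] + np.array([3.0, 0.0, 10.0]) - origin) / spacing).astype(int)
        pi_idx = np.clip(pi_idx, 1, np.asarray(shape) - 3)
        i, j, k = pi_idx
        nc[i : i + 2, j : j + 2, k] = spec.plaque_peak_hu - 50.0
        nc[i, j, k] = spec.plaque_peak_hu
        ce[i : i + 2, j : j + 2, k] = spec.plaque_peak_hu - 50.0
        ce[i, j, k] = spec.plaque_peak_hu

    roi = VoxelMask(shell & ~vessel_all, tuple(spec.spacing), tuple(spec.origin))
    vol_nc = CTVolume(nc, tuple(spec.spacing), tuple(spec.origin),
                      tube_voltage=120.0, phase=Phase.NONCONTRAST)
    vol_ce = CTVolume(ce, tuple(spec.spacing), tuple(spec.origin),
                      tube_voltage=120.0, phase=Phase.CONTRAST)
    return vol_nc, vol_ce, roi, centerlines


@dataclass(frozen=True)
class CohortSpec:
    """Parameterization of a simulated first-ablation AF cohort.

    Defaults encode the study-population summaries: 208 patients, 35%
    persistent AF, per-type fat-dispersion locations 49.9 / 52.6 HU (scale
    2.9 HU, approximated from the printed interquartile ranges), and 1-year
    recurrence probabilities by (AF type, dispersion group) of 22% / 37% /
    35% / 71%. Event days are uniform on [90, 365]; a 10% fraction of
    patients additionally gets a blanked recurrence on days [0, 89].
    """

    n: int = 208
    persistent_prevalence: float = 0.35
    dispersion_loc: Mapping[str, float] = field(
        default_factory=lambda: {"paroxysmal": 49.9, "persistent": 52.6}
    )
    dispersion_scale: float = 2.9
    recurrence_prob: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("paroxysmal", "below"): 0.22,
            ("paroxysmal", "above"): 0.37,
            ("persistent", "below"): 0.35,
            ("persistent", "above"): 0.71,
        }
    )
    pre_blanking_fraction: float = 0.10
    censor_fraction: float = 0.0
    age_loc: float = 64.0
    age_scale: float = 10.0
    male_prob: float = 0.75
    bmi_loc: Mapping[str, float] = field(
        default_factory=lambda: {"paroxysmal": 27.0, "persistent": 30.0}
    )
    bmi_scale: float = 4.5
    la_volume_index_loc: Mapping[str, float] = field(
        default_factory=lambda: {"paroxysmal": 62.0, "persistent": 84.0}
    )
    la_volume_index_scale: float = 16.0
    la_eat_volume_index_loc: Mapping[str, float] = field(
        default_factory=lambda: {"paroxysmal": 13.0, "persistent": 17.0}
    )
    la_eat_volume_index_scale: float = 5.0
    e_eat_loc: Mapping[str, float] = field(
        default_factory=lambda: {"paroxysmal": 32.0, "persistent": 37.0}
    )
    e_eat_scale: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SpecError(f"n must be >= 2, got {self.n}")
        probs = [self.persistent_prevalence, self.pre_blanking_fraction,
                 self.censor_fraction, self.male_prob, *self.recurrence_prob.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SpecError("all probabilities must lie in [0, 1]")
        if self.dispersion_scale <= 0:
            raise SpecError("dispersion_scale must be > 0")

    def with_n(self, n: int) -> "CohortSpec":
        return replace(self, n=n)


def generate_cohort(spec: CohortSpec = CohortSpec()) -> CohortTable:
    """Simulate a cohort table reproducible from (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    persistent = rng.random(n) < spec.persistent_prevalence
    af_type = np.where(persistent, "persistent", "paroxysmal")
    loc = np.where(persistent, spec.dispersion_loc["persistent"],
                   spec.dispersion_loc["paroxysmal"])
    dispersion = rng.normal(loc, spec.dispersion_scale)
    # group assignment mirrors the analysis: realized cohort mean, strict >
    above = dispersion > dispersion.mean()
    group = np.where(above, "above", "below")
    p = np.array([spec.recurrence_prob[(a, g)] for a, g in zip(af_type, group)])
    recur = rng.random(n) < p
    event_day = rng.integers(90, 366, size=n)
    pre_blank = rng.random(n) < spec.pre_blanking_fraction
    blank_day = rng.integers(0, 90, size=n)
    censored = (~recur) & (rng.random(n) < spec.censor_fraction)
    censor_day = rng.integers(90, 366, size=n)

    age = rng.normal(spec.age_loc, spec.age_scale, n).clip(18, 95)
    male = rng.random(n) < spec.male_prob
    bmi = rng.normal(np.where(persistent, spec.bmi_loc["persistent"],
                              spec.bmi_loc["paroxysmal"]), spec.bmi_scale, n).clip(15, 60)
    lavi = rng.normal(np.where(persistent, spec.la_volume_index_loc["persistent"],
                               spec.la_volume_index_loc["paroxysmal"]),
                      spec.la_volume_index_scale, n).clip(20, 200)
    laeat = rng.normal(np.where(persistent, spec.la_eat_volume_index_loc["persistent"],
                                spec.la_eat_volume_index_loc["paroxysmal"]),
                       spec.la_eat_volume_index_scale, n).clip(2, 60)
    eeat = rng.normal(np.where(persistent, spec.e_eat_loc["persistent"],
                               spec.e_eat_loc["paroxysmal"]), spec.e_eat_scale, n).clip(-10, 90)

    records = []
    for i in range(n):
        days: list[float] = []
        if pre_blank[i]:
            days.append(float(blank_day[i]))
        if recur[i]:
            days.append(float(event_day[i]))
        fu = 365.0
        if censored[i]:
            fu = float(censor_day[i])
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                age=float(age[i]),
                sex="male" if male[i] else "female",
                bmi=float(bmi[i]),
                af_type=str(af_type[i]),
                la_dispersion_hu=float(dispersion[i]),
                la_volume_index=float(lavi[i]),
                la_eat_volume_index=float(laeat[i]),
                e_eat_pct=float(eeat[i]),
                recurrence_days=sorted(days),
                last_followup_day=fu,
            )
        )
    return CohortTable.from_records(records)
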