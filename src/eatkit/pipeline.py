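"""Configuration-driven orchestration: per-patient metrics and cohort stats.

`run_patient` chains the imaging operations (kVp normalization, fat
compartment masks, pericoronary cylinders, e-EAT, Agatston, BSA indexing)
into one metrics CSV row; `run_cohort` chains the statistical pipeline
(blanking-period endpoints, mean dichotomization, group comparisons,
Kaplan-Meier curves, univariate and multivariable Cox models) into report
tables. Both are deterministic given identical inputs and configuration,
and log structured JSON-lines events including per-patient exclusions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import metrics as mx
from .exceptions import EatkitError
from .segmentation import (
    VESSEL_WINDOWS,
    CompartmentDefinition,
    compartment_masks,
    pericoronary_cylinder_mask,
)
from .volume import (
    IDENTITY_CALIBRATION,
    Centerline,
    CTVolume,
    VoxelMask,
    adjust_to_reference_kvp,
)

log = logging.getLogger("eatkit.pipeline")

#: Univariate Cox covariates (one model per entry).
UNIVARIATE_COVARIATES: tuple[ch.CovariateSpec, ...] = (
    ch.CovariateSpec("male_sex", "sex", "binary", positive_level="male"),
    ch.CovariateSpec("age_ge_70", "age", "threshold", threshold=70.0),
    ch.CovariateSpec("bmi_ge_30", "bmi", "threshold", threshold=30.0),
    ch.CovariateSpec("persistent_af", "af_type", "binary", positive_level="persistent"),
    ch.CovariateSpec("la_volume_index_above_mean", "la_volume_index", "mean_dichotomized"),
    ch.CovariateSpec("la_eat_volume_index", "la_eat_volume_index", "raw"),
    ch.CovariateSpec("e_eat_above_mean", "e_eat_pct", "mean_dichotomized"),
    ch.CovariateSpec("la_dispersion_above_mean", "la_dispersion_hu", "mean_dichotomized"),
)

#: Default multivariable adjustment set: dispersion adjusted for sex, age,
#: BMI, AF type and LA volume index.
MULTIVARIABLE_COVARIATES: tuple[ch.CovariateSpec, ...] = (
    ch.CovariateSpec("la_dispersion_above_mean", "la_dispersion_hu", "mean_dichotomized"),
    ch.CovariateSpec("male_sex", "sex", "binary", positive_level="male"),
    ch.CovariateSpec("age_ge_70", "age", "threshold", threshold=70.0),
    ch.CovariateSpec("bmi_ge_30", "bmi", "threshold", threshold=30.0),
    ch.CovariateSpec("persistent_af", "af_type", "binary", positive_level="persistent"),
    ch.CovariateSpec("la_volume_index_above_mean", "la_volume_index", "mean_dichotomized"),
)

#: Extended multivariable set (adds enhancing-EAT and fat volume index).
MULTIVARIABLE_COVARIATES_EXTENDED: tuple[ch.CovariateSpec, ...] = MULTIVARIABLE_COVARIATES + (
    ch.CovariateSpec("e_eat_above_mean", "e_eat_pct", "mean_dichotomized"),
    ch.CovariateSpec("la_eat_volume_index", "la_eat_volume_index", "raw"),
)

CONTINUOUS_COMPARISON_COLUMNS = (
    "age",
    "bmi",
    "la_dispersion_hu",
    "la_volume_index",
    "la_eat_volume_index",
    "e_eat_pct",
)


@dataclass
class RunConfig:
    """One reproducible run: inputs, analysis parameters, output directory."""

    output_dir: Optional[Path] = None
    seed: int = 0
    compartments: CompartmentDefinition = field(default_factory=CompartmentDefinition)
    calibration: Mapping[float, tuple[float, float]] = field(
        default_factory=lambda: dict(IDENTITY_CALIBRATION)
    )
    cylinder_radius_mm: float = 4.0
    vessel_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(VESSEL_WINDOWS)
    )
    extended_multivariable: bool = False
    log_path: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        for key in ("seed", "cylinder_radius_mm", "extended_multivariable"):
            if key in raw:
                kwargs[key] = raw[key]
        if "compartments" in raw:
            c = raw["compartments"]
            kwargs["compartments"] = CompartmentDefinition(
                tuple(c["low_band"]), tuple(c["high_band"])
            )
        if "calibration" in raw:
            kwargs["calibration"] = {
                float(k): tuple(v) for k, v in raw["calibration"].items()
            }
        if "vessel_windows" in raw:
            kwargs["vessel_windows"] = {
                k: tuple(v) for k, v in raw["vessel_windows"].items()
            }
        return cls(**kwargs)


def _emit(config: RunConfig, event: str, **fields) -> None:
    record = {"event": event, **fields}
    log.info(json.dumps(record, default=str))
    if config.log_path is not None:
        with open(config.log_path, "a") as fh:
            fh.write(json.dumps(record, default=str) + "\n")


def run_patient(
    config: RunConfig,
    patient_id: str,
    contrast: CTVolume,
    roi_contrast: VoxelMask,
    noncontrast: Optional[CTVolume] = None,
    roi_noncontrast: Optional[VoxelMask] = None,
    centerlines: Optional[Mapping[str, Centerline]] = None,
    height_cm: Optional[float] = None,
    weight_kg: Optional[float] = None,
    la_volume_ml: Optional[float] = None,
) -> mx.PatientMetrics:
    """Compute one patient's imaging biomarkers.

    The contrast scan and its fat ROI are required; everything else degrades
    gracefully (contrast-only runs leave e-EAT missing, no noncontrast scan
    leaves the Agatston score missing, no anthropometrics leave the indexed
    volumes missing). Any stage failure is logged as a structured error and
    the affected fields stay missing, so a cohort run continues past a bad
    patient.
    """
    out = mx.PatientMetrics(patient_id=patient_id)
    comp = config.compartments
    try:
        ce = adjust_to_reference_kvp(contrast, config.calibration)
        roi_contrast.require_same_grid(ce)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.la = mx.compute_eat_stats(ce, roi_contrast, comp)
        if not out.la.evaluable:
            _emit(config, "patient_warning", patient_id=patient_id,
                  stage="la_stats", reason="empty fat compartment")
    except EatkitError as exc:
        _emit(config, "patient_error", patient_id=patient_id, stage="la_stats",
              error=type(exc).__name__, message=str(exc))
        return out

    for vessel, cl in (centerlines or {}).items():
        if vessel not in config.vessel_windows:
            continue
        start, length = config.vessel_windows[vessel]
        try:
            cyl = pericoronary_cylinder_mask(
                ce, cl, radius=config.cylinder_radius_mm,
                start_offset=start, length=length,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                setattr(out, vessel, mx.compute_eat_stats(ce, cyl, comp))
        except EatkitError as exc:
            _emit(config, "patient_error", patient_id=patient_id,
                  stage=f"{vessel}_cylinder", error=type(exc).__name__, message=str(exc))

    if noncontrast is not None:
        try:
            nc = adjust_to_reference_kvp(noncontrast, config.calibration)
            out.agatston = mx.agatston_score(nc)
            if roi_noncontrast is not None:
                roi_noncontrast.require_same_grid(nc)
                _, _, total_nc = compartment_masks(nc, roi_noncontrast, comp)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    out.e_eat_pct = mx.compute_eeat(
                        total_nc.volume_ml(), out.la.vol_total
                    )
        except EatkitError as exc:
            _emit(config, "patient_error", patient_id=patient_id,
                  stage="noncontrast", error=type(exc).__name__, message=str(exc))
    else:
        _emit(config, "patient_warning", patient_id=patient_id,
              stage="noncontrast", reason="contrast-only run: e-EAT/Agatston missing")

    if height_cm is not None and weight_kg is not None:
        try:
            out.bsa = mx.bsa_mosteller(height_cm, weight_kg)
            if la_volume_ml is not None:
                out.la_volume_index = la_volume_ml / out.bsa
            if not np.isnan(out.la.vol_total):
                out.la_eat_volume_index = out.la.vol_total / out.bsa
        except EatkitError as exc:
            _emit(config, "patient_error", patient_id=patient_id, stage="bsa",
                  error=type(exc).__name__, message=str(exc))
    _emit(config, "patient_done", patient_id=patient_id,
          la_dispersion_hu=out.la.dispersion)
    return out


def metrics_table(rows: Sequence[mx.PatientMetrics]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in rows], columns=mx.METRICS_COLUMNS)


def _comparison_table(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-AF-type group comparison (continuous: Mann-Whitney; sex: Fisher)."""
    rows = []
    by_type = {t: df[df["af_type"] == t] for t in ("paroxysmal", "persistent")}
    degenerate = any(len(g) == 0 for g in by_type.values())
    if degenerate:
        warnings.warn("only one AF type present: group comparison not possible")
        _emit(config, "comparison_skipped", reason="single AF type")
    for col in CONTINUOUS_COMPARISON_COLUMNS:
        if col not in df.columns:
            continue
        x = by_type["paroxysmal"][col].dropna() if not degenerate else pd.Series(dtype=float)
        y = by_type["persistent"][col].dropna() if not degenerate else pd.Series(dtype=float)
        if len(x) == 0 or len(y) == 0:
            rows.append({"variable": col, "paroxysmal": np.nan,
                         "persistent": np.nan, "p": np.nan})
            continue
        res = ch.mann_whitney(x, y)
        fmt = lambda s: f"{s.median():.1f} ({s.quantile(0.25):.1f}, {s.quantile(0.75):.1f})"  # noqa: E731
        rows.append({"variable": col, "paroxysmal": fmt(x),
                     "persistent": fmt(y), "p": res.p})
    if not degenerate:
        table = [
            [int((by_type[t]["sex"] == "male").sum()),
             int((by_type[t]["sex"] == "female").sum())]
            for t in ("paroxysmal", "persistent")
        ]
        res = ch.fisher_exact(table)
        rows.append({
            "variable": "male_sex",
            "paroxysmal": f"{table[0][0]}/{sum(table[0])}",
            "persistent": f"{table[1][0]}/{sum(table[1])}",
            "p": res.p,
        })
    return pd.DataFrame(rows)


def _km_tables(df: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    groupings = {
        "dispersion_group": df["dispersion_group"],
        "af_type": df["af_type"],
        "af_type_x_dispersion": df["af_type"].astype(str) + "/" + df["dispersion_group"].astype(str),
    }
    curve_rows, rate_rows = [], []
    for name, groups in groupings.items():
        if groups.dropna().nunique() < 2:
            warnings.warn(f"grouping {name!r} has < 2 levels: KM comparison skipped")
            _emit(config, "km_skipped", grouping=name, reason="<2 levels")
        fit = ch.km_estimate(df["time"], df["event"], groups)
        for g, curve in fit.curves.items():
            for _, r in curve.iterrows():
                curve_rows.append({"grouping": name, "group": g, "time": r["time"],
                                   "survival": r["survival"], "at_risk": r["at_risk"]})
            rate_rows.append({"grouping": name, "group": g,
                              "event_rate_365_pct": 100.0 * fit.event_rate_365[g]})
    return pd.DataFrame(curve_rows), pd.DataFrame(rate_rows)


def run_cohort(config: RunConfig, cohort: ch.CohortTable) -> dict[str, pd.DataFrame]:
    """Run the full statistical pipeline on a cohort table.

    Returns (and, if an output directory is configured, writes as CSV) the
    group-comparison table, the univariate and multivariable Cox tables, the
    Kaplan-Meier curves for the dispersion / AF-type / combined groupings,
    and the per-stratum 1-year event rates.
    """
    df = ch.add_endpoints(cohort)
    labels, cutoff = ch.dichotomize_at_mean(df["la_dispersion_hu"])
    df["dispersion_group"] = labels
    _emit(config, "dichotomize", column="la_dispersion_hu", cutoff=cutoff)

    comparison = _comparison_table(df, config)

    uni_rows = []
    for spec in UNIVARIATE_COVARIATES:
        if spec.column not in df.columns:
            continue
        try:
            fit = ch.cox_fit(df, [spec])
            uni_rows.append(fit.summary.iloc[0].to_dict())
        except EatkitError as exc:
            _emit(config, "cox_skipped", covariate=spec.name,
                  error=type(exc).__name__, message=str(exc))
            uni_rows.append({"term": spec.name, "hr": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan})
    cox_uni = pd.DataFrame(uni_rows)

    multi_set = (MULTIVARIABLE_COVARIATES_EXTENDED if config.extended_multivariable
                 else MULTIVARIABLE_COVARIATES)
    multi_set = tuple(s for s in multi_set if s.column in df.columns)
    try:
        cox_multi = ch.cox_fit(df, multi_set).summary
    except EatkitError as exc:
        _emit(config, "cox_skipped", covariate="multivariable",
              error=type(exc).__name__, message=str(exc))
        cox_multi = pd.DataFrame(columns=["term", "hr", "ci_low", "ci_high", "p"])

    km_curves, km_rates = _km_tables(df, config)
    out = {
        "group_comparison": comparison,
        "cox_univariate": cox_uni,
        "cox_multivariable": cox_multi,
        "km_curves": km_curves,
        "km_event_rates": km_rates,
    }
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in out.items():
            table.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
        _emit(config, "cohort_done", output_dir=str(outdir), n=len(df))
    return out
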