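"""Cohort statistics for 1-year arrhythmia-recurrence analysis.

The endpoint is recurrence of an atrial arrhythmia (> 30 s) between days 90
and 365 after ablation; the first 90 days are a blanking period whose
recurrences do not count. Continuous predictors are dichotomized at the
cohort mean (strictly above vs at-or-below). Group survival is summarized
with Kaplan-Meier curves and the 1-year event rate ``1 - S(365)``; effect
sizes come from Cox proportional-hazards models (Efron tie handling, as
day-granular times are heavily tied). Group comparisons use the
Mann-Whitney U test (continuous) and Fisher's exact test (categorical);
rater agreement uses a two-way mixed-model intraclass correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .exceptions import FitError, InputError

__all__ = [
    "PatientRecord",
    "CohortTable",
    "Endpoint",
    "CovariateSpec",
    "SurvivalFit",
    "ICCResult",
    "derive_endpoint",
    "add_endpoints",
    "dichotomize_at_mean",
    "km_estimate",
    "cox_fit",
    "mann_whitney",
    "fisher_exact",
    "icc_two_way_mixed",
]

BLANKING_DAYS = 90
FOLLOWUP_DAYS = 365

#: Column dictionary of the cohort CSV dialect.
COHORT_COLUMNS = {
    "patient_id": "unique patient identifier",
    "age": "age in years",
    "sex": "male | female",
    "bmi": "body mass index, kg/m^2",
    "af_type": "paroxysmal | persistent",
    "la_dispersion_hu": "left-atrial EAT dispersion, HU",
    "la_volume_index": "CT LA volume indexed by BSA, mL/m^2",
    "la_eat_volume_index": "CT LA EAT volume indexed by BSA, mL/m^2",
    "e_eat_pct": "enhancing-EAT fraction, percent",
    "recurrence_days": "semicolon-joined days post-ablation with arrhythmia > 30 s",
    "last_followup_day": "last follow-up day post-ablation",
}


@dataclass
class PatientRecord:
    """One patient's covariates, imaging metrics, and follow-up."""

    patient_id: str
    age: float
    sex: str
    bmi: float
    af_type: str
    la_dispersion_hu: float = float("nan")
    la_volume_index: float = float("nan")
    la_eat_volume_index: float = float("nan")
    e_eat_pct: float = float("nan")
    recurrence_days: list[float] = field(default_factory=list)
    last_followup_day: float = FOLLOWUP_DAYS

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InputError(f"sex must be male/female, got {self.sex!r}")
        if self.af_type not in ("paroxysmal", "persistent"):
            raise InputError(f"af_type must be paroxysmal/persistent, got {self.af_type!r}")
        if any(d < 0 for d in self.recurrence_days) or self.last_followup_day < 0:
            raise InputError("days must be >= 0")
        if self.recurrence_days and self.last_followup_day < max(self.recurrence_days):
            raise InputError("last_followup_day must cover all recorded recurrences")


class Endpoint(NamedTuple):
    event: int
    time: float
    short_followup: bool


def derive_endpoint(record: "PatientRecord | Sequence[float]", last_followup_day: float | None = None) -> Endpoint:
    """Blanking-period endpoint: first recurrence in days [90, 365].

    Recurrences before day 90 are blanked and recurrences after day 365 fall
    outside the 1-year window; in either case the patient is censored at
    ``min(last_followup, 365)``. Follow-up shorter than the blanking period
    cannot yield an event and is flagged.
    """
    if isinstance(record, PatientRecord):
        days, fu = record.recurrence_days, record.last_followup_day
    else:
        if last_followup_day is None:
            raise InputError("last_followup_day required when passing raw recurrence days")
        days, fu = list(record), float(last_followup_day)
    qualifying = [d for d in days if BLANKING_DAYS <= d <= FOLLOWUP_DAYS]
    if qualifying:
        return Endpoint(1, float(min(qualifying)), False)
    return Endpoint(0, float(min(fu, FOLLOWUP_DAYS)), fu < BLANKING_DAYS)


@dataclass
class CohortTable:
    """A cohort as a pandas DataFrame with the documented column dialect."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise InputError("cohort is empty")
        if self.df["patient_id"].duplicated().any():
            raise InputError("patient_ids must be unique")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord]) -> "CohortTable":
        rows = []
        for r in records:
            row = {k: getattr(r, k) for k in COHORT_COLUMNS if k != "recurrence_days"}
            row["recurrence_days"] = ";".join(f"{d:g}" for d in r.recurrence_days)
            rows.append(row)
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, dtype={"patient_id": str, "recurrence_days": str})
        df["recurrence_days"] = df["recurrence_days"].fillna("")
        return cls(df)

    def to_csv(self, path: str | Path) -> Path:
        self.df.to_csv(path, index=False)
        return Path(path)

    def recurrence_day_lists(self) -> list[list[float]]:
        out = []
        for v in self.df["recurrence_days"]:
            if isinstance(v, (list, tuple, np.ndarray)):
                out.append([float(d) for d in v])
            elif v is None or (isinstance(v, float) and math.isnan(v)) or str(v) == "":
                out.append([])
            else:
                out.append([float(d) for d in str(v).split(";") if d != ""])
        return out


def add_endpoints(cohort: CohortTable) -> pd.DataFrame:
    """Return the cohort frame with derived ``event``/``time`` columns."""
    df = cohort.df.copy()
    eps = [
        derive_endpoint(days, fu)
        for days, fu in zip(cohort.recurrence_day_lists(), df["last_followup_day"])
    ]
    df["event"] = [e.event for e in eps]
    df["time"] = [e.time for e in eps]
    df["short_followup"] = [e.short_followup for e in eps]
    n_short = int(df["short_followup"].sum())
    if n_short:
        warnings.warn(f"{n_short} patients with follow-up shorter than the blanking period")
    return df


def dichotomize_at_mean(values: Sequence[float]) -> tuple[pd.Series, float]:
    """Label values 'above'/'below' their arithmetic mean (strictly above).

    Missing values keep a missing label and are excluded from the cutoff.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    nonmiss = s.dropna()
    if len(nonmiss) < 2:
        raise InputError("need >= 2 non-missing values to dichotomize")
    cutoff = float(nonmiss.mean())
    labels = pd.Series(pd.NA, index=s.index, dtype="object")
    labels[s.notna()] = np.where(s[s.notna()] > cutoff, "above", "below")
    return labels, cutoff


@dataclass
class SurvivalFit:
    """Cox hazard ratios and/or Kaplan-Meier curves."""

    summary: Optional[pd.DataFrame] = None  # term, hr, ci_low, ci_high, p
    curves: Optional[dict] = None  # group -> DataFrame(time, survival, at_risk)
    event_rate_365: Optional[dict] = None  # group -> 1 - S(365)


def km_estimate(
    time: Sequence[float],
    event: Sequence[int],
    groups: Sequence,
) -> SurvivalFit:
    """Product-limit survival per group and the 1-year event rate.

    Empty or all-missing groups are skipped with a warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = pd.Series(list(groups))
    curves: dict = {}
    rates: dict = {}
    n_missing = int(groups.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} patients with empty group label: excluded from curves")
    for g in groups.dropna().unique():
        sel = (groups == g).to_numpy()
        if not sel.any():
            warnings.warn(f"group {g!r} is empty: no curve")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curves[g] = pd.DataFrame(
            {"time": surv.index.values, "survival": surv.values, "at_risk": at_risk.values}
        )
        rates[g] = float(1.0 - kmf.predict(FOLLOWUP_DAYS))
    return SurvivalFit(curves=curves, event_rate_365=rates)


@dataclass(frozen=True)
class CovariateSpec:
    """How a cohort column enters a Cox model.

    mode 'raw' uses the numeric column as-is; 'mean_dichotomized' enters an
    indicator for strictly-above-the-cohort-mean; 'threshold' an indicator
    for at-or-above a fixed cutoff (e.g. age >= 70); 'binary' an indicator
    for ``positive_level`` of a categorical column.
    """

    name: str
    column: str
    mode: str = "raw"
    positive_level: Optional[str] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "mean_dichotomized", "binary", "threshold"):
            raise InputError(f"unknown covariate mode {self.mode!r}")
        if self.mode == "binary" and self.positive_level is None:
            raise InputError("binary covariates need positive_level")
        if self.mode == "threshold" and self.threshold is None:
            raise InputError("threshold covariates need a threshold")


def _design_matrix(df: pd.DataFrame, covariates: Sequence[CovariateSpec]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for c in covariates:
        col = df[c.column]
        if c.mode == "raw":
            X[c.name] = pd.to_numeric(col, errors="coerce")
        elif c.mode == "mean_dichotomized":
            labels, _ = dichotomize_at_mean(col)
            X[c.name] = labels.map({"above": 1.0, "below": 0.0})
        elif c.mode == "threshold":
            num = pd.to_numeric(col, errors="coerce")
            X[c.name] = np.where(num.isna(), np.nan, (num >= c.threshold).astype(float))
        else:
            X[c.name] = np.where(col.isna(), np.nan, (col == c.positive_level).astype(float))
    return X


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[CovariateSpec],
    duration_col: str = "time",
    event_col: str = "event",
) -> SurvivalFit:
    """Cox proportional-hazards fit with Efron tie handling.

    Rows with any missing covariate are excluded listwise (count logged as a
    warning). Raises :class:`FitError` when there are no events, a covariate
    is constant, or the partial likelihood does not converge.
    """
    X = _design_matrix(df, covariates)
    data = X.copy()
    data["_time"] = pd.to_numeric(df[duration_col])
    data["_event"] = pd.to_numeric(df[event_col])
    n0 = len(data)
    data = data.dropna()
    if len(data) < n0:
        warnings.warn(f"excluded {n0 - len(data)} rows with missing values (listwise)")
    if len(data) == 0 or data["_event"].sum() == 0:
        raise FitError("no events in the analysis set")
    for c in covariates:
        if data[c.name].nunique() <= 1:
            raise FitError(f"covariate {c.name!r} is constant")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines raises several convergence errors
        raise FitError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "term": s.index,
            "hr": s["exp(coef)"].values,
            "ci_low": s["exp(coef) lower 95%"].values,
            "ci_high": s["exp(coef) upper 95%"].values,
            "p": s["p"].values,
        }
    ).reset_index(drop=True)
    return SurvivalFit(summary=summary)


class TestResult(NamedTuple):
    statistic: float
    p: float


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U test, two-sided.

    Exact for combined n <= 20 (full permutation enumeration when ties make
    the classical exact distribution invalid), tie-corrected normal
    approximation otherwise. The returned U is the midrank U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("both samples must be nonempty")
    u = _u_statistic(x, y)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20:
        if not has_ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            return TestResult(float(res.statistic), float(res.pvalue))
        perm = stats.permutation_test(
            (x, y),
            _u_statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=200_000,  # > C(20,10): full enumeration
        )
        return TestResult(u, float(perm.pvalue))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue))


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided hypergeometric p (tables with probability at most the observed
    one) and the conditional maximum-likelihood odds ratio. A zero row or
    column margin carries no information: p = 1 and the odds ratio is NaN.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise InputError("table must be 2x2 nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(float("nan"), 1.0)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    orr = stats.contingency.odds_ratio(t, kind="conditional")
    return TestResult(float(orr.statistic), float(p))


#: Koo & Li agreement bands for ICC interpretation.
def koo_li_class(icc: float) -> str:
    if math.isnan(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


class ICCResult(NamedTuple):
    icc: float
    agreement: str
    ms_subjects: float
    ms_raters: float
    ms_error: float


def icc_two_way_mixed(
    ratings: Sequence[Sequence[float]], model: str = "consistency"
) -> ICCResult:
    """Single-measure two-way mixed-model intraclass correlation.

    ``model='consistency'`` gives ICC(3,1) = (MS_R - MS_E)/(MS_R + (k-1) MS_E)
    from the two-way ANOVA mean squares (subjects x raters, no replication);
    ``model='agreement'`` gives the absolute-agreement form ICC(2,1), which
    additionally charges the rater variance. Constant ratings across all
    subjects leave the ICC undefined (NaN).
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise InputError("ratings must be n x k with n >= 3 subjects, k >= 2 raters")
    if np.isnan(X).any():
        raise InputError("missing cells are not supported")
    if model not in ("consistency", "agreement"):
        raise InputError(f"unknown ICC model {model!r}")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if model == "consistency":
        denom = ms_rows + (k - 1) * ms_err
    else:
        denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if denom == 0:
        warnings.warn("constant ratings: ICC undefined")
        icc = float("nan")
    else:
        icc = (ms_rows - ms_err) / denom
    return ICCResult(icc, koo_li_class(icc), ms_rows, ms_cols, ms_err)
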