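import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eatkit.cohort import (
    CovariateSpec,
    PatientRecord,
    _u_statistic,
    cox_fit,
    derive_endpoint,
    dichotomize_at_mean,
    fisher_exact,
    icc_two_way_mixed,
    km_estimate,
    mann_whitney,
)
from eatkit.exceptions import FitError, InputError


class TestEndpoint:
    @pytest.mark.parametrize(
        "days,fu,event,time",
        [
            ([45], 365, 0, 365),        # blanked recurrence only
            ([45, 120], 365, 1, 120),   # first qualifying event
            ([400], 400, 0, 365),       # recurrence outside the 1-year window
            ([], 200, 0, 200),          # censored before 1 year
            ([90], 365, 1, 90),         # day 90 itself counts
            ([365], 365, 1, 365),       # day 365 itself counts
        ],
    )
    def test_blanking_window_rules(self, days, fu, event, time):
        ep = derive_endpoint(days, fu)
        assert (ep.event, ep.time) == (event, time)

    def test_short_followup_flagged(self):
        ep = derive_endpoint([], 60)
        assert ep.event == 0 and ep.time == 60 and ep.short_followup

    @given(
        days=st.lists(st.floats(0, 500, allow_nan=False), max_size=5),
        fu=st.floats(0, 500, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_never_event_outside_window(self, days, fu):
        fu = max([fu] + days)
        ep = derive_endpoint(days, fu)
        assert 0 <= ep.time <= 365
        if ep.event:
            assert 90 <= ep.time <= 365
            assert ep.time in days

    def test_record_invariants(self):
        with pytest.raises(InputError):
            PatientRecord("p1", 60, "male", 25, "paroxysmal",
                          recurrence_days=[200], last_followup_day=150)


class TestDichotomize:
    def test_strict_inequality_at_cutoff(self):
        labels, cutoff = dichotomize_at_mean([1.0, 2.0, 3.0])
        assert cutoff == 2.0
        assert list(labels) == ["below", "below", "above"]

    def test_all_equal_labels_below(self):
        labels, cutoff = dichotomize_at_mean([5.0, 5.0, 5.0])
        assert cutoff == 5.0 and set(labels) == {"below"}

    def test_symmetric_distribution_splits_in_half(self, rng):
        vals = rng.normal(0, 1, 10_000)
        labels, _ = dichotomize_at_mean(vals)
        assert (labels == "above").mean() == pytest.approx(0.5, abs=0.02)

    def test_missing_values_keep_missing_labels(self):
        labels, cutoff = dichotomize_at_mean([1.0, np.nan, 3.0])
        assert cutoff == 2.0 and pd.isna(labels[1])
        with pytest.raises(InputError):
            dichotomize_at_mean([np.nan, 1.0])

    def test_groups_partition_non_missing(self, rng):
        vals = rng.normal(50, 3, 500)
        labels, _ = dichotomize_at_mean(vals)
        assert ((labels == "above") | (labels == "below")).all()


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        """event@100, censored@200, event@300: S=2/3 after 100, 0 after 300."""
        fit = km_estimate([100, 200, 300], [1, 0, 1], ["g", "g", "g"])
        curve = fit.curves["g"].set_index("time")["survival"]
        assert curve.loc[100] == pytest.approx(2 / 3)
        assert curve.loc[300] == pytest.approx(0.0)
        assert fit.event_rate_365["g"] == pytest.approx(1.0)

    def test_no_events_gives_flat_curve(self):
        fit = km_estimate([365] * 5, [0] * 5, ["g"] * 5)
        assert (fit.curves["g"]["survival"] == 1.0).all()
        assert fit.event_rate_365["g"] == 0.0

    def test_all_events_at_blanking_end(self):
        fit = km_estimate([90] * 4, [1] * 4, ["g"] * 4)
        assert fit.event_rate_365["g"] == pytest.approx(1.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(90, 366, 60)
        fit = km_estimate(times, np.ones_like(times), ["g"] * 60)
        curve = fit.curves["g"]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            fit = km_estimate([100.0], [1], [np.nan])
        assert fit.curves == {}


def _simulate_survival(rng, n, hr, p0=0.3):
    group = np.repeat([0.0, 1.0], n // 2)
    lam0 = -np.log(1 - p0) / 275.0
    day = 90.0 + rng.exponential(1.0 / (lam0 * np.where(group > 0, hr, 1.0)))
    event = (day <= 365).astype(int)
    time = np.minimum(day, 365.0)
    return pd.DataFrame({"group": group, "event": event, "time": time})


class TestCox:
    def test_null_simulation_hr_near_one(self):
        rng = np.random.default_rng(11)
        df = _simulate_survival(rng, 2000, 1.0)
        fit = cox_fit(df, [CovariateSpec("group", "group", "raw")])
        assert 0.9 <= fit.summary.loc[0, "hr"] <= 1.1

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(12)
        df = _simulate_survival(rng, 5000, 2.0)
        fit = cox_fit(df, [CovariateSpec("group", "group", "raw")])
        assert fit.summary.loc[0, "hr"] == pytest.approx(2.0, rel=0.10)
        lo, hi = fit.summary.loc[0, "ci_low"], fit.summary.loc[0, "ci_high"]
        assert lo < fit.summary.loc[0, "hr"] < hi

    def test_constant_covariate_is_a_fit_error(self):
        df = pd.DataFrame({"x": [1.0] * 10, "event": [1] * 10,
                           "time": np.arange(100, 110)})
        with pytest.raises(FitError, match="constant"):
            cox_fit(df, [CovariateSpec("x", "x", "raw")])

    def test_zero_events_is_a_fit_error(self):
        df = pd.DataFrame({"x": [0.0, 1.0], "event": [0, 0], "time": [365, 365]})
        with pytest.raises(FitError, match="events"):
            cox_fit(df, [CovariateSpec("x", "x", "raw")])

    def test_type_one_error_calibrated(self):
        """Null rejections at the 5% level over 1000 small replicates."""
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(1000):
            df = _simulate_survival(rng, 200, 1.0, p0=0.5)
            try:
                fit = cox_fit(df, [CovariateSpec("group", "group", "raw")])
            except FitError:
                continue
            rejections += fit.summary.loc[0, "p"] < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07


def _mw_enumeration_p(x, y):
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = _u_statistic(np.asarray(x, float), np.asarray(y, float))
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        us.append(_u_statistic(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    return min(1.0, 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean()))


class TestMannWhitney:
    def test_identical_samples_give_central_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, x)
        assert res.statistic == len(x) ** 2 / 2

    def test_full_separation_gives_extreme_u(self):
        res = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0, 13.0])
        assert res.statistic in (0.0, 12.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 12, 4).astype(float)
        y = rng.integers(0, 12, 4).astype(float)
        res = mann_whitney(x, y)
        assert res.p == pytest.approx(_mw_enumeration_p(x, y), abs=1e-9)

    def test_label_swap_invariance(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        assert mann_whitney(x, y).p == pytest.approx(mann_whitney(y, x).p)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney([], [1.0])


def _fisher_enumeration_p(table):
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    n1, n2, m = a + b, c + d, a + c
    rv = hypergeom(n1 + n2, n1, m)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(k) for k in range(max(0, m - n2), min(n1, m) + 1)
               if rv.pmf(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_uniform_table(self):
        res = fisher_exact([[5, 5], [5, 5]])
        assert res.statistic == pytest.approx(1.0) and res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[10, 0], [0, 10]],
        [[8, 2], [3, 7]],
        [[1, 9], [5, 5]],
    ])
    def test_p_matches_hypergeometric_enumeration(self, table):
        res = fisher_exact(table)
        assert res.p == pytest.approx(_fisher_enumeration_p(table), abs=1e-9)

    def test_zero_margin(self):
        res = fisher_exact([[0, 0], [3, 7]])
        assert res.p == 1.0 and math.isnan(res.statistic)

    def test_label_swap_invariance(self):
        t = [[8, 2], [3, 7]]
        swapped = [[3, 7], [8, 2]]
        assert fisher_exact(t).p == pytest.approx(fisher_exact(swapped).p)


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        r = icc_two_way_mixed(np.c_[x, x])
        assert r.icc == pytest.approx(1.0) and r.agreement == "excellent"

    def test_constant_offset_keeps_consistency_at_one(self):
        x = np.arange(10.0)
        r = icc_two_way_mixed(np.c_[x, x + 3.0])
        assert r.icc == pytest.approx(1.0)
        assert icc_two_way_mixed(np.c_[x, x + 3.0], model="agreement").icc < 1.0

    def test_matches_independent_anova_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(20, 2)) + 2.0 * rng.normal(size=(20, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(20), 2),
            "rater": np.tile([0, 1], 20),
            "value": X.ravel(),
        })
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="value")
        exp_c = float(table.loc[table.Type == "ICC(C,1)", "ICC"].iloc[0])
        exp_a = float(table.loc[table.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_two_way_mixed(X).icc == pytest.approx(exp_c, abs=1e-10)
        assert icc_two_way_mixed(X, model="agreement").icc == pytest.approx(exp_a, abs=1e-10)

    def test_constant_ratings_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            r = icc_two_way_mixed(np.full((5, 2), 3.0))
        assert math.isnan(r.icc) and r.agreement == "undefined"

    @pytest.mark.parametrize("icc,label", [
        (0.4, "poor"), (0.6, "moderate"), (0.86, "good"), (0.96, "excellent"),
    ])
    def test_koo_li_bands(self, icc, label):
        from eatkit.cohort import koo_li_class

        assert koo_li_class(icc) == label
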