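"""Tests for the phenoconversion survival module: Cox screening, candidate
selection, maximally selected cutpoints, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest

from evsmall.survival import (
    conversion_analysis,
    cox_screen,
    cox_univariate_adjusted,
    km_estimate,
    logrank_statistic,
    optimal_cutpoint,
    select_candidates,
)
from evsmall.synthetic import SyntheticConfig, simulate_conversion_cohort


def _records(time, event, feature, age=None, sex=None):
    n = len(time)
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": age if age is not None else np.full(n, 64.0),
            "sex": sex if sex is not None else ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "x": feature,
        },
        index=[f"p{i}" for i in range(n)],
    )


class TestLogrank:
    def test_hand_computed_six_subject_table(self):
        # group A events at t=1,2,3; group B events at t=4,5,6 (no censoring).
        # Hand table for A: O_A=3, E_A=0.5+0.4+0.25=1.15,
        # V=0.25+0.24+0.1875=0.6775 -> chi2 = 1.85^2/0.6775 = 5.0517
        time = [1, 2, 3, 4, 5, 6]
        event = [1] * 6
        group = [0, 0, 0, 1, 1, 1]
        z, chi2, p = logrank_statistic(time, event, group)
        assert chi2 == pytest.approx(5.0517, abs=1e-3)
        assert z < 0  # group 1's events come later than expected under H0

    def test_lifelines_cross_check(self, rng):
        from lifelines.statistics import logrank_test

        time = rng.exponential(2.0, size=40)
        event = rng.integers(0, 2, size=40)
        event[:4] = 1
        group = rng.integers(0, 2, size=40)
        group[:2] = [0, 1]
        _, chi2, p = logrank_statistic(time, event, group)
        ref = logrank_test(
            time[group == 0], time[group == 1], event[group == 0], event[group == 1]
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_identical_groups_give_zero(self):
        time = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        event = [1, 1, 0, 1, 1, 0]
        group = [0, 0, 0, 1, 1, 1]
        z, chi2, p = logrank_statistic(time, event, group)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)


class TestKaplanMeier:
    def test_equals_empirical_survival_without_censoring(self, rng):
        time = rng.exponential(1.0, size=25)
        curve = km_estimate(time, np.ones(25, dtype=int))
        for _, row in curve.iloc[1:].iterrows():
            empirical = np.mean(time > row["time"])
            assert row["survival"] == pytest.approx(empirical, abs=1e-12)

    def test_nonincreasing_from_one(self, rng):
        time = rng.exponential(2.0, size=30)
        event = rng.integers(0, 2, size=30)
        curve = km_estimate(time, event)
        assert curve.iloc[0]["survival"] == 1.0
        assert (curve["survival"].diff().dropna() <= 1e-12).all()

    def test_lifelines_cross_check(self, rng):
        from lifelines import KaplanMeierFitter

        time = rng.exponential(2.0, size=40)
        event = rng.integers(0, 2, size=40)
        event[:3] = 1
        curve = km_estimate(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        for _, row in curve.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.survival_function_at_times(row["time"]).iloc[0]), abs=1e-9
            )


class TestCox:
    def test_all_censored_rejected(self):
        rec = _records([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="events"):
            cox_univariate_adjusted(rec, "x")

    def test_zero_variance_feature_rejected(self):
        rec = _records([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], [1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="variance"):
            cox_univariate_adjusted(rec, "x")

    def test_null_feature_estimates_center_at_zero(self):
        betas, pvals = [], []
        for rep in range(30):
            cfg = SyntheticConfig(
                seed=5000 + rep, n_irbd=80, conversion_hazard_ratio=1.4,
                n_conversion_features=0, followup_horizon=10.0,
            )
            rec, _ = simulate_conversion_cohort(cfg, baseline_hazard=0.15)
            res = cox_univariate_adjusted(rec, "miR-0001")
            betas.append(res.beta)
            pvals.append(res.p)
        assert abs(np.mean(betas)) < 0.1
        # Wald p approximately uniform: no pile-up below 0.05
        assert np.mean(np.array(pvals) < 0.05) <= 0.2

    def test_planted_hazard_ratio_recovered(self):
        cfg = SyntheticConfig(
            seed=4, n_irbd=500, conversion_hazard_ratio=3.0,
            n_conversion_features=1, followup_horizon=30.0,
        )
        rec, truth = simulate_conversion_cohort(cfg, baseline_hazard=0.2)
        res = cox_univariate_adjusted(rec, truth.conversion_features[0])
        assert 2.4 <= res.hr <= 3.75
        assert res.p < 0.001

    def test_lifelines_unadjusted_cross_check(self):
        # adjusted=False path agrees with a direct lifelines fit
        cfg = SyntheticConfig(seed=8, n_irbd=120, followup_horizon=10.0)
        rec, _ = simulate_conversion_cohort(cfg, baseline_hazard=0.1)
        res = cox_univariate_adjusted(rec, "miR-0002", covariates=())
        assert res.adjusted is False
        from lifelines import CoxPHFitter

        df = rec[["time", "event"]].copy()
        x = rec["miR-0002"]
        df["z"] = (x - x.mean()) / x.std(ddof=1)
        ref = CoxPHFitter().fit(df, "time", "event")
        assert res.beta == pytest.approx(float(ref.params_["z"]), abs=1e-8)


class TestSelectCandidates:
    def test_threshold_and_ordering(self):
        tab = pd.DataFrame(
            {"p": [0.2, 0.01, 0.05, 0.03]},
            index=["a", "b", "c", "d"],
        )
        assert select_candidates(tab) == ["b", "d"]  # 0.05 excluded (strict)

    def test_empty_input(self):
        assert select_candidates(pd.DataFrame({"p": []})) == []


class TestOptimalCutpoint:
    def test_separated_groups_found(self):
        # low-expression patients survive long; high-expression convert early
        time = [5.0, 6.0, 7.0, 8.0, 9.0, 0.5, 0.7, 1.0, 1.2, 1.5]
        event = [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
        feature = [1.0, 1.1, 1.2, 1.3, 1.4, 3.0, 3.1, 3.2, 3.3, 3.4]
        rec = _records(time, event, feature)
        cp = optimal_cutpoint(rec, "x", minprop=0.1)
        assert 1.4 < cp.cutpoint < 3.0
        assert cp.n_high == 5 and cp.n_low == 5
        assert cp.statistic > 0  # high group converts more than expected

    def test_constant_feature_rejected(self):
        rec = _records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0], [2.0] * 4)
        with pytest.raises(ValueError):
            optimal_cutpoint(rec, "x")

    def test_minprop_bounds_respected(self, rng):
        time = rng.exponential(2.0, size=20)
        event = np.ones(20, dtype=int)
        feature = rng.normal(size=20)
        rec = _records(time, event, feature)
        cp = optimal_cutpoint(rec, "x", minprop=0.3)
        assert 6 <= cp.n_low <= 14

    def test_brute_force_oracle_equivalence(self, rng):
        # exhaustive maximization with lifelines' log-rank as the oracle
        from lifelines.statistics import logrank_test

        for rep in range(12):
            r = np.random.default_rng(rep)
            n = 20
            time = r.exponential(2.0, size=n)
            event = r.integers(0, 2, size=n)
            event[:3] = 1
            feature = np.round(r.normal(size=n), 2)
            rec = _records(time, event, feature)
            try:
                cp = optimal_cutpoint(rec, "x", minprop=0.1)
            except ValueError:
                continue
            values = np.unique(feature)
            best_stat, best_cut = -1.0, None
            for lo, hi in zip(values[:-1], values[1:]):
                cut = 0.5 * (lo + hi)
                prop = np.mean(feature <= cut)
                if not (0.1 <= prop <= 0.9):
                    continue
                high = feature > cut
                ref = logrank_test(
                    time[~high], time[high], event[~high], event[high]
                )
                stat = np.sqrt(ref.test_statistic)
                if stat > best_stat:
                    best_stat, best_cut = stat, cut
            assert cp.cutpoint == pytest.approx(best_cut)
            assert abs(cp.statistic) == pytest.approx(best_stat, rel=1e-6)


class TestConversionAnalysis:
    def test_planted_feature_selected_and_dichotomized(self):
        cfg = SyntheticConfig(
            seed=6, n_irbd=120, conversion_hazard_ratio=4.0,
            n_conversion_features=1, followup_horizon=5.0,
        )
        rec, truth = simulate_conversion_cohort(cfg, baseline_hazard=0.08)
        feats = [c for c in rec.columns if c.startswith("miR")]
        cox_table, candidates, km_results = conversion_analysis(rec, feats)
        planted = truth.conversion_features[0]
        assert planted in candidates
        cp, curves = km_results[planted]
        assert set(curves) == {"high", "low"}
        # high-expression group converts faster: lower final survival
        assert (
            curves["high"]["survival"].iloc[-1]
            < curves["low"]["survival"].iloc[-1]
        )

    def test_cutpoint_inflation_on_null_is_anticonservative(self):
        # selecting the best cutpoint inflates the naive log-rank p: on null
        # cohorts the rejection rate is well above nominal
        rejected = 0
        reps = 30
        for rep in range(reps):
            r = np.random.default_rng(7000 + rep)
            n = 40
            time = r.exponential(2.0, size=n)
            event = (time < 3.0).astype(int)
            time = np.minimum(time, 3.0)
            feature = r.normal(size=n)
            rec = _records(time, event, feature)
            cp = optimal_cutpoint(rec, "x", minprop=0.1)
            rejected += cp.logrank_p < 0.05
        assert rejected / reps > 0.10
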