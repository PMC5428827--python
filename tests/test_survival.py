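"""Landmark tables, stepwise AIC, nested LOOCV, c-index and KM stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltarad.cox import fit_cox
from deltarad.survival import (
    build_survival_table,
    concordance_index,
    finalize_models,
    likelihood_ratio_test,
    loocv_predict,
    median_split_km,
    nested_loocv_selection,
    stepwise_aic_cox,
)


def _frame(times, events, X=None):
    idx = pd.Index([f"P{i}" for i in range(len(times))], name="patient")
    surv = pd.DataFrame({"time": times, "event": events}, index=idx)
    if X is None:
        return surv
    return surv, pd.DataFrame(X, index=idx)


def _sim_cohort(seed, n=60, beta_x=1.0, n_noise=2, censor=0.25):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    noise = rng.normal(size=(n, n_noise))
    t_event = rng.exponential(1.0 / np.exp(beta_x * x))
    c = rng.exponential(t_event.mean() / censor * (1 - censor), n)
    surv, X = _frame(np.minimum(t_event, c), t_event <= c,
                     {"x": x, **{f"z{i}": noise[:, i] for i in range(n_noise)}})
    return surv, X


class TestSurvivalTable:
    def test_landmark_arithmetic(self):
        clinical = pd.DataFrame(
            {"entry_day": [0, 0], "OS_day": [400, 500], "OS_event": [1, 0]},
            index=pd.Index(["A", "B"], name="patient"),
        )
        t = build_survival_table(clinical, "OS")
        assert t.loc["A", "time"] == 310 and t.loc["A", "event"] == 1
        assert t.loc["B", "time"] == 410 and t.loc["B", "event"] == 0

    def test_pre_landmark_event_rejected(self):
        clinical = pd.DataFrame(
            {"entry_day": [0], "OS_day": [80], "OS_event": [1]},
            index=pd.Index(["A"], name="patient"),
        )
        with pytest.raises(ValueError):
            build_survival_table(clinical, "OS")


class TestStepwise:
    def test_forced_covariate_never_dropped(self):
        surv, X = _sim_cohort(0, beta_x=0.0)
        fit = stepwise_aic_cox(X, surv, ["x", "z0"], forced=["z1"])
        assert "z1" in fit.covariates

    def test_true_covariate_retained(self):
        for seed in range(5):
            surv, X = _sim_cohort(seed, beta_x=1.2)
            fit = stepwise_aic_cox(X, surv, list(X.columns))
            assert "x" in fit.covariates, seed

    def test_pure_noise_reduces_to_forced_only(self):
        """With 2 noise candidates, P(no false add) ~ 0.84^2 ~ 0.71."""
        kept_forced_only = 0
        for seed in range(30):
            surv, X = _sim_cohort(seed, beta_x=0.7, n_noise=2)
            fit = stepwise_aic_cox(X, surv, ["z0", "z1"], forced=["x"])
            kept_forced_only += fit.covariates == ("x",)
        assert kept_forced_only >= 0.6 * 30

    def test_deterministic(self):
        surv, X = _sim_cohort(3)
        a = stepwise_aic_cox(X, surv, list(X.columns))
        b = stepwise_aic_cox(X, surv, list(X.columns))
        assert a.covariates == b.covariates
        assert np.allclose(a.coef, b.coef)


class TestLRT:
    def test_identical_models_p_one(self):
        surv, X = _sim_cohort(1)
        f = fit_cox(X[["x"]], surv["time"], surv["event"], covariates=("x",))
        assert likelihood_ratio_test(f, f) == 1.0

    def test_non_nested_raises(self):
        surv, X = _sim_cohort(1)
        a = fit_cox(X[["x"]], surv["time"], surv["event"], covariates=("x",))
        b = fit_cox(X[["z0"]], surv["time"], surv["event"], covariates=("z0",))
        with pytest.raises(ValueError):
            likelihood_ratio_test(a, b)

    def test_noise_addition_chi2_calibrated(self):
        """p-values of adding a pure-noise covariate are U(0,1) over 400 reps."""
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(400):
            n = 50
            t = rng.exponential(1.0, n)
            e = rng.random(n) > 0.2
            z = rng.normal(size=(n, 1))
            small = fit_cox(np.empty((n, 0)), t, e, covariates=())
            large = fit_cox(z, t, e, covariates=("z",))
            pvals.append(likelihood_ratio_test(small, large))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_generating_covariate_significant(self):
        surv, X = _sim_cohort(2, beta_x=1.0)
        small = fit_cox(X[["z0"]], surv["time"], surv["event"], covariates=("z0",))
        large = fit_cox(X[["z0", "x"]], surv["time"], surv["event"], covariates=("z0", "x"))
        assert likelihood_ratio_test(small, large) < 0.05


class TestLOOCV:
    def test_selection_counts_bounded_by_iterations(self):
        surv, X = _sim_cohort(4, n=25)
        freq = nested_loocv_selection(surv, X, X[["z0"]], X[["z1"]],
                                      clinical_covariates=["x"])
        assert freq.total == 25
        assert all(0 <= c <= 25 for d in freq.counts.values() for c in d.values())

    def test_empty_covariate_set_predicts_zero(self):
        surv, X = _sim_cohort(5, n=20)
        preds = loocv_predict(surv, X, {1: []})
        assert (preds[1] == 0.0).all()

    def test_leave_one_out_contract(self):
        """Patient i's prediction ignores patient i's own outcome."""
        surv, X = _sim_cohort(6, n=30)
        preds = loocv_predict(surv, X, {1: ["x"]})
        surv2 = surv.copy()
        surv2.loc["P0", "time"] = surv2["time"].max() * 5
        surv2.loc["P0", "event"] = False
        preds2 = loocv_predict(surv2, X, {1: ["x"]})
        assert preds.loc["P0", 1] == pytest.approx(preds2.loc["P0", 1])

    def test_planted_effect_predictions_track_hazard(self):
        surv, X = _sim_cohort(7, n=60, beta_x=1.2)
        preds = loocv_predict(surv, X, {1: ["x"]})
        rho = stats.spearmanr(preds[1], X["x"]).statistic
        assert rho > 0.9


class TestFinalize:
    def test_strict_majority_and_nesting(self):
        surv, X = _sim_cohort(8, n=20)
        from deltarad.survival import SelectionFrequencyTable

        freq = SelectionFrequencyTable(
            {1: {"x": 20}, 2: {"z0": 10}, 3: {"z1": 11}}, total=20
        )
        models = finalize_models(freq, surv, X)
        assert models[1].covariates == ("x",)
        assert models[2].covariates == ("x",)       # 50% exactly -> excluded
        assert set(models[3].covariates) == {"x", "z1"}
        assert set(models[1].covariates) <= set(models[2].covariates) <= set(models[3].covariates)

    def test_nothing_selected_gives_null_models(self):
        surv, X = _sim_cohort(9, n=20)
        from deltarad.survival import SelectionFrequencyTable

        freq = SelectionFrequencyTable({1: {"x": 0}, 2: {}, 3: {}}, total=20)
        models = finalize_models(freq, surv, X)
        for lvl in (1, 2, 3):
            assert models[lvl].covariates == ()


class TestConcordance:
    def test_perfect_and_tied(self):
        times = np.array([5.0, 10.0, 20.0, 40.0])
        events = np.ones(4, bool)
        assert concordance_index(-times, times, events) == 1.0  # risk = reversed rank
        assert concordance_index(np.zeros(4), times, events) == 0.5

    def test_three_patient_brute_force(self):
        """All 3 pairs comparable; risk scores (0.2, 0.9, 0.1) get 2 of 3 right."""
        c = concordance_index([0.2, 0.9, 0.1], [5.0, 10.0, 20.0], [1, 1, 1])
        assert c == pytest.approx(2 / 3)

    def test_negation_sums_to_one(self, rng):
        pred = rng.normal(size=40)
        times = rng.exponential(1.0, 40)
        events = rng.random(40) > 0.3
        c1 = concordance_index(pred, times, events)
        c2 = concordance_index(-pred, times, events)
        assert c1 + c2 == pytest.approx(1.0)


class TestMedianSplitKM:
    def test_identical_groups_logrank_zero(self):
        times = np.concatenate([np.arange(1.0, 11.0)] * 2)
        surv = _frame(times, np.ones(20, bool))
        preds = pd.Series([0.0] * 10 + [1.0] * 10, index=surv.index)
        km = median_split_km(preds, surv)
        assert km.logrank_stat == pytest.approx(0.0, abs=1e-9)
        assert km.logrank_p == pytest.approx(1.0)
        assert len(km.high_risk) == 10

    def test_km_starts_at_one(self):
        times = np.concatenate([np.arange(1.0, 11.0)] * 2)
        surv = _frame(times, np.ones(20, bool))
        preds = pd.Series(np.arange(20.0), index=surv.index)
        km = median_split_km(preds, surv)
        assert float(km.km_high.predict(0)) == 1.0
        assert float(km.km_low.predict(0)) == 1.0

    def test_separated_times_significant(self):
        times = np.concatenate([np.linspace(1, 5, 10), np.linspace(50, 60, 10)])
        surv = _frame(times, np.ones(20, bool))
        preds = pd.Series(np.concatenate([np.ones(10), np.zeros(10)]), index=surv.index)
        km = median_split_km(preds, surv)
        assert km.logrank_p < 0.01
        assert set(km.high_risk) == set(surv.index[:10])

    def test_ties_at_median_go_low_risk(self):
        surv = _frame(np.arange(1.0, 7.0), np.ones(6, bool))
        preds = pd.Series([0.0, 1.0, 1.0, 1.0, 2.0, 3.0], index=surv.index)
        km = median_split_km(preds, surv)  # median = 1 -> ties low
        assert len(km.low_risk) == 4

    def test_identical_predictions_error(self):
        surv = _frame(np.arange(1.0, 7.0), np.ones(6, bool))
        preds = pd.Series(np.ones(6), index=surv.index)
        with pytest.raises(ValueError):
            median_split_km(preds, surv)
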