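import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from strainhet.survival_models import (ModelSpec, bonferroni_adjust,
                                       brier_score, censoring_survival,
                                       check_diagnostics, compare_c_index,
                                       continuous_nri, fit_cox, lrt_and_aic,
                                       uno_c_index,
                                       variance_inflation_factors)
from conftest import random_survival_instance
from oracles import (brier_oracle, censoring_km_oracle, cox_loglik_oracle,
                     nri_oracle, uno_c_oracle)


class TestBonferroni:
    def test_arithmetic(self):
        assert bonferroni_adjust(0.001) == pytest.approx(0.015)

    def test_cap_at_one(self):
        assert bonferroni_adjust(0.2) == 1.0

    def test_threshold(self):
        assert 0.05 / 15 == pytest.approx(0.0033, abs=5e-5)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(1.2)


class TestModelSpec:
    def test_tiers_are_nested(self):
        specs = {t: ModelSpec("hf", "cov_cs", tier=t) for t in (1, 2, 3)}
        assert set(specs[1].covariates()) <= set(specs[2].covariates())
        assert set(specs[2].covariates()) <= set(specs[3].covariates())

    def test_tier3_includes_reciprocal_marker(self):
        assert "gcs_z" in ModelSpec("hf", "cov_cs", tier=3).covariates()
        assert "cov_ls_z" in ModelSpec("hf", "gls", tier=3).covariates()

    def test_focal_appears_once(self):
        cols = ModelSpec("hf", "cov_cs", tier=3).covariates()
        assert cols.count("cov_cs_z") == 1

    def test_unknown_biomarker_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("hf", "lvef", tier=1)


class TestFitCox:
    def test_tiny_fit_matches_partial_likelihood_grid(self):
        # single binary covariate, no ties, no censoring
        x = [1, 0, 1, 0, 1, 0, 0, 1]
        t = [1.0, 2.0, 3.0, 4.5, 5.0, 6.5, 7.0, 8.0]
        frame = pd.DataFrame({
            "participant_id": range(8), "cov_cs": x, "gcs": 0.0,
            "time_hf": t, "event_hf": True, "prevalent_hf": False})
        frame["x"] = x
        spec = ModelSpec("hf", "cov_cs", tier=1)
        fit = fit_cox(spec, frame)
        # brute-force maximization of the hand-written partial likelihood
        # in terms of the z-scored covariate
        xz = (np.array(x, float) - np.mean(x)) / np.std(x, ddof=1)
        res = minimize_scalar(
            lambda b: -cox_loglik_oracle(b, xz, t, [True] * 8),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert fit.summary.loc["cov_cs_z", "coef"] == pytest.approx(
            res.x, abs=1e-5)
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-8)

    def test_covariate_rescaling_rescales_beta(self, modeling_frame):
        spec = ModelSpec("composite_cv", "cov_cs", tier=2)
        fit1 = fit_cox(spec, modeling_frame)
        scaled = modeling_frame.copy()
        scaled["bmi"] = scaled["bmi"] * 10.0
        fit2 = fit_cox(spec, scaled)
        assert fit2.summary.loc["bmi", "coef"] == pytest.approx(
            fit1.summary.loc["bmi", "coef"] / 10.0, rel=1e-5)
        # z-scored focal marker untouched by covariate rescaling
        assert fit2.focal_hr == pytest.approx(fit1.focal_hr, rel=1e-6)

    def test_prevalent_exclusion_and_aic_identity(self, modeling_frame):
        spec = ModelSpec("hf", "cov_cs", tier=2)
        fit = fit_cox(spec, modeling_frame)
        assert fit.n == (~modeling_frame["prevalent_hf"]).sum()
        k = len(spec.covariates())
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * k)

    def test_zero_events_errors(self, modeling_frame):
        frame = modeling_frame.copy()
        frame["event_hf"] = False
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(ModelSpec("hf", "cov_cs", tier=1), frame)


class TestDiagnostics:
    def test_orthogonal_covariates_unit_vif(self, modeling_frame):
        fit = fit_cox(ModelSpec("composite_cv", "cov_cs", tier=2),
                      modeling_frame)
        diag = check_diagnostics(fit)
        assert all(v < 5.0 for v in diag["vif"].values())
        assert diag["pass"]
        assert all(0 <= p <= 1 for p in diag["schoenfeld_p"].values())

    def test_duplicated_column_infinite_vif(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        design = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        vif = variance_inflation_factors(design)
        assert math.isinf(vif["a"]) and math.isinf(vif["b"])
        assert vif["c"] < 2.0

    def test_schoenfeld_detects_time_varying_effect(self):
        # effect that reverses over time violates proportional hazards
        rng = np.random.default_rng(1)
        n = 4000
        x = rng.normal(size=n)
        # piecewise hazard: x harmful early, protective late
        t1 = rng.exponential(1.0 / np.exp(1.2 * x))
        t = np.where(t1 < 1.0, t1, 1.0 + rng.exponential(
            1.0 / np.exp(-1.2 * x)))
        frame = pd.DataFrame({
            "participant_id": range(n), "cov_cs": x, "gcs": 0.0,
            "time_hf": t, "event_hf": True, "prevalent_hf": False})
        fit = fit_cox(ModelSpec("hf", "cov_cs", tier=1), frame)
        diag = check_diagnostics(fit)
        assert diag["schoenfeld_p"]["cov_cs_z"] < 0.05


class TestCensoringSurvival:
    def test_matches_hand_km_left_and_right(self):
        rng = np.random.default_rng(2)
        _, times, events = random_survival_instance(rng, n=40)
        g = censoring_survival(times, events)
        for q in np.quantile(times, [0.2, 0.5, 0.9]):
            assert g(q, left=True) == pytest.approx(
                censoring_km_oracle(times, events, q, left=True), abs=1e-12)
            assert g(q, left=False) == pytest.approx(
                censoring_km_oracle(times, events, q, left=False), abs=1e-12)


class TestUnoC:
    def test_perfect_discrimination(self):
        t = np.arange(1.0, 21.0)
        risk = -t   # higher risk = earlier event
        assert uno_c_index(risk, t, np.ones(20, bool), tau=25.0) == 1.0

    def test_all_tied_risks_half(self):
        rng = np.random.default_rng(3)
        _, t, e = random_survival_instance(rng, n=50)
        assert uno_c_index(np.zeros(50), t, e, tau=np.quantile(t, 0.9)) == 0.5

    def test_no_censoring_equals_harrells_c(self):
        from lifelines.utils import concordance_index
        rng = np.random.default_rng(4)
        n = 80
        risk = rng.normal(size=n)
        t = rng.weibull(1.5, n) * np.exp(-risk)
        e = np.ones(n, bool)
        mine = uno_c_index(risk, t, e, tau=t.max() + 1)
        harrell = concordance_index(t, -risk, e)
        assert mine == pytest.approx(harrell, abs=1e-12)

    def test_matches_brute_force_under_censoring(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            risk, t, e = random_survival_instance(rng, n=50)
            tau = float(np.quantile(t, 0.9))
            assert uno_c_index(risk, t, e, tau) == pytest.approx(
                uno_c_oracle(risk, t, e, tau), abs=1e-10)

    def test_matches_scikit_survival_reference(self):
        from sksurv.metrics import concordance_index_ipcw
        rng = np.random.default_rng(9)
        for _ in range(3):
            risk, t, e = random_survival_instance(rng, n=200)
            tau = float(np.quantile(t, 0.8))
            y = np.array(list(zip(e, t)), dtype=[("e", bool), ("t", float)])
            ref = concordance_index_ipcw(y, y, risk, tau=tau)[0]
            assert uno_c_index(risk, t, e, tau) == pytest.approx(ref,
                                                                 abs=1e-12)

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            uno_c_index([1.0, 2.0], [5.0, 6.0], [False, False], tau=10.0)


class TestBrier:
    def test_oracle_predictions_score_zero(self):
        t = np.array([1.0, 2.0, 8.0, 9.0])
        e = np.array([True, True, False, False])
        pred = np.array([1.0, 1.0, 0.0, 0.0])
        assert brier_score(pred, t, e, horizon=5.0) == 0.0

    def test_coin_flip_quarter(self):
        t = np.array([1.0] * 10 + [9.0] * 10)
        e = np.array([True] * 10 + [False] * 10)
        assert brier_score(np.full(20, 0.5), t, e, 5.0) == pytest.approx(0.25)

    def test_matches_brute_force_under_censoring(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            risk, t, e = random_survival_instance(rng, n=60)
            pred = 1 / (1 + np.exp(-risk))
            h = float(np.quantile(t, 0.6))
            assert brier_score(pred, t, e, h) == pytest.approx(
                brier_oracle(pred, t, e, h), abs=1e-10)

    def test_invalid_risk_errors(self):
        with pytest.raises(ValueError):
            brier_score([1.5], [1.0], [True], 5.0)


class TestContinuousNRI:
    def test_identical_models_zero(self):
        rng = np.random.default_rng(7)
        risk, t, e = random_survival_instance(rng, n=40)
        nri, _ = continuous_nri(risk, risk, t, e, horizon=np.median(t))
        assert nri == 0.0

    def test_saturation_bound(self):
        t = np.array([1.0] * 5 + [9.0] * 5)
        e = np.array([True] * 5 + [False] * 5)
        old = np.full(10, 0.5)
        new = np.r_[np.full(5, 0.9), np.full(5, 0.1)]
        nri, _ = continuous_nri(old, new, t, e, horizon=5.0)
        assert nri == pytest.approx(200.0)

    def test_hand_count_toy(self):
        # 10 subjects, no censoring by horizon
        t = np.array([1, 2, 3, 4, 9, 9, 9, 9, 9, 9], float)
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool)
        old = np.linspace(0.1, 0.9, 10)
        new = old.copy()
        new[[0, 1]] += 0.05   # 2 of 4 events up
        new[[4, 5, 6]] -= 0.05  # 3 of 6 non-events down
        nri, _ = continuous_nri(old, new, t, e, horizon=5.0)
        assert nri == pytest.approx(100 * (2 / 4 + 3 / 6))

    def test_matches_brute_force_under_censoring(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            risk, t, e = random_survival_instance(rng, n=60)
            old = 1 / (1 + np.exp(-risk))
            new = 1 / (1 + np.exp(-(risk + rng.normal(0, 0.3, 60))))
            h = float(np.quantile(t, 0.6))
            nri, _ = continuous_nri(old, new, t, e, horizon=h)
            assert nri == pytest.approx(nri_oracle(old, new, t, e, h),
                                        abs=1e-8)

    def test_no_events_by_horizon_errors(self):
        with pytest.raises(ValueError):
            continuous_nri([0.1], [0.2], [9.0], [False], horizon=5.0)


class TestModelComparison:
    def test_identical_models_zero_delta(self, modeling_frame):
        spec = ModelSpec("composite_cv", "cov_cs", tier=2)
        out = compare_c_index(spec, spec, modeling_frame, B=50, seed=0)
        assert out["delta_c"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_lrt_identical_models(self, modeling_frame):
        spec = ModelSpec("composite_cv", "cov_cs", tier=2)
        fit = fit_cox(spec, modeling_frame)
        out = lrt_and_aic(fit, fit)
        assert out["chi2"] == 0.0 and out["delta_aic"] == 0.0

    def test_lrt_focal_addition(self, modeling_frame):
        spec = ModelSpec("composite_cv", "cov_cs", tier=3)
        from strainhet.survival_models import _prepare_rows
        rows = _prepare_rows(spec, modeling_frame)
        fit_f = fit_cox(spec, modeling_frame, rows=rows)
        fit_r = fit_cox(spec.reduced(), modeling_frame, rows=rows)
        out = lrt_and_aic(fit_f, fit_r)
        assert out["df"] == 1
        assert out["chi2"] >= 0
        assert out["delta_aic"] == pytest.approx(2 - out["chi2"])

    def test_non_nested_rejected(self, modeling_frame):
        fit_a = fit_cox(ModelSpec("composite_cv", "cov_cs", tier=1),
                        modeling_frame)
        fit_b = fit_cox(ModelSpec("composite_cv", "gls", tier=1),
                        modeling_frame)
        with pytest.raises(ValueError, match="nested"):
            lrt_and_aic(fit_a, fit_b)


class TestSubgroups:
    def test_hfpef_rule(self):
        from strainhet.survival_models import hfpef_risk_mask
        frame = pd.DataFrame({
            "age": [70, 70], "lvef": [55.0, 45.0],
            "obesity": True, "hypertension": True, "diabetes": True,
            "ckd": False, "af": False})
        mask = hfpef_risk_mask(frame)
        assert mask.tolist() == [True, False]   # LVEF gate

    def test_zero_event_subgroup_not_estimable(self, modeling_frame):
        from strainhet.survival_models import subgroup_analysis
        frame = modeling_frame.copy()
        # make prevalent-MI subgroup event-free
        frame.loc[frame["prev_mi"], "event_hf"] = False
        res = subgroup_analysis(frame, ModelSpec("hf", "cov_cs", tier=1),
                                subgroups={"prevalent_mi": frame["prev_mi"]})
        assert res["prevalent_mi"].get("not_estimable") is True
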