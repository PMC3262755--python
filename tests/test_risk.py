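import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from rasprt.registry import CaseRecord, RiskFactorSchema, default_schema
from rasprt.risk import (
    DegenerateWindowError,
    RiskModel,
    build_model_sequence,
    fit_monthly_model,
    predict_case,
)
from rasprt.simulate import simulate_frame

from conftest import single_year_scenario

INTERCEPT_ONLY = RiskFactorSchema(factors=())


def bare_frame(outcomes, months):
    """Cases without risk factors: one per (outcome, month) pair."""
    return pd.DataFrame(
        {
            "case_id": [f"C{i:05d}" for i in range(len(outcomes))],
            "hospital_id": "H01",
            "procedure_date": [dt.date(2002 + (m - 1) // 12, (m - 1) % 12 + 1, 15) for m in months],
            "outcome": outcomes,
        }
    )


class TestFitMonthlyModel:
    def test_intercept_only_fit_recovers_event_rate(self):
        # 2% deaths in the window -> intercept = logit(0.02), predictions 0.02
        outcomes = [1] * 20 + [0] * 980 + [0]  # last case falls in month 2
        frame = bare_frame(outcomes, [1] * 1000 + [2])
        model = fit_monthly_model(frame, "2002-02", INTERCEPT_ONLY)
        assert model.coefficients["intercept"] == pytest.approx(float(logit(0.02)), abs=1e-6)
        preds = model.predict(frame.tail(1))
        assert preds[0] == pytest.approx(0.02, abs=1e-6)
        assert model.n_train == 1000

    def test_parameter_recovery_on_large_synthetic_window(self):
        # 20,000 cases generated with known coefficients: each fitted
        # coefficient should land within 3 reported SEs of the truth
        sc = single_year_scenario(n_hospitals=10, cases_per_hospital=2000, mortality=0.02, seed=21)
        frame = simulate_frame(sc)
        model = fit_monthly_model(frame, "2005-01", sc.schema)
        assert model.converged and not model.stabilized

        import statsmodels.api as sm

        months = frame["procedure_date"].dt.to_period("M")
        window = frame.loc[
            (months >= model.training_window[0]) & (months <= model.training_window[1])
        ]
        assert model.n_train == len(window) > 15_000
        x = sc.schema.design_matrix(window, add_intercept=True)
        fit = sm.GLM(window["outcome"].to_numpy(float), x, family=sm.families.Binomial()).fit()
        ses = np.sqrt(np.diag(fit.cov_params()))
        names = ["intercept"] + sc.schema.design_columns()
        for name, se in zip(names[1:], ses[1:]):
            truth = sc.coefficients[name]
            assert abs(model.coefficients[name] - truth) < 3 * se, name

    def test_zero_death_window_signals_skip(self):
        frame = bare_frame([0] * 50, [1] * 50)
        with pytest.raises(DegenerateWindowError, match="single outcome class"):
            fit_monthly_model(frame, "2002-02", INTERCEPT_ONLY)

    def test_empty_window_signals_skip(self):
        frame = bare_frame([0, 1], [5, 5])
        with pytest.raises(DegenerateWindowError, match="no training cases"):
            fit_monthly_model(frame, "2002-02", INTERCEPT_ONLY)

    def test_separation_falls_back_to_flagged_ridge(self):
        # a binary factor perfectly predicting death separates the likelihood
        schema = RiskFactorSchema(factors=(default_schema().factors[2],))  # renal_failure
        frame = bare_frame([1] * 5 + [0] * 95, [1] * 100)
        frame["renal_failure"] = [1] * 5 + [0] * 95
        model = fit_monthly_model(frame, "2002-02", schema)
        assert model.stabilized
        assert np.isfinite(model.coefficients["renal_failure"])

    def test_refit_is_deterministic_to_ten_significant_digits(self):
        sc = single_year_scenario(n_hospitals=4, cases_per_hospital=500, seed=23)
        frame = simulate_frame(sc)
        a = fit_monthly_model(frame, "2004-12", sc.schema)
        b = fit_monthly_model(frame, "2004-12", sc.schema)
        for name, value in a.coefficients.items():
            assert b.coefficients[name] == pytest.approx(value, rel=1e-10)

    def test_calibration_in_the_large(self):
        sc = single_year_scenario(n_hospitals=6, cases_per_hospital=500, seed=24)
        frame = simulate_frame(sc)
        model = fit_monthly_model(frame, "2004-12", sc.schema)
        observed, mean_predicted = model.calibration
        assert mean_predicted == pytest.approx(observed, abs=1e-8)


class TestPredict:
    def _zero_model(self, schema):
        names = ["intercept"] + schema.design_columns()
        return RiskModel(
            analysis_month=pd.Period("2002-02", "M"),
            training_window=(pd.Period("2002-01", "M"), pd.Period("2002-01", "M")),
            coefficients={n: 0.0 for n in names},
            n_train=0, converged=True, stabilized=False,
            calibration=(0.0, 0.0), schema=schema,
        )

    def _reference_case(self):
        return CaseRecord(
            case_id="X", hospital_id="H01", procedure_date=dt.date(2002, 2, 1), outcome=0,
            risk_factors={"age": 0.0, "male": 0, "renal_failure": 0, "diabetes": 0,
                          "hypertension": 0, "peripheral_vascular_disease": 0, "prior_cabg": 0,
                          "prior_ptca_pci": 0, "cardiogenic_shock": 0,
                          "ejection_fraction": "ge40", "mi_timing": "none",
                          "status": "elective", "preop_iabp": 0},
        )

    def test_all_reference_case_under_zero_coefficients_predicts_half(self, schema):
        assert predict_case(self._zero_model(schema), self._reference_case()) == 0.5

    def test_predictions_respect_clipping_contract(self, schema):
        model = self._zero_model(schema)
        object.__setattr__(model, "coefficients", {**model.coefficients, "intercept": -50.0})
        p = predict_case(model, self._reference_case())
        assert 0.0 < p < 1.0 and p == pytest.approx(1e-6)

    def test_unseen_categorical_level_is_rejected(self, schema):
        model = self._zero_model(schema)
        case = self._reference_case()
        bad = CaseRecord(case.case_id, case.hospital_id, case.procedure_date, 0,
                         {**case.risk_factors, "status": "mystery"})
        with pytest.raises(ValueError, match="unseen level"):
            predict_case(model, bad)


class TestModelSequence:
    def test_window_arithmetic_over_24_months(self):
        rng = np.random.default_rng(30)
        months = list(rng.integers(1, 25, size=4000))
        outcomes = list((rng.random(4000) < 0.05).astype(int))
        frame = bare_frame(outcomes, months)
        seq = build_model_sequence(frame, INTERCEPT_ONLY)
        assert len(seq) == 23
        m13 = seq.get("2003-01")
        assert m13.training_window == (pd.Period("2002-02", "M"), pd.Period("2002-12", "M"))
        # an 11-month cap: month 24 trains on months 13..23
        m24 = seq.get("2003-12")
        assert m24.training_window == (pd.Period("2003-01", "M"), pd.Period("2003-11", "M"))

    def test_second_month_trains_on_exactly_one_month(self):
        rng = np.random.default_rng(31)
        frame = bare_frame(list((rng.random(600) < 0.1).astype(int)), [1] * 300 + [2] * 300)
        seq = build_model_sequence(frame, INTERCEPT_ONLY)
        model = seq.get("2002-02")
        assert model.training_window == (pd.Period("2002-01", "M"), pd.Period("2002-01", "M"))
        assert model.n_train == 300

    def test_first_month_has_no_model(self):
        rng = np.random.default_rng(32)
        frame = bare_frame(list((rng.random(600) < 0.1).astype(int)), [1] * 300 + [2] * 300)
        seq = build_model_sequence(frame, INTERCEPT_ONLY)
        assert seq.get("2002-01") is None
        assert "2002-01" in seq.skipped

    def test_windows_never_include_the_analysis_month(self):
        rng = np.random.default_rng(33)
        months = list(rng.integers(1, 19, size=3000))
        frame = bare_frame(list((rng.random(3000) < 0.05).astype(int)), months)
        seq = build_model_sequence(frame, INTERCEPT_ONLY)
        for month in seq:
            model = seq.models[month]
            assert model.training_window[1] == month - 1
            assert (month - model.training_window[0]).n <= 11
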