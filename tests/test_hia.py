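"""Logit transform, OLS diagnostics, PRESS, elimination, prediction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlchia.hia import (
    HIARegressionError,
    backward_eliminate,
    fit_mlr,
    inverse_logit_hia,
    load_model,
    logit_hia,
    predict_hia,
    press_statistic,
    r_squared_pred,
    reproduce_paper,
    round_half_away,
    save_model,
    validate_model,
)
from oracles import ols_normal_equations, press_leave_one_out


def make_table(log_pmw, psa, hia):
    return pd.DataFrame(
        {
            "name": [f"c{i}" for i in range(len(hia))],
            "log_pmw": log_pmw,
            "psa": psa,
            "hia_percent": hia,
            "role": "train",
        }
    )


def random_table(rng, n, noise_sd=0.25):
    lp = rng.uniform(0.9, 3.0, n)
    psa = rng.uniform(37, 89, n)
    L = 4.1 - 0.94 * lp - 0.022 * psa + rng.normal(0, noise_sd, n)
    hia = 100 * 10**L / (1 + 10**L)
    return make_table(lp, psa, hia)


class TestLogit:
    def test_symmetry_point(self):
        assert logit_hia(50) == 0.0

    def test_direct_value(self):
        assert logit_hia(82) == pytest.approx(math.log10(82 / 18), abs=1e-10)
        assert logit_hia(82) == pytest.approx(0.65854, abs=1e-5)

    @pytest.mark.parametrize("bad", [0, 100, -5, 120])
    def test_boundary_values_rejected(self, bad):
        with pytest.raises(HIARegressionError):
            logit_hia(bad)

    def test_inverse_examples(self):
        assert inverse_logit_hia(0) == 50
        assert inverse_logit_hia(3) == pytest.approx(100 * 1000 / 1001)

    @given(st.floats(min_value=1e-6, max_value=100 - 1e-6,
                     exclude_min=False, exclude_max=False))
    def test_round_trip_identity(self, p):
        assert inverse_logit_hia(logit_hia(p)) == pytest.approx(p, abs=1e-10)

    def test_logit_strictly_increasing(self):
        grid = np.linspace(0.5, 99.5, 200)
        vals = [logit_hia(p) for p in grid]
        assert np.all(np.diff(vals) > 0)

    def test_rounding_half_away(self):
        assert round_half_away(34.5) == 35
        assert round_half_away(33.4) == 33
        assert round_half_away(-34.5) == -35


class TestFitMlr:
    def test_exact_linear_data_perfect_fit(self):
        lp = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 1.2, 2.8])
        L = 1 + 2 * lp
        hia = 100 * 10**L / (1 + 10**L)
        # single-predictor exact relation: logit = 1 + 2*log_pmw
        df = make_table(lp, np.zeros_like(lp), hia)
        fit = fit_mlr(df, ("log_pmw",))
        assert fit.coefficients == pytest.approx((1.0, 2.0), abs=1e-8)
        assert fit.r_squared == pytest.approx(100.0, abs=1e-8)
        assert fit.s == pytest.approx(0.0, abs=1e-7)
        assert fit.vif == (1.0,)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            df = random_table(rng, n=rng.integers(8, 30))
            fit = fit_mlr(df)
            X = df[["log_pmw", "psa"]].to_numpy()
            y = np.array([logit_hia(v) for v in df["hia_percent"]])
            expected = ols_normal_equations(X, y)
            assert np.allclose(fit.coefficients, expected, rtol=1e-8, atol=1e-10)

    def test_coefficient_coverage_under_generating_model(self):
        # recovered coefficients should fall inside their own 95% CIs
        # in the vast majority of seeded replications
        truth = np.array([4.1, -0.94, -0.022])
        hits = np.zeros(3)
        n_rep = 100
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            fit = fit_mlr(random_table(rng, 200))
            for j, (lo, hi) in enumerate(fit.confidence_intervals):
                hits[j] += lo <= truth[j] <= hi
        assert np.all(hits / n_rep >= 0.90)

    def test_singular_design_rejected(self):
        df = random_table(np.random.default_rng(0), 20)
        df["psa"] = 2 * df["log_pmw"]  # exact collinearity
        with pytest.raises(HIARegressionError, match="singular|collinear"):
            fit_mlr(df)

    def test_too_few_records_rejected(self):
        df = random_table(np.random.default_rng(0), 20).head(3)
        with pytest.raises(HIARegressionError, match="too small"):
            fit_mlr(df)

    def test_model_save_load_round_trip(self, tmp_path):
        fit = fit_mlr(random_table(np.random.default_rng(3), 30))
        path = tmp_path / "model.json"
        save_model(fit, path)
        again = load_model(path)
        assert again == fit


class TestPress:
    def test_hat_matrix_equals_explicit_loo(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            X = rng.normal(size=(n, 2))
            y = 1 + X @ [0.5, -0.3] + rng.normal(0, 0.4, n)
            hat = press_statistic(X, y)
            loo = press_leave_one_out(X, y)
            assert hat == pytest.approx(loo, rel=1e-8)

    def test_exact_data_gives_full_predictive_r2(self):
        X = np.linspace(0, 1, 12).reshape(-1, 1)
        y = 2 + 3 * X[:, 0]
        assert r_squared_pred(X, y) == pytest.approx(100.0, abs=1e-6)

    def test_r2_pred_never_exceeds_r2(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            df = random_table(rng, int(rng.integers(8, 40)), noise_sd=0.5)
            fit = fit_mlr(df)
            assert fit.r_squared_pred <= fit.r_squared + 1e-10


class TestBackwardElimination:
    def test_pure_noise_predictor_dropped(self):
        rng = np.random.default_rng(123)
        n = 100
        df = random_table(rng, n, noise_sd=0.15)
        df["noise_x"] = rng.normal(size=n)
        fit, log = backward_eliminate(df, ["log_pmw", "psa", "noise_x"])
        assert "noise_x" not in fit.predictor_names
        assert "log_pmw" in fit.predictor_names
        assert (log["predictor"] == "noise_x").any()

    def test_exact_duplicate_removed_in_vif_phase(self):
        rng = np.random.default_rng(2)
        df = random_table(rng, 50)
        df["log_pmw_copy"] = df["log_pmw"]
        fit, log = backward_eliminate(df, ["log_pmw", "log_pmw_copy", "psa"])
        removed = set(log[log["reason"] == "vif"]["predictor"])
        assert removed & {"log_pmw", "log_pmw_copy"}
        assert len(set(fit.predictor_names) & {"log_pmw", "log_pmw_copy"}) == 1

    def test_all_eliminated_falls_back_to_intercept(self):
        rng = np.random.default_rng(9)
        n = 60
        df = make_table(
            rng.uniform(1, 3, n), rng.uniform(40, 80, n),
            np.clip(rng.uniform(20, 95, n), 1, 99),
        )
        df["log_pmw"] = rng.normal(size=n)  # decouple predictors from response
        df["psa"] = rng.normal(size=n)
        with pytest.warns(UserWarning, match="intercept-only"):
            fit, log = backward_eliminate(df, ["log_pmw", "psa"])
        assert fit.predictor_names == ()
        assert len(log) == 2


class TestPredictionAndValidation:
    def test_prediction_decreasing_in_each_predictor(self):
        fit = reproduce_paper().fit
        base, _ = predict_hia(fit, 2.0, 60.0)
        assert predict_hia(fit, 2.5, 60.0)[0] < base
        assert predict_hia(fit, 2.0, 70.0)[0] < base

    def test_exact_match_gives_zero_difference(self):
        fit = reproduce_paper().fit
        pred, _ = predict_hia(fit, 2.0, 60.0)
        df = make_table([2.0], [60.0], [pred])
        report = validate_model(fit, df)
        assert report.min_difference == pytest.approx(0.0, abs=1e-9)
        assert report.min_difference == report.max_difference

    def test_empty_validation_rejected(self):
        fit = reproduce_paper().fit
        with pytest.raises(HIARegressionError, match="empty"):
            validate_model(fit, make_table([], [], []))


class TestReproduction:
    def test_training_split(self, compound_table):
        report = reproduce_paper()
        assert report.fit.n_train == 15
        assert set(compound_table[compound_table["role"] == "validation"]["name"]) == {
            "Acetaminophen", "Ibuprofen", "Salicylic acid"
        }

    def test_flags_inconsistent_overall_p_value(self):
        report = reproduce_paper()
        row = report.statistics.set_index("quantity").loc["f_p_value"]
        assert row["note"] != ""
        # the F-distribution p-value at (2, 12) df is far below the printed 0.007
        assert row["computed"] < 1e-4
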