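"""Correlation screening, stepwise selection, fit statistics, evaluation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm

from leafcgsd.modeling import (
    DegenerateDesignError,
    LinearModel,
    StepwiseConfig,
    correlation_screen,
    evaluate_model,
    fit_all_inversion_models,
    fit_all_response_models,
    fit_statistics,
    stepwise_fit,
)


def _noise_frame(rng, n, names):
    return pd.DataFrame({name: rng.normal(0, 1, n) for name in names})


class TestCorrelationScreen:
    def test_perfect_linearity(self, rng):
        x = rng.normal(0, 1, 10)
        left = pd.DataFrame({"a": 2 * x})
        right = pd.DataFrame({"b": x})
        corr = correlation_screen(left, right)
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)
        assert corr.p.loc["a", "b"] < 1e-9

    def test_matches_covariance_formula_oracle(self, rng):
        left = _noise_frame(rng, 40, ["a", "b"])
        right = _noise_frame(rng, 40, ["c"])
        corr = correlation_screen(left, right)
        for a in ("a", "b"):
            x, y = np.asarray(left[a]), np.asarray(right["c"])
            r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                        / np.sqrt(((x - x.mean()) ** 2).sum()
                                  * ((y - y.mean()) ** 2).sum()))
            assert corr.r.loc[a, "c"] == pytest.approx(r_oracle, rel=1e-12)
            # two-tailed p from t with n-2 df
            t = r_oracle * np.sqrt(38 / (1 - r_oracle**2))
            assert corr.p.loc[a, "c"] == pytest.approx(2 * sps.t.sf(abs(t), 38),
                                                       rel=1e-9)

    def test_null_p_values_roughly_uniform(self, rng):
        # independent x, y: p below 0.1 about 10% of the time
        hits = 0
        reps = 200
        for _ in range(reps):
            left = pd.DataFrame({"a": rng.normal(0, 1, 50)})
            right = pd.DataFrame({"b": rng.normal(0, 1, 50)})
            if correlation_screen(left, right).p.loc["a", "b"] < 0.1:
                hits += 1
        assert 0.1 * reps - 3 * np.sqrt(reps * 0.09) <= hits \
            <= 0.1 * reps + 3 * np.sqrt(reps * 0.09)

    def test_constant_column_flagged_nan(self, rng):
        left = pd.DataFrame({"a": np.ones(10)})
        right = pd.DataFrame({"b": rng.normal(0, 1, 10)})
        corr = correlation_screen(left, right)
        assert np.isnan(corr.r.loc["a", "b"])

    def test_undefined_moment_cells_dropped_pairwise(self, rng):
        a = rng.normal(0, 1, 20)
        a[:5] = np.nan
        corr = correlation_screen(pd.DataFrame({"a": a}),
                                  pd.DataFrame({"b": rng.normal(0, 1, 20)}))
        assert corr.n.loc["a", "b"] == 15


class TestStepwise:
    def test_planted_signal_recovered(self, rng):
        n = 100
        x1 = rng.normal(0, 1, n)
        X = pd.DataFrame({"x1": x1, "x2": rng.normal(0, 1, n)})
        y = 3.0 + 2.0 * x1 + rng.normal(0, 1e-4, n)
        model = stepwise_fit(y, X)
        assert model.status == "fitted"
        assert "x1" in model.predictors
        assert dict(model.terms)["x1"] == pytest.approx(2.0, abs=1e-2)
        assert model.intercept == pytest.approx(3.0, abs=1e-2)

    def test_single_predictor_equals_closed_form_ols(self, rng):
        n = 50
        x = rng.normal(10, 3, n)
        y = 1.5 + 0.7 * x + rng.normal(0, 0.3, n)
        model = stepwise_fit(y, pd.DataFrame({"x": x}))
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert dict(model.terms)["x"] == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-10)

    def test_null_rate_matches_family_wise_entry_probability(self, rng):
        # with 5 independent null candidates, P(no entry) = 0.95^5 ~ 0.774;
        # check the realized rate against that calibration (99% binomial band)
        reps, unable = 100, 0
        for _ in range(reps):
            X = _noise_frame(rng, 100, list("abcde"))
            y = rng.normal(0, 1, 100)
            if stepwise_fit(y, X).status == "unable_to_model":
                unable += 1
        expected = 0.95**5
        half = 2.576 * np.sqrt(expected * (1 - expected) * reps)
        assert expected * reps - half <= unable <= expected * reps + half

    def test_backward_removal_drops_proxy_predictor(self, rng):
        # x3 = x1 + x2 + small noise can enter first but must be removed once
        # the true pair is in
        n = 200
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        x3 = x1 + x2 + rng.normal(0, 0.1, n)
        y = 1.0 + 2.0 * x1 + 3.0 * x2 + rng.normal(0, 0.01, n)
        model = stepwise_fit(y, pd.DataFrame({"x3": x3, "x1": x1, "x2": x2}))
        assert set(model.predictors) == {"x1", "x2"}

    def test_stepwise_sidesteps_exact_duplicate_candidate(self, rng):
        # partial F of an exact multiple of an included predictor is 1, so the
        # duplicate never enters and selection succeeds
        x = rng.normal(0, 1, 30)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        y = 1.0 + x + rng.normal(0, 0.05, 30)
        model = stepwise_fit(y, X)
        assert model.predictors == ["x1"]

    def test_forced_entry_collinearity_error(self, rng):
        x = rng.normal(0, 1, 30)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        y = 1.0 + x + rng.normal(0, 0.1, 30)
        with pytest.raises(DegenerateDesignError):
            stepwise_fit(y, X, StepwiseConfig(forced_entry=True))

    def test_residuals_orthogonal_to_selected_predictors(self, rng):
        n = 80
        X = _noise_frame(rng, n, list("abc"))
        y = 2 + X["a"] * 1.5 - X["b"] * 0.8 + rng.normal(0, 0.5, n)
        model = stepwise_fit(y, X)
        pred = np.array([evaluate_model(model, row) for _, row in X.iterrows()])
        resid = np.asarray(y) - pred
        for name in model.predictors:
            dot = float(np.dot(resid, X[name]))
            assert abs(dot) <= 1e-8 * n * np.abs(X[name]).max() * np.abs(resid).max() + 1e-8

    def test_matches_statsmodels_ols_on_selected_set(self, rng):
        n = 60
        X = _noise_frame(rng, n, ["u", "v"])
        y = 1 + 2 * X["u"] - 3 * X["v"] + rng.normal(0, 0.2, n)
        model = stepwise_fit(y, X)
        sm_fit = sm.OLS(y, sm.add_constant(X[model.predictors])).fit()
        assert model.intercept == pytest.approx(sm_fit.params["const"], rel=1e-9)
        for name, coef in model.terms:
            assert coef == pytest.approx(sm_fit.params[name], rel=1e-9)
        assert model.r2 == pytest.approx(sm_fit.rsquared, rel=1e-9)
        assert model.adj_r2 == pytest.approx(sm_fit.rsquared_adj, rel=1e-9)
        assert model.f == pytest.approx(sm_fit.fvalue, rel=1e-9)
        assert model.sig_f == pytest.approx(sm_fit.f_pvalue, rel=1e-9, abs=1e-300)
        assert model.rmse == pytest.approx(np.sqrt(sm_fit.mse_resid), rel=1e-9)

    def test_best_subset_agreement_on_planted_single_signal(self, rng):
        # exhaustive best-subset under the same entry criterion agrees with
        # stepwise for a clear single-signal design in nearly all seeds
        agree, reps = 0, 60
        for _ in range(reps):
            n = 60
            X = _noise_frame(rng, n, list("abcde"))
            y = 1.0 + 2.5 * X["c"] + rng.normal(0, 0.5, n)
            model = stepwise_fit(y, X)
            # best single predictor by SSE
            sses = {}
            for name in X.columns:
                xv = np.asarray(X[name])
                b = ((xv - xv.mean()) * (y - y.mean())).sum() / ((xv - xv.mean()) ** 2).sum()
                r = y - (y.mean() - b * xv.mean()) - b * xv
                sses[name] = float(r @ r)
            best_single = min(sses, key=sses.get)
            if model.predictors and model.predictors[0] == best_single == "c":
                agree += 1
        assert agree >= 0.95 * reps


class TestDirectionConsistency:
    def test_fitted_slope_sign_matches_correlation_sign(self, rng):
        # planted single-factor signal: the response model's slope and the
        # correlation cell must agree in sign, both ways round
        for slope in (2.0, -2.0):
            n = 60
            x = rng.normal(0, 1, n)
            X = pd.DataFrame({"x": x, "z": rng.normal(0, 1, n)})
            y = 5.0 + slope * x + rng.normal(0, 0.3, n)
            model = stepwise_fit(y, X)
            corr = correlation_screen(pd.DataFrame({"y": y}), X)
            assert np.sign(dict(model.terms)["x"]) == np.sign(
                corr.r.loc["y", "x"]) == np.sign(slope)


class TestFitStatistics:
    def test_perfect_fit(self, rng):
        x = rng.normal(0, 1, 30)
        y = 2.0 + 4.0 * x
        model = stepwise_fit(y, pd.DataFrame({"x": x}))
        assert model.r2 == pytest.approx(1.0)
        assert model.rmse == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_fixture(self):
        # y on x with known residuals: x=[0,1,2,3], y=[0,1,1,2] -> b=0.6, a=0.1
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 1.0, 2.0])
        model = LinearModel(response="y", intercept=0.1, terms=[("x", 0.6)], n=4)
        model = fit_statistics(model, y, pd.DataFrame({"x": x}))
        sse = float(((y - (0.1 + 0.6 * x)) ** 2).sum())  # 0.2
        sst = float(((y - y.mean()) ** 2).sum())  # 2.0
        assert model.r2 == pytest.approx(1 - sse / sst)
        assert model.adj_r2 == pytest.approx(1 - (sse / sst) * 3 / 2)
        assert model.rmse == pytest.approx(np.sqrt(sse / 2))
        assert model.f == pytest.approx((sst - sse) / (sse / 2))
        assert model.sig_f == pytest.approx(sps.f.sf((sst - sse) / (sse / 2), 1, 2))

    def test_noise_predictor_shrinks_adjusted_r2(self, rng):
        # forced entry of a pure-noise extra predictor: R^2 never decreases,
        # adjusted R^2 decreases in expectation
        diffs_r2, diffs_adj = [], []
        for _ in range(100):
            n = 40
            x = rng.normal(0, 1, n)
            y = 1 + x + rng.normal(0, 1, n)
            base = stepwise_fit(y, pd.DataFrame({"x": x}),
                                StepwiseConfig(forced_entry=True))
            noisy = stepwise_fit(
                y, pd.DataFrame({"x": x, "z": rng.normal(0, 1, n)}),
                StepwiseConfig(forced_entry=True))
            diffs_r2.append(noisy.r2 - base.r2)
            diffs_adj.append(noisy.adj_r2 - base.adj_r2)
        assert min(diffs_r2) >= -1e-12
        assert np.mean(diffs_adj) < 0


class TestEvaluateModel:
    # example equations in published form: evaluation is plain arithmetic
    R_MEAN = LinearModel(response="R_Mean", intercept=29.094,
                         terms=[("VP_h", 0.298)], n=35)
    G_MEDIAN = LinearModel(response="G_Median", intercept=46.048,
                           terms=[("RH_h", 0.214), ("TD_h", 0.705)], n=35)

    def test_zero_inputs_return_intercept(self):
        assert evaluate_model(self.R_MEAN, {"VP_h": 0.0}) == pytest.approx(
            29.094, abs=1e-12)

    def test_two_term_equation_matches_hand_arithmetic(self):
        got = evaluate_model(self.G_MEDIAN, {"RH_h": 50.0, "TD_h": 10.0})
        assert got == pytest.approx(46.048 + 0.214 * 50 + 0.705 * 10, abs=1e-12)

    def test_missing_predictor_named(self):
        with pytest.raises(KeyError, match="TD_h"):
            evaluate_model(self.G_MEDIAN, {"RH_h": 50.0})

    def test_unable_to_model_cannot_be_evaluated(self):
        m = LinearModel(response="B_Mean", status="unable_to_model")
        with pytest.raises(ValueError, match="unable_to_model"):
            evaluate_model(m, {})


class TestFitAll:
    def test_response_and_inversion_shapes(self, rng):
        from leafcgsd.cgsd import cgsd_table, compute_cgsd
        from leafcgsd.synthetic import generate_study, greenhouse_scenario

        study = generate_study(greenhouse_scenario(5))
        recs = [compute_cgsd(img, sid) for img, sid in
                zip(study.images, study.sample_ids)]
        cgsd_df = cgsd_table(recs)
        meteo_df = study.meteo.to_frame()
        resp = fit_all_response_models(cgsd_df, meteo_df)
        inv = fit_all_inversion_models(meteo_df, cgsd_df)
        assert len(resp) == 20
        assert len(inv) == 5
        # the flat-B planted map makes B_Mean unfittable; G_Mean must fit
        assert resp["B_Mean"].status == "unable_to_model"
        assert resp["G_Mean"].status == "fitted"

    def test_model_json_roundtrip(self, tmp_path, rng):
        from leafcgsd.modeling import load_models, save_models

        X = _noise_frame(rng, 50, ["a", "b"])
        y = 1 + 2 * X["a"] + rng.normal(0, 0.1, 50)
        models = {"y": stepwise_fit(y, X),
                  "none": LinearModel(response="none", status="unable_to_model")}
        save_models(models, tmp_path / "m.json")
        back = load_models(tmp_path / "m.json")
        assert back["y"].to_dict() == models["y"].to_dict()
        assert back["none"].status == "unable_to_model"
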