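"""Conditional-logit fitter, lag mixed models, AIC machinery, collinearity."""

import numpy as np
import pandas as pd
import pytest

from snowtrack import models
from snowtrack.models import (ModelFit, SeparationError, compare_models,
                              fit_conditional_logit, fit_lag_model, screen_collinearity)
from snowtrack.simulate import simulate_strata


def brute_force_loglik(beta, strata, predictor):
    """Independent oracle: direct python evaluation of the conditional
    likelihood, one stratum at a time."""
    ll = 0.0
    for _, g in strata.groupby("stratum"):
        eta = beta * g[predictor].to_numpy()
        chosen = eta[g["case"].to_numpy() == 1][0]
        m = eta.max()
        ll += chosen - (m + np.log(np.exp(eta - m).sum()))
    return ll


class TestConditionalLogit:
    def test_matches_grid_search_oracle(self):
        strata = simulate_strata(50, K=10, beta={"snow": -1.0}, seed=1)
        fit = fit_conditional_logit(strata, ["snow"])
        grid = np.arange(-3.0, 0.5, 0.001)
        lls = np.array([brute_force_loglik(b, strata, "snow") for b in grid])
        assert fit.params["snow"] == pytest.approx(grid[np.argmax(lls)], abs=1e-3)
        assert fit.loglik == pytest.approx(lls.max(), abs=1e-6)

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit
        strata = simulate_strata(120, K=10, beta={"snow": -1.0, "wind": 0.5},
                                 continuous_covariates=("wind",), seed=2)
        fit = fit_conditional_logit(strata, ["snow", "wind"])
        sm_fit = ConditionalLogit(strata["case"], strata[["snow", "wind"]],
                                  groups=strata["stratum"]).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), sm_fit.params, atol=1e-4)
        np.testing.assert_allclose(fit.se.to_numpy(), sm_fit.bse, rtol=1e-3)
        assert fit.loglik >= sm_fit.llf - 1e-6

    def test_null_loglik_is_minus_log_k_plus_1(self):
        strata = simulate_strata(40, K=10, beta={"snow": 0.0}, seed=3)
        fit = fit_conditional_logit(strata, ["snow"])
        assert fit.flags["null_loglik"] == pytest.approx(-40 * np.log(11.0))

    def test_stratum_constant_offset_invariance(self):
        strata = simulate_strata(60, K=10, beta={"snow": -1.0}, seed=4)
        fit1 = fit_conditional_logit(strata, ["snow"])
        shifted = strata.copy()
        offsets = shifted["stratum"].map(lambda s: 3.7 * (s % 5))
        shifted["snow"] = shifted["snow"] + offsets
        fit2 = fit_conditional_logit(shifted, ["snow"])
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-8)
        assert fit2.params["snow"] == pytest.approx(fit1.params["snow"], abs=1e-6)

    def test_constant_predictor_dropped_null_loglik(self):
        strata = simulate_strata(30, K=10, beta={"snow": 0.0}, seed=5)
        strata["flat"] = 1.0
        with pytest.warns(UserWarning, match="no within-stratum variation"):
            fit = fit_conditional_logit(strata, ["flat"])
        assert fit.k_params == 0
        assert fit.loglik == pytest.approx(-30 * np.log(11.0))

    def test_separation_raises_naming_predictor(self):
        # chosen endpoint always uniquely snow-free
        rows = []
        for s in range(30):
            snow = np.ones(11)
            snow[0] = 0.0
            case = np.zeros(11, dtype=int)
            case[0] = 1
            rows.append(pd.DataFrame({"stratum": s, "case": case, "snow": snow,
                                      "individual": f"i{s % 5}"}))
        strata = pd.concat(rows, ignore_index=True)
        with pytest.raises(SeparationError, match="snow"):
            fit_conditional_logit(strata, ["snow"])

    def test_cluster_robust_se_larger_on_clustered_data(self):
        strata = simulate_strata(200, K=10, beta={"snow": -1.0}, seed=6, n_individuals=8)
        plain = fit_conditional_logit(strata, ["snow"])
        robust = fit_conditional_logit(strata, ["snow"], cluster_robust=True)
        # same point estimate, different (finite, positive) uncertainty
        assert robust.params["snow"] == plain.params["snow"]
        assert robust.se["snow"] > 0 and np.isfinite(robust.se["snow"])


class TestLagModels:
    @staticmethod
    def gaussian_lag_table(slope=0.3, n_ind=20, sd_ind=0.5, sd_noise=1.0,
                           seed=0, years=(2016,)):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_ind):
            for yr in years:
                a = rng.normal(0, sd_ind)
                for lag in range(-10, 11):
                    rows.append({"individual": f"i{i:02d}", "year": yr,
                                 "date": f"{yr}-05-01", "lag": lag,
                                 "variable": "temperature",
                                 "value": 1.0 + a + slope * lag + rng.normal(0, sd_noise),
                                 "missing": False})
        return pd.DataFrame(rows)

    def test_gaussian_slope_recovery(self):
        lt = self.gaussian_lag_table(slope=0.3, n_ind=20, seed=1)
        fit = fit_lag_model(lt, "temperature")
        assert abs(fit.params["lag"] - 0.3) < 3 * fit.se["lag"]
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)

    def test_gaussian_nested_year_structure_used(self):
        lt = self.gaussian_lag_table(slope=0.2, n_ind=10, seed=2, years=(2015, 2016))
        fit = fit_lag_model(lt, "temperature")
        assert "year-in-individual" in fit.grouping
        assert abs(fit.params["lag"] - 0.2) < 3 * fit.se["lag"]

    def test_constant_response_degenerate(self):
        lt = self.gaussian_lag_table(slope=0.0, n_ind=5, sd_ind=0.0, sd_noise=0.0, seed=3)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_lag_model(lt, "temperature")
        assert fit.params["lag"] == 0.0
        assert fit.flags.get("degenerate")

    def test_single_individual_falls_back_to_fixed_effects(self):
        lt = self.gaussian_lag_table(n_ind=1, seed=4)
        with pytest.warns(UserWarning, match="fixed-effects"):
            fit = fit_lag_model(lt, "temperature")
        assert fit.flags.get("fallback")

    def test_binomial_slope_sign_on_melting_series(self):
        # a melting world: P(snow) declines with the shifted date at a fixed
        # location, so the lag slope must come out negative
        rng = np.random.default_rng(5)
        rows = []
        for i in range(12):
            melt_day = rng.uniform(-6, 6)
            for lag in range(-10, 11):
                p = 1.0 / (1.0 + np.exp(0.8 * (lag - melt_day)))
                rows.append({"individual": f"i{i:02d}", "year": 2016,
                             "date": "2016-05-01", "lag": lag, "variable": "snow",
                             "value": float(rng.random() < p), "missing": False})
        fit = fit_lag_model(pd.DataFrame(rows), "snow")
        assert fit.params["lag"] < 0
        assert fit.se["lag"] > 0


class TestCompareModels:
    @staticmethod
    def fake_fit(name, aic_target, n=100, k=2):
        ll = (2 * k - aic_target) / 2.0
        return ModelFit(name, "y", ["x"], pd.Series({"x": 0.0}), pd.Series({"x": 1.0}),
                        ll, k, n)

    def test_equal_aic_splits_weights(self):
        comp = compare_models([self.fake_fit("a", 100.0), self.fake_fit("b", 100.0)])
        np.testing.assert_allclose(comp.table["weight"], [0.5, 0.5])
        assert (comp.table["delta_aic"] == 0).all()

    def test_delta_exactly_two_not_different(self):
        comp = compare_models([self.fake_fit("a", 100.0), self.fake_fit("b", 102.0)])
        assert not comp.table["different"].any()  # strict > 2

    def test_weights_closed_form(self):
        comp = compare_models([self.fake_fit("a", 100.0), self.fake_fit("b", 102.0),
                               self.fake_fit("c", 110.0)])
        raw = np.array([1.0, np.exp(-1.0), np.exp(-5.0)])
        np.testing.assert_allclose(comp.table["weight"], raw / raw.sum(), rtol=1e-12)
        assert comp.table["weight"].sum() == pytest.approx(1.0)

    def test_differing_n_rejected(self):
        with pytest.raises(ValueError, match="differing row counts"):
            compare_models([self.fake_fit("a", 100.0, n=100), self.fake_fit("b", 90.0, n=99)])


class TestScreenCollinearity:
    def test_identical_columns_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        rep = screen_collinearity(df, ["a", "b"])
        assert rep["flagged"].all()
        assert rep["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)})
        rep = screen_collinearity(df, ["a", "b"])
        assert abs(rep["r"].iloc[0]) < 0.05
        assert not rep["flagged"].any()

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=200)
        b = 0.6 * a + rng.normal(size=200)
        rep = screen_collinearity(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        r_hand = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert rep["r"].iloc[0] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_flagged_undefined(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2, 3, 4]})
        rep = screen_collinearity(df, ["a", "b"])
        assert rep["flagged"].iloc[0]
        assert np.isnan(rep["r"].iloc[0])
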