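"""Model selection, diversity-model fits, variogram and correlations."""
import itertools

import numpy as np
import pandas as pd
import pytest

from idhscape import inference
from idhscape.inference import MCMCSettings

from conftest import make_power_data

TABLE_THETA = (73.0, 10.839859, -1.480906, 2.0, 0.0177333, 0.0546224)


class TestBmaPip:
    def test_single_active_predictor_dominates(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = 2.0 * X["a"].to_numpy()  # noise-free
        res = inference.bma_pip(X, y)
        assert res.pip["a"] > 0.99
        assert res.model_probs["prob"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_pip_equals_sum_of_containing_model_probabilities(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=list("abcde"))
        y = X["b"].to_numpy() + rng.normal(0, 1, 40)
        res = inference.bma_pip(X, y)
        for col in X.columns:
            direct = res.model_probs.loc[
                res.model_probs["predictors"].map(lambda t: col in t),
                "prob"].sum()
            assert res.pip[col] == pytest.approx(direct, abs=1e-12)

    def test_pure_noise_keeps_inclusion_low(self):
        pips = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(60, 6)),
                             columns=[f"x{i}" for i in range(6)])
            res = inference.bma_pip(X, r.normal(size=60))
            pips.append(res.pip.mean())
        assert np.mean(pips) < 0.5

    def test_guardrails(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 21)))
        with pytest.raises(ValueError, match="enumeration limit"):
            inference.bma_pip(X, rng.normal(size=30))
        with pytest.raises(ValueError, match="more than 3"):
            inference.bma_pip(X.iloc[:3, :2], np.ones(3))
        Xd = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        with pytest.warns(UserWarning, match="ridge"):
            inference.bma_pip(Xd, rng.normal(size=10))


def _exhaustive_best_aic(data, response, terms, hierarchy):
    import statsmodels.api as sm
    best = (np.inf, None)
    for k in range(len(terms) + 1):
        for sub in itertools.combinations(terms, k):
            if any(hierarchy.get(t) not in (None, *sub) for t in sub):
                continue
            X = sm.add_constant(data[list(sub)], has_constant="add") \
                if sub else pd.DataFrame({"const": np.ones(len(data))})
            aic = sm.OLS(data[response], X).fit().aic
            if aic < best[0]:
                best = (aic, set(sub))
    return best


class TestStepwiseAic:
    def test_recovers_single_strong_predictor(self, rng):
        data = pd.DataFrame(rng.normal(size=(80, 5)),
                            columns=[f"x{i}" for i in range(5)])
        data["y"] = 3.0 * data["x2"] + rng.normal(0, 0.5, 80)
        terms = [f"x{i}" for i in range(5)]
        res = inference.stepwise_aic(data, "y", terms)
        best_aic, best_set = _exhaustive_best_aic(data, "y", terms, {})
        assert "x2" in res.terms and "x2" in best_set
        assert res.aic == pytest.approx(best_aic, abs=1e-6)

    def test_intercept_only_truth_selects_nothing(self):
        # a noise realization for which the exhaustive-AIC oracle keeps the
        # empty model; the stepwise search must agree
        r = np.random.default_rng(0)
        data = pd.DataFrame(r.normal(size=(200, 4)),
                            columns=list("abcd"))
        data["y"] = 5.0 + r.normal(0, 1.0, 200)
        res = inference.stepwise_aic(data, "y", list("abcd"))
        _, best_set = _exhaustive_best_aic(data, "y", list("abcd"), {})
        assert best_set == set()
        assert res.terms == []

    def test_local_optimum_contract_and_hierarchy(self, rng):
        data = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        data["a2"] = data["a"] ** 2
        data["y"] = data["a"] + 0.8 * data["a2"] + rng.normal(0, 0.3, 60)
        hierarchy = {"a2": "a"}
        res = inference.stepwise_aic(data, "y", ["a", "b", "c", "a2"],
                                     hierarchy)
        assert {"a", "a2"} <= set(res.terms)
        # no single add or drop obeying the hierarchy improves the AIC
        import statsmodels.api as sm
        cur = set(res.terms)
        for t in ["a", "b", "c", "a2"]:
            if t in cur:
                trial = cur - {t}
                if t == "a" and "a2" in trial:
                    continue
            else:
                if hierarchy.get(t) not in (None, *cur):
                    continue
                trial = cur | {t}
            X = sm.add_constant(data[sorted(trial)], has_constant="add")
            assert sm.OLS(data["y"], X).fit().aic >= res.aic - 1e-8

    def test_non_finite_response_rejected(self, rng):
        data = pd.DataFrame({"x": rng.normal(size=10),
                             "y": [np.nan] + [1.0] * 9})
        with pytest.raises(ValueError, match="non-finite"):
            inference.stepwise_aic(data, "y", ["x"])


class TestQuadraticFit:
    def test_noise_free_recovery_to_machine_precision(self):
        tab = make_power_data(33, TABLE_THETA, 0.0, seed=21)
        fit = inference.fit_idh_quadratic(tab)
        t0, t1, t2, _, t4, t5 = TABLE_THETA
        for name, truth in [("const", t0), ("urti_pct", t1),
                            ("urti_pct2", t2), ("rainfall_mm", t4),
                            ("elevation_m", t5)]:
            assert fit.params[name] == pytest.approx(truth, abs=1e-8)
        assert fit.peak_u == pytest.approx(-t1 / (2 * t2), abs=1e-8)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_positive_curvature_reports_no_peak(self):
        tab = make_power_data(40, (73.0, -2.0, 1.0, 2.0, 0.0177, 0.0546),
                              0.0, seed=22)
        fit = inference.fit_idh_quadratic(tab)
        assert fit.peak_u is None

    def test_needs_six_sites(self):
        tab = make_power_data(5, TABLE_THETA, 1.0, seed=23)
        with pytest.raises(ValueError, match="6 sites"):
            inference.fit_idh_quadratic(tab)


class TestPowerModel:
    def test_fixed_exponent_agrees_with_least_squares(self):
        tab = make_power_data(120, TABLE_THETA, 0.5, seed=77)
        post = inference.fit_idh_power(
            tab, settings=MCMCSettings(chains=2, draws=1500, warmup=1500,
                                       seed=3, fix_power=2.0))
        quad = inference.fit_idh_quadratic(tab)
        med = post.median()
        assert med["theta1"] == pytest.approx(quad.params["urti_pct"],
                                              abs=0.15)
        assert med["theta2"] == pytest.approx(quad.params["urti_pct2"],
                                              abs=0.05)
        assert med["theta4"] == pytest.approx(quad.params["rainfall_mm"],
                                              abs=2e-4)
        assert (post.samples["theta3"] == 2.0).all()
        assert post.converged

    def test_posterior_concentrates_as_noise_vanishes(self):
        tab = make_power_data(150, TABLE_THETA, 0.1, seed=31)
        post = inference.fit_idh_power(
            tab, settings=MCMCSettings(chains=2, draws=1000, warmup=1000,
                                       seed=5, fix_power=2.0))
        ci = post.ci()
        width = ci["upper"] - ci["lower"]
        assert width["theta1"] < 0.5
        assert width["theta4"] < 5e-4
        med = post.median()
        assert med["theta1"] == pytest.approx(TABLE_THETA[1], abs=0.3)

    def test_alpha_draw_redraw_widens_posterior(self):
        tab = make_power_data(60, TABLE_THETA, 3.0, seed=41)
        rng = np.random.default_rng(2)
        draws = tab["alpha_mean"].to_numpy() + rng.normal(
            0.0, 8.0, size=(200, len(tab)))
        s = MCMCSettings(chains=2, draws=800, warmup=800, seed=6,
                         fix_power=2.0)
        tight = inference.fit_idh_power(tab, settings=s)
        wide = inference.fit_idh_power(tab, alpha_draws=draws, settings=s)
        assert wide.samples["sigma"].median() > tight.samples["sigma"].median()

    def test_settings_validation(self):
        tab = make_power_data(30, TABLE_THETA, 2.0, seed=1)
        with pytest.raises(ValueError, match="prior bounds"):
            inference.fit_idh_power(
                tab, settings=MCMCSettings(fix_power=9.0))
        with pytest.raises(ValueError, match="one column per site"):
            inference.fit_idh_power(tab, alpha_draws=np.ones((10, 3)))


class TestPeakAndShape:
    def test_quadratic_closed_form_vertex(self):
        df = pd.DataFrame({"theta1": [10.839859], "theta2": [-1.480906],
                           "theta3": [2.0]})
        peak = inference.peak_and_shape(df, u_max=6.5)
        assert peak.u_star[0] == pytest.approx(3.659874, abs=1e-5)
        assert peak.p_unimodal == 1.0

    def test_non_negative_curvature_counts_as_boundary(self):
        df = pd.DataFrame({"theta1": [5.0, -1.0], "theta2": [0.5, 0.2],
                           "theta3": [2.0, 2.0]})
        peak = inference.peak_and_shape(df, u_max=6.5)
        assert peak.p_unimodal == 0.0
        assert set(peak.u_star) <= {0.0, 6.5}

    def test_general_exponent_matches_grid_search(self):
        df = pd.DataFrame({"theta1": [8.0], "theta2": [-2.0],
                           "theta3": [1.7]})
        peak = inference.peak_and_shape(df, u_max=6.5)
        grid = np.linspace(0, 6.5, 200001)
        g = 8.0 * grid - 2.0 * grid**1.7
        assert peak.u_star[0] == pytest.approx(grid[np.argmax(g)], abs=1e-3)


class TestVariogram:
    def test_constant_field_is_flat_zero(self, rng):
        coords = rng.uniform(0, 10, (8, 2))
        v = inference.empirical_variogram(coords, np.full(8, 3.0),
                                          np.array([0.0, 5.0, 15.0]))
        assert (v["gamma"].dropna() == 0.0).all()

    def test_two_point_semivariance(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 5.0],
                           [5.0, 5.0], [9.0, 9.0]])
        vals = np.array([0.0, 2.0, 0.0, 0.0, 0.0])
        v = inference.empirical_variogram(coords, vals,
                                          np.array([0.9, 1.1]))
        # the single pair at distance 1 has gamma = 0.5 * 2^2 = 2
        assert v["gamma"].iloc[0] == pytest.approx(2.0)
        assert v["n_pairs"].iloc[0] == 1

    def test_iid_field_flat_at_the_variance(self):
        sd = 2.0
        gammas = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            coords = r.uniform(0, 100, (100, 2))
            v = inference.empirical_variogram(
                coords, r.normal(0, sd, 100), np.linspace(0, 100, 5))
            gammas.append(v["gamma"].to_numpy())
        mean_g = np.nanmean(gammas, axis=0)
        se = np.nanstd(gammas, axis=0, ddof=1) / np.sqrt(40)
        ok = ~np.isnan(mean_g)
        assert (np.abs(mean_g[ok] - sd**2) < 4 * se[ok]).all()


class TestPearson:
    def test_exact_and_sign_properties(self):
        res = inference.pearson_cor([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        a = inference.pearson_cor([1, 2, 3, 5], [2, 1, 4, 3])
        b = inference.pearson_cor([1, 2, 3, 5], [-2, -1, -4, -3])
        assert a.r == pytest.approx(-b.r)
        assert a.p == pytest.approx(b.p)

    def test_t_statistic_from_printed_r_and_df(self):
        # |r| = 0.833 on 31 DF gives |t| ~ 8.4 by t = r sqrt(df/(1-r^2))
        t = -0.833 * np.sqrt(31 / (1 - 0.833**2))
        assert t == pytest.approx(-8.3827, abs=1e-3)
        x = np.arange(33.0)
        res = inference.pearson_cor(x, -x)
        assert res.df == 31

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            inference.pearson_cor([1.0, 1.0, 1.0], [1, 2, 3])
        with pytest.raises(ValueError, match="3 finite"):
            inference.pearson_cor([1.0, np.nan], [1.0, 2.0])
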