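import math
import types

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mangoripen as mr
from mangoripen.errors import CollinearityError, LeakageError, ValidationError
from mangoripen.experiments import evaluate_on_frame


class TestMetrics:
    def test_rmse_hand_arithmetic(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        est = obs - np.array([1.0, -1.0, 1.0, -1.0])
        assert mr.rmse(obs, est, f=2) == pytest.approx(math.sqrt(4 / 2))
        assert mr.rmse(obs, obs, f=2) == 0.0
        # homogeneity: doubling residuals doubles RMSE
        est2 = obs - 2 * np.array([1.0, -1.0, 1.0, -1.0])
        assert mr.rmse(obs, est2, 2) == pytest.approx(2 * mr.rmse(obs, est, 2))

    def test_rmse_needs_dof(self):
        with pytest.raises(ValidationError):
            mr.rmse([1.0, 2.0], [1.0, 2.0], f=2)

    def test_mrd_hand_arithmetic(self):
        assert mr.mrd([10.0, 10.0], [8.0, 12.0], f=1) == pytest.approx(
            math.sqrt(0.08), abs=5e-4
        )
        assert mr.mrd([10.0, 10.0], [10.0, 10.0], f=1) == 0.0

    def test_mrd_scale_invariant(self):
        obs = np.array([4.0, 8.0, 12.0])
        est = np.array([5.0, 7.0, 13.0])
        assert mr.mrd(obs, est, 1) == pytest.approx(mr.mrd(3 * obs, 3 * est, 1))

    def test_mrd_excludes_day_zero(self):
        """Day-0 rows carry no relative error; n is reduced accordingly."""
        obs = np.array([0.0, 10.0, 10.0])
        est = np.array([99.0, 8.0, 12.0])
        assert mr.mrd(obs, est, f=1) == pytest.approx(math.sqrt(0.08), abs=5e-4)

    def test_mrd_all_zero_undefined(self):
        with pytest.raises(ValidationError):
            mr.mrd([0.0, 0.0], [1.0, 1.0], f=1)

    def test_zero_iff_exact(self):
        """RMSE and MRD are zero exactly when every prediction is exact."""
        obs = np.array([2.0, 4.0, 6.0, 8.0])
        assert mr.rmse(obs, obs, 2) == 0.0
        assert mr.mrd(obs, obs, 2) == 0.0
        est = obs.copy()
        est[1] += 1e-9
        assert mr.rmse(obs, est, 2) > 0.0
        assert mr.mrd(obs, est, 2) > 0.0

    def test_aic_orderings(self):
        # at fixed f, smaller RSS -> smaller AIC
        assert mr.aic_from_rss(1.0, 50, 3) < mr.aic_from_rss(2.0, 50, 3)
        # identical RSS, one extra coefficient -> AIC difference exactly 2
        assert mr.aic_from_rss(1.0, 50, 4) - mr.aic_from_rss(1.0, 50, 3) == 2.0
        assert mr.aic_from_rss(0.0, 50, 3) == -math.inf


class TestFit:
    def test_constant_response(self):
        df = pd.DataFrame({"pH": [3.0, 3.5, 4.0, 5.0], "day": [7.0] * 4})
        res = mr.fit_mlr(df, mr.ModelSpec(("pH",), "X"))
        assert res.intercept == pytest.approx(7.0)
        assert res.coefficients["pH"] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_grid_on_toy_set(self):
        """OLS solution minimises RSS over a coarse (intercept, slope) grid."""
        df = pd.DataFrame({"pH": [3.0, 4.0, 6.0], "day": [1.0, 2.0, 5.0]})
        res = mr.fit_mlr(df, mr.ModelSpec(("pH",), "X"))
        a_grid = np.linspace(-5, 5, 201)
        b_grid = np.linspace(-2, 3, 201)
        x, y = df["pH"].to_numpy(), df["day"].to_numpy()
        rss = ((y[None, None, :] - a_grid[:, None, None]
                - b_grid[None, :, None] * x[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        assert res.intercept == pytest.approx(a_grid[i], abs=0.05)
        assert res.coefficients["pH"] == pytest.approx(b_grid[j], abs=0.05)

    @given(seed=st.integers(0, 300))
    def test_matches_normal_equations(self, seed):
        """lstsq fit equals the explicit normal-equation solve (tiny n, p)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        preds = ["pH", "Hue", "SSC"][: int(rng.integers(1, 4))]
        df = pd.DataFrame(rng.normal(5, 2, size=(n, len(preds))), columns=preds)
        df["day"] = rng.normal(6, 3, size=n)
        res = mr.fit_mlr(df, mr.ModelSpec(tuple(preds), "X"))
        X = np.column_stack([np.ones(n), df[preds].to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ df["day"].to_numpy())
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-8)

    def test_matches_statsmodels(self, calibration_obs):
        """Independent cross-check of coefficients and R^2 against statsmodels."""
        import statsmodels.api as sm

        data = mr.prepare_model_frame(calibration_obs)
        res = mr.fit_mlr(data, mr.ModelSpec(("pH", "Hue", "SSC", "C_c"), "X"))
        X = sm.add_constant(
            np.column_stack(
                [data["pH"], data["hue_deg"], data["SSC"], data["C_c"]]
            )
        )
        ref = sm.OLS(data["day"].to_numpy(), X).fit()
        assert np.allclose(res.params.to_numpy(), ref.params, atol=1e-8)
        assert res.rsquared == pytest.approx(ref.rsquared, abs=1e-10)
        assert np.allclose(res.bse.to_numpy(), ref.bse, atol=1e-8)

    def test_noiseless_refit_recovers_generating_model(self, calibration_obs, bank):
        """Exact recovery: data generated from a linear model refits to it."""
        data = mr.prepare_model_frame(calibration_obs).copy()
        data["y"] = evaluate_on_frame(bank.multivarietal[4], data)
        res = mr.fit_mlr(
            data, mr.ModelSpec(("pH", "Hue", "SSC", "C_c"), "X"), response="y"
        )
        assert res.intercept == pytest.approx(12.038, abs=1e-8)
        assert res.coefficients["C_c"] == pytest.approx(-14.836, abs=1e-8)

    def test_collinearity_names_offender(self, diourou_obs):
        """Variety-level predictors are constant within one variety."""
        data = mr.prepare_model_frame(diourou_obs)
        with pytest.raises(CollinearityError) as err:
            mr.fit_mlr(data, mr.ModelSpec(("pH", "Hue", "SSC", "C_f", "C_c"), "X"))
        assert {"C_f", "C_c"} <= set(err.value.columns)


class TestAlphaDuality:
    def test_alpha_equals_rescaled_x_fit(self, diourou_obs):
        """beta_alpha = beta_X * X_p(0); intercept and R^2 identical."""
        x0 = mr.harvest_baselines(diourou_obs)
        spec_x = mr.ModelSpec(("pH", "Hue", "SSC"), "X")
        spec_a = mr.ModelSpec(("pH", "Hue", "SSC"), "alpha")
        rx = mr.fit_mlr(diourou_obs, spec_x)
        ra = mr.fit_mlr(diourou_obs, spec_a)
        assert ra.intercept == pytest.approx(rx.intercept, abs=1e-10)
        assert ra.rsquared == pytest.approx(rx.rsquared, abs=1e-10)
        for p in ("pH", "Hue", "SSC"):
            assert ra.coefficients[p] == pytest.approx(
                rx.coefficients[p] * x0.loc["Diourou", p], rel=1e-10
            )

    def test_published_coefficient_ratio_recovers_harvest_ph(self, bank):
        """The alpha/X coefficient ratio embeds the harvest baseline."""
        ratio = (
            bank.intra["Diourou"]["alpha"].coefficients["pH"]
            / bank.intra["Diourou"]["X"].coefficients["pH"]
        )
        assert round(ratio, 2) == 2.81


class TestDiagnostics:
    def test_shapiro_needs_three_residuals(self):
        fake = types.SimpleNamespace(resid=np.array([0.1, -0.1]))
        with pytest.raises(ValidationError):
            mr.residual_normality(fake)

    def test_bimodal_residuals_rejected(self):
        rng = np.random.default_rng(0)
        resid = np.concatenate([rng.normal(-5, 0.1, 40), rng.normal(5, 0.1, 40)])
        fake = types.SimpleNamespace(resid=resid)
        with pytest.warns(UserWarning):
            stat, p = mr.residual_normality(fake)
        assert p < 1e-6

    def test_ancova_time_effect_dominates(self, calibration_obs):
        """Storage time drives pH/SSC/Hue/TA on the default campaigns."""
        table = mr.ancova_screen(calibration_obs)
        times = table[table["term"] == "storage time"]
        assert (times["p"] < 1e-10).all()
        varieties = table[table["term"] == "variety"]
        assert (varieties["p"] < 1e-6).any()

    def test_ancova_no_variety_effect_when_anchors_shared(self, profiles):
        """Clones of one variety show no variety effect."""
        import dataclasses

        a = profiles["Diourou"]
        b = dataclasses.replace(a, name="Diourou-clone")
        obs = mr.simulate_campaign(
            mr.CampaignDesign(varieties=(a, b), n_per_variety=10, seed=5)
        )
        table = mr.ancova_screen(obs).set_index(["response", "term"])
        assert table.loc[("pH", "variety"), "p"] > 0.05


class TestComparison:
    def test_duplicate_specs_identical_metrics(self, calibration_obs):
        data = mr.prepare_model_frame(calibration_obs)
        spec = mr.ModelSpec(("pH", "Hue", "SSC"), "X", label="first")
        spec2 = mr.ModelSpec(("pH", "Hue", "SSC"), "X", label="second")
        comp = mr.compare_models(data, [spec, spec2])
        assert comp.table.loc["first", "aic"] == comp.table.loc["second", "aic"]
        assert comp.table.loc["first", "r2"] == comp.table.loc["second", "r2"]

    def test_single_variety_flags_varietal_predictors(self, diourou_obs):
        data = mr.prepare_model_frame(diourou_obs)
        comp = mr.compare_models(data, mr.candidate_specs("X"))
        control = comp.table.loc["1 (control)"]
        assert np.isfinite(control["aic"])
        flagged = comp.table[comp.table["note"].str.startswith("collinear")]
        assert len(flagged) == 5  # every candidate with a varietal variable
        assert comp.best_label == "1 (control)"


class TestCalibrateValidate:
    def test_leakage_rejected(self, calibration_obs):
        with pytest.raises(LeakageError):
            mr.calibrate_validate(
                calibration_obs, calibration_obs, mr.ModelSpec(("pH",), "X")
            )

    def test_empty_validation_rejected(self, calibration_obs):
        with pytest.raises(ValidationError):
            mr.calibrate_validate(
                calibration_obs, calibration_obs.iloc[0:0], mr.ModelSpec(("pH",), "X")
            )

    def test_validation_tracks_calibration_same_generator(self):
        """Same generating process -> validation R^2 near calibration R^2."""
        cal = mr.simulate_campaign(mr.calibration_design(seed=21))
        val = mr.simulate_campaign(mr.validation_design(seed=22))
        spec = mr.ModelSpec(("pH", "Hue", "SSC"), "X")
        _, mc, mv = mr.calibrate_validate(cal, val, spec)
        assert mv.r2 == pytest.approx(mc.r2, abs=0.15)

    def test_alpha_form_robust_to_harvest_shift(self, profiles):
        """Season-shifted validation hurts the X form more than the alpha form.

        Shifting a whole trajectory by a common factor leaves relative
        values unchanged, so the alpha model (validated with the new
        campaign's own baselines) keeps its accuracy.
        """
        shift = {"pH": 1.10, "SSC": 1.12, "Hue": 0.95}
        shifted = tuple(
            profiles[v].scaled_anchors(shift) for v in mr.LOCAL_VARIETIES
        )
        wins = 0
        n_rep = 7
        for r in range(n_rep):
            cal = mr.simulate_campaign(mr.calibration_design(seed=100 + r))
            val = mr.simulate_campaign(
                mr.validation_design(seed=200 + r, varieties=shifted)
            )
            _, _, vx = mr.calibrate_validate(
                cal, val, mr.ModelSpec(("pH", "Hue", "SSC"), "X")
            )
            _, _, va = mr.calibrate_validate(
                cal, val, mr.ModelSpec(("pH", "Hue", "SSC"), "alpha")
            )
            wins += va.mrd <= vx.mrd
        assert wins > n_rep / 2
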