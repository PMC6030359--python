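import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import TRUE_VOLUME_OPT, make_plant_day
from nectarclim.models import (
    ModelDesignError,
    aic_select,
    fit_flowering_group_model,
    fit_quadratic_lmm,
    fit_time_group_interaction,
    fit_zinb_empty,
    r2_nakagawa,
)
from nectarclim.preprocess import build_trait_frame
from nectarclim.simulate import ExperimentDesign, SpeciesProfile, TraitCurve


def _quad_frame(rng, n_plants=10, n_temps=8, b=(0.4, 0.3, -0.5),
                plant_sd=0.3, resid_sd=0.3):
    temps = np.linspace(-1.5, 1.5, n_temps)
    rows = []
    for p in range(n_plants):
        u = rng.normal(0, plant_sd)
        for t in temps:
            y = b[0] + b[1] * t + b[2] * t**2 + u + rng.normal(0, resid_sd)
            rows.append((f"p{p}", "sp", "experimental", t, y))
    return pd.DataFrame(rows, columns=["plant_id", "species", "group", "temp_std", "value_std"])


class TestQuadraticLmm:
    def test_noiseless_exact(self):
        frame = _quad_frame(np.random.default_rng(0), plant_sd=0.0, resid_sd=0.0)
        fit = fit_quadratic_lmm(frame)
        assert fit.params["Intercept"] == pytest.approx(0.4, abs=1e-6)
        assert fit.params["temp"] == pytest.approx(0.3, abs=1e-6)
        assert fit.params["temp2"] == pytest.approx(-0.5, abs=1e-6)

    def test_balanced_no_plant_effect_equals_ols(self):
        # balanced design: mixed-model fixed effects coincide with OLS
        frame = _quad_frame(np.random.default_rng(1), plant_sd=0.0, resid_sd=0.4)
        fit = fit_quadratic_lmm(frame)
        X = np.column_stack(
            [np.ones(len(frame)), frame["temp_std"], frame["temp_std"] ** 2]
        )
        beta_ols, *_ = np.linalg.lstsq(X, frame["value_std"].to_numpy(), rcond=None)
        assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-8)

    def test_design_errors(self):
        frame = _quad_frame(np.random.default_rng(2))
        with pytest.raises(ModelDesignError):
            fit_quadratic_lmm(frame[frame["plant_id"] == "p0"])
        two_temps = frame[frame["temp_std"].isin(frame["temp_std"].unique()[:2])]
        with pytest.raises(ModelDesignError):
            fit_quadratic_lmm(two_temps)

    def test_vertex_recovery_simulation(self, default_profile, default_design):
        # scaled-down version of the acceptance-scale recovery study
        from nectarclim.optima import optimum_temperature

        errors = []
        for seed in range(40):
            table = make_plant_day(default_profile, default_design, seed)
            frame, meta = build_trait_frame(table, "mean_volume")
            fit = fit_quadratic_lmm(frame, meta)
            t_opt, _ = optimum_temperature(fit)
            errors.append(abs(t_opt - TRUE_VOLUME_OPT))
        assert np.median(errors) <= 0.5


class TestTimeGroupInteraction:
    def _both_groups_frame(self, profile, design, seed):
        table = make_plant_day(profile, design, seed, with_control=True)
        return build_trait_frame(table, "mean_volume", scope="pooled")

    def test_single_group_rejected(self, default_profile, default_design):
        table = make_plant_day(default_profile, default_design, 1)
        frame, meta = build_trait_frame(table, "mean_volume")
        with pytest.raises(ModelDesignError):
            fit_time_group_interaction(frame, meta)

    def test_duplicated_control_zero_interaction(self, default_profile, default_design):
        table = make_plant_day(default_profile, default_design, 1)
        dup = table.copy()
        dup["group"] = "control"
        dup["plant_id"] = dup["plant_id"] + "_ctl"
        both = pd.concat([table, dup], ignore_index=True)
        frame, meta = build_trait_frame(both, "mean_volume", scope="pooled")
        fit = fit_time_group_interaction(frame, meta)
        assert abs(fit.params["time:group"]) < 1e-8
        assert abs(fit.params["time2:group"]) < 1e-8

    def test_power_when_temperature_effect_present(self, default_profile, default_design):
        detected = 0
        n_reps = 60
        for seed in range(n_reps):
            frame, meta = self._both_groups_frame(default_profile, default_design, seed)
            fit = fit_time_group_interaction(frame, meta)
            if (
                fit.pvalues["time:group"] < 0.05
                or fit.pvalues["time2:group"] < 0.05
            ):
                detected += 1
        assert detected / n_reps > 0.8

    def test_combined_model_runs(self, default_profile, default_design):
        tables = []
        for name in ("a", "b"):
            profile = dataclasses.replace(default_profile, species_name=name)
            tables.append(make_plant_day(profile, default_design, 3, with_control=True))
        both = pd.concat(tables, ignore_index=True)
        frame, meta = build_trait_frame(both, "mean_volume", scope="pooled")
        fit = fit_time_group_interaction(frame, meta, combined=True)
        assert fit.converged
        assert "species" in fit.re_var and "plant" in fit.re_var


class TestFloweringGroupModel:
    def _two_group_table(self, early_opt, late_opt, seed, n_plants=10):
        design = ExperimentDesign(
            n_plants=n_plants, n_steps=8, start_day_temp=14, increment=3,
            light_hours=12,
        )
        tables = []
        for i, (month, opt) in enumerate(
            [(1, early_opt), (3, early_opt), (5, late_opt), (6, late_opt)]
        ):
            profile = SpeciesProfile(
                f"sp{i}", month,
                volume_curve=TraitCurve(2.0, opt, 10.0),
                concentration_curve=TraitCurve(35.0, opt, 18.0),
                flowers_curve=TraitCurve(60.0, opt, 14.0),
            )
            table = make_plant_day(profile, design, seed + 100 * i)
            table["flowering_group"] = "early" if month <= 4 else "late"
            tables.append(table)
        return pd.concat(tables, ignore_index=True)

    def test_interaction_sign_tracks_construction(self):
        hits = 0
        n_reps = 25
        for seed in range(n_reps):
            table = self._two_group_table(14.0, 28.0, seed)
            frame, meta = build_trait_frame(table, "mean_volume", scope="pooled")
            frame["flowering_group"] = table.loc[frame.index, "flowering_group"]
            fit = fit_flowering_group_model(frame, meta)
            # later-flowering group has the higher optimum: positive shift of
            # the vertex means positive linear interaction given b2 < 0
            if fit.params["temp:group"] > 0:
                hits += 1
        assert hits / n_reps > 0.95

    def test_label_swap_flips_interaction_sign(self):
        table = self._two_group_table(14.0, 28.0, 0)
        frame, meta = build_trait_frame(table, "mean_volume", scope="pooled")
        frame["flowering_group"] = table.loc[frame.index, "flowering_group"]
        fit = fit_flowering_group_model(frame, meta)
        swapped = frame.copy()
        swapped["flowering_group"] = np.where(
            frame["flowering_group"] == "early", "late", "early"
        )
        fit2 = fit_flowering_group_model(swapped, meta)
        assert fit2.params["temp:group"] == pytest.approx(
            -fit.params["temp:group"], rel=1e-4, abs=1e-6
        )
        assert fit2.params["temp2:group"] == pytest.approx(
            -fit.params["temp2:group"], rel=1e-4, abs=1e-6
        )

    def test_null_interaction_rate(self):
        rejections = 0
        n_reps = 30
        for seed in range(n_reps):
            table = self._two_group_table(21.0, 21.0, seed)
            frame, meta = build_trait_frame(table, "mean_volume", scope="pooled")
            frame["flowering_group"] = table.loc[frame.index, "flowering_group"]
            fit = fit_flowering_group_model(frame, meta)
            if fit.pvalues["temp:group"] < 0.05:
                rejections += 1
        # nominal-rate check at coarse resolution (30 reps)
        assert rejections / n_reps <= 0.2


class TestAicSelect:
    def _frame(self, rng, quadratic):
        b2 = -0.5 if quadratic else 0.0
        return _quad_frame(rng, b=(0.2, 0.4, b2), plant_sd=0.2, resid_sd=0.3)

    def test_identical_models_zero_delta(self):
        frame = self._frame(np.random.default_rng(3), True)
        sel = aic_select(frame)
        assert sel["delta_aic"] == pytest.approx(
            abs(sel["aic"]["linear"] - sel["aic"]["quadratic"])
        )

    def test_linear_truth_prefers_simple(self):
        wins = sum(
            aic_select(self._frame(np.random.default_rng(s), False))["chosen"] == "linear"
            for s in range(30)
        )
        assert wins / 30 > 0.8

    def test_quadratic_truth_prefers_quadratic(self):
        wins = sum(
            aic_select(self._frame(np.random.default_rng(s), True))["chosen"] == "quadratic"
            for s in range(30)
        )
        assert wins / 30 > 0.95


class TestR2Nakagawa:
    def test_no_random_variance_r2m_equals_r2c(self):
        frame = _quad_frame(np.random.default_rng(4), plant_sd=0.0, resid_sd=0.3)
        fit = fit_quadratic_lmm(frame)
        fit.re_var = {"plant": 0.0}
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(r2c)

    def test_null_model_r2m_zero(self):
        frame = _quad_frame(np.random.default_rng(5))
        fit = fit_quadratic_lmm(frame)
        fit.params[:] = [fit.params["Intercept"], 0.0, 0.0]
        fit.var_fixed = 0.0
        r2m, _ = r2_nakagawa(fit)
        assert r2m == 0.0

    def test_independent_recomputation(self):
        frame = _quad_frame(np.random.default_rng(6))
        fit = fit_quadratic_lmm(frame)
        X = np.column_stack(
            [np.ones(len(frame)), frame["temp_std"], frame["temp_std"] ** 2]
        )
        pred = X @ fit.params.to_numpy()
        var_f = float(np.var(pred, ddof=1))
        total = var_f + sum(fit.re_var.values()) + fit.resid_var
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(var_f / total, abs=1e-8)
        assert r2c == pytest.approx(
            (var_f + sum(fit.re_var.values())) / total, abs=1e-8
        )

    def test_ordering_invariant(self):
        frame = _quad_frame(np.random.default_rng(7))
        fit = fit_quadratic_lmm(frame)
        r2m, r2c = r2_nakagawa(fit)
        assert 0 <= r2m <= r2c <= 1


class TestZinb:
    @staticmethod
    def _nb_frame(rng, n=2000, pi=0.0, b=(0.5, 0.3, -0.4), k=3.0):
        x = rng.uniform(-1.5, 1.5, n)
        mu = np.exp(b[0] + b[1] * x + b[2] * x**2)
        y = rng.poisson(rng.gamma(k, mu / k)).astype(float)
        if pi > 0:
            y[rng.uniform(size=n) < pi] = 0
        return pd.DataFrame(
            {"n_empty": y, "temp_std": x, "plant_id": np.repeat(np.arange(n // 10), 10)}
        )

    def test_reduces_to_nb_without_zero_inflation(self):
        frame = self._nb_frame(np.random.default_rng(8))
        fit = fit_zinb_empty(frame)
        assert fit.zi_prob <= 0.02
        assert fit.params["temp"] == pytest.approx(0.3, abs=0.1)
        assert fit.params["temp2"] == pytest.approx(-0.4, abs=0.1)

    def test_matches_reference_implementation(self):
        # oracle: statsmodels' ZINB on well-behaved data
        import warnings

        from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

        frame = self._nb_frame(np.random.default_rng(9), pi=0.3)
        fit = fit_zinb_empty(frame)
        X = np.column_stack(
            [np.ones(len(frame)), frame["temp_std"], frame["temp_std"] ** 2]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = ZeroInflatedNegativeBinomialP(
                frame["n_empty"], X, exog_infl=np.ones((len(frame), 1)),
                inflation="logit", p=2,
            ).fit(disp=0, method="bfgs", maxiter=500)
        assert fit.loglike == pytest.approx(ref.llf, abs=1e-3)
        assert np.allclose(fit.params.to_numpy(), ref.params[1:4], atol=1e-3)

    def test_marginal_mean_identity(self):
        frame = self._nb_frame(np.random.default_rng(10), pi=0.25)
        fit = fit_zinb_empty(frame)
        mu = np.exp(
            fit.params["Intercept"]
            + fit.params["temp"] * frame["temp_std"]
            + fit.params["temp2"] * frame["temp_std"] ** 2
        )
        marginal = (1 - fit.zi_prob) * mu
        se = frame["n_empty"].std(ddof=1) / np.sqrt(len(frame))
        assert abs(marginal.mean() - frame["n_empty"].mean()) < 4 * se

    def test_nesting_loglik(self):
        # ZINB optimum cannot fall below the plain-NB fit it nests
        import warnings

        from statsmodels.discrete.discrete_model import NegativeBinomialP

        frame = self._nb_frame(np.random.default_rng(11), pi=0.2)
        fit = fit_zinb_empty(frame)
        X = np.column_stack(
            [np.ones(len(frame)), frame["temp_std"], frame["temp_std"] ** 2]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = NegativeBinomialP(frame["n_empty"], X, p=2).fit(disp=0, maxiter=200)
        assert fit.loglike >= nb.llf - 1e-6

    def test_u_shaped_empties_positive_quadratic(self, default_design):
        hits = 0
        n_reps = 25
        for seed in range(n_reps):
            profile = SpeciesProfile(
                "sp", 6, zero_inflation_base=0.1, zero_inflation_heat_slope=0.25
            )
            table = make_plant_day(profile, default_design, seed)
            frame, meta = build_trait_frame(table, "n_flowers")
            frame["n_empty"] = table.loc[frame.index, "n_empty"]
            fit = fit_zinb_empty(frame)
            if fit.params["temp2"] > 0:
                hits += 1
        assert hits / n_reps > 0.9

    def test_all_zero_saturated(self):
        frame = pd.DataFrame(
            {"n_empty": np.zeros(30), "temp_std": np.linspace(-1, 1, 30),
             "plant_id": np.repeat(np.arange(10), 3)}
        )
        fit = fit_zinb_empty(frame)
        assert fit.saturated
        assert fit.zi_prob == 1.0

    def test_random_intercept_variant(self):
        rng = np.random.default_rng(12)
        n_plants, n_obs = 30, 8
        u = rng.normal(0, 0.5, n_plants)
        rows = []
        for p in range(n_plants):
            x = np.linspace(-1.5, 1.5, n_obs)
            mu = np.exp(0.3 + 0.2 * x - 0.3 * x**2 + u[p])
            y = rng.poisson(mu)
            for xi, yi in zip(x, y):
                rows.append((f"p{p}", xi, float(yi)))
        frame = pd.DataFrame(rows, columns=["plant_id", "temp_std", "n_empty"])
        fit = fit_zinb_empty(frame, random_intercept=True)
        assert fit.random_intercept_sd is not None
        assert fit.random_intercept_sd == pytest.approx(0.5, abs=0.25)
        assert fit.params["temp2"] == pytest.approx(-0.3, abs=0.2)
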