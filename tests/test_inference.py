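"""Parameter recovery and contracts for the model battery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from invadiv import (
    ModelSpec,
    SpatialIndex,
    collinearity_screen,
    fit_presence_model,
    fit_severity_models,
    fit_strategy_model,
    rf_shap_importance,
    sensitivity_preinvasion,
    simulate_richness_change,
    summarize_fits,
)
from invadiv.errors import (
    ConvergenceError,
    InvalidArgumentError,
    SchemaError,
)
from invadiv.inference import relative_coefficient_change


def _coords(n, rng, spread=8.0):
    return rng.uniform(-spread, spread, n), rng.uniform(-spread, spread, n)


class TestCollinearityScreen:
    def test_duplicate_column_dropped_once(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=100)})
        df["b"] = df["a"]
        retained, report = collinearity_screen(df, always_keep=())
        assert retained == ["a"]
        assert len(report) == 1

    def test_independent_covariates_untouched(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(1000, 5)),
                          columns=list("abcde"))
        retained, report = collinearity_screen(df, always_keep=())
        assert retained == list("abcde")
        assert report.empty

    def test_keep_list_wins(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=500)
        soil = 0.9 * mat + 0.1 * rng.normal(size=500)
        df = pd.DataFrame({"mat": mat, "soil_ph": soil})
        retained, _ = collinearity_screen(df, threshold=0.7)
        assert retained == ["mat"]

    def test_non_numeric_is_schema_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": ["x", "y"]})
        with pytest.raises(SchemaError):
            collinearity_screen(df)


class TestPresenceModel:
    def _simulate(self, n=2000, beta=(-0.8, 0.5), seed=0, noise=None):
        rng = np.random.default_rng(seed)
        lat, lon = _coords(n, rng)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        eta = 0.3 + beta[0] * x1 + beta[1] * x2
        if noise is not None:
            eta = eta + noise
        y = (rng.random(n) < expit(eta)).astype(int)
        return (
            pd.DataFrame({"y": y, "x1": x1, "x2": x2}),
            SpatialIndex(lat, lon),
        )

    def test_recovers_coefficients_within_three_se(self):
        data, idx = self._simulate()
        spec = ModelSpec(response="y", family="binomial-logit",
                         predictors=["x1", "x2"])
        fit = fit_presence_model(data, spec, idx)
        assert abs(fit.params["x1"] - (-0.8)) < 3 * fit.bse["x1"]
        assert abs(fit.params["x2"] - 0.5) < 3 * fit.bse["x2"]
        assert "rac" in fit.params.index

    def test_constant_response_rejected(self):
        data, idx = self._simulate(n=100)
        data["y"] = 1
        spec = ModelSpec(response="y", family="binomial-logit",
                         predictors=["x1", "x2"])
        with pytest.raises(ConvergenceError):
            fit_presence_model(data, spec, idx)

    def test_rac_reduces_residual_morans_i(self):
        from invadiv.synthetic import gaussian_kernel_field
        from invadiv.rng import stream

        rng = np.random.default_rng(3)
        n = 800
        lat, lon = _coords(n, rng, spread=6.0)
        noise = 1.2 * gaussian_kernel_field(lat, lon, 250.0, stream(3, "f"))
        data, _ = self._simulate(n=n, seed=3, noise=noise)
        idx = SpatialIndex(lat, lon)
        spec = ModelSpec(response="y", family="binomial-logit",
                         predictors=["x1", "x2"])
        fit = fit_presence_model(data, spec, idx)
        assert (
            fit.extras["morans_i_stage2"]["i"]
            < fit.extras["morans_i_stage1"]["i"]
        )


class TestSeverityModels:
    def _simulate(self, n=2000, beta_div=-0.8, seed=0, phi=10.0, slope=0.6):
        rng = np.random.default_rng(seed)
        div = rng.normal(size=n)
        x = rng.normal(size=n)
        total = rng.integers(4, 30, size=n)
        p = expit(-1.0 + beta_div * div)
        nn = rng.binomial(total, p)
        mu = expit(-0.5 + slope * x)
        prop = rng.beta(mu * phi, (1 - mu) * phi)
        return pd.DataFrame(
            {"div": div, "x": x, "total": total, "nn": nn, "prop": prop}
        )

    def _specs(self):
        rich = ModelSpec(response="nn", family="binomial-counts",
                         predictors=["div"], trials="total")
        abund = ModelSpec(response="prop", family="beta-logit",
                          predictors=["x"])
        return rich, abund

    def test_binomial_recovery(self):
        data = self._simulate()
        rich, abund = self._specs()
        fit_r, _ = fit_severity_models(data, rich, abund)
        assert abs(fit_r.params["div"] - (-0.8)) < 3 * fit_r.bse["div"]

    def test_beta_regression_recovery(self):
        data = self._simulate()
        rich, abund = self._specs()
        _, fit_a = fit_severity_models(data, rich, abund)
        assert abs(fit_a.params["x"] - 0.6) < 3 * fit_a.bse["x"]

    def test_boundary_proportions_squeezed(self):
        data = self._simulate(n=500)
        data.loc[:4, "prop"] = 1.0
        rich, abund = self._specs()
        _, fit_a = fit_severity_models(data, rich, abund)
        assert fit_a.extras["n_squeezed"] == 5

    def test_degenerate_abundance_rejected(self):
        data = self._simulate(n=200)
        data["prop"] = 0.4
        rich, abund = self._specs()
        with pytest.raises(ConvergenceError):
            fit_severity_models(data, rich, abund)

    def test_zero_denominator_rejected(self):
        data = self._simulate(n=100)
        data.loc[0, "total"] = 0
        rich, abund = self._specs()
        with pytest.raises(InvalidArgumentError):
            fit_severity_models(data, rich, abund)

    def test_standardization_invariance(self):
        data = self._simulate()
        rich, abund = self._specs()
        fit1, _ = fit_severity_models(data, rich, abund)
        data2 = data.assign(div=data["div"] * 2.0)
        fit2, _ = fit_severity_models(data2, rich, abund)
        assert fit1.params["div"] == pytest.approx(
            fit2.params["div"], abs=1e-8
        )


def _strategy_data(n=2000, gamma=-0.3, interact=0.0, seed=0, noise_sd=0.2):
    rng = np.random.default_rng(seed)
    mat = rng.normal(15.0, 5.0, n)
    map_mm = rng.normal(1200.0, 250.0, n)
    ports = rng.lognormal(4.0, 1.0, n)
    z = lambda v: (v - v.mean()) / v.std()
    y = (
        0.1
        + gamma * z(mat) ** 2
        + 0.05 * z(map_mm)
        + interact * z(mat) * z(ports)
        + rng.normal(0, noise_sd, n)
    )
    return pd.DataFrame(
        {"strategy": y, "mat": mat, "map": map_mm, "dist_ports_km": ports}
    )


def _strategy_spec():
    return ModelSpec(
        response="strategy", family="gaussian",
        predictors=["mat", "map", "dist_ports_km"],
        quadratic=["mat"],
        interactions=[("mat", "map"), ("mat", "dist_ports_km"),
                      ("map", "dist_ports_km")],
    )


class TestStrategyModel:
    def test_quadratic_temperature_recovered(self):
        fit = fit_strategy_model(_strategy_data(), _strategy_spec())
        assert fit.params["mat_sq"] < 0
        assert fit.pvalues["mat_sq"] < 0.05

    def test_planted_interaction_survives_pruning(self):
        fit = fit_strategy_model(
            _strategy_data(interact=0.15), _strategy_spec()
        )
        assert "mat:dist_ports_km" in fit.extras["final_interactions"]
        assert fit.params["mat:dist_ports_km"] > 0

    def test_final_model_has_no_nonsignificant_interaction(self):
        for seed in range(5):
            fit = fit_strategy_model(
                _strategy_data(seed=seed), _strategy_spec()
            )
            for term in fit.extras["final_interactions"]:
                assert fit.pvalues[term] < 0.05

    def test_main_effects_never_removed(self):
        fit = fit_strategy_model(_strategy_data(), _strategy_spec())
        for term in ("mat", "map", "dist_ports_km", "mat_sq"):
            assert term in fit.params.index


class TestRandomForestShap:
    def _data(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = x1 + 0.1 * rng.normal(size=n)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "noise": noise})

    def test_dominant_signal_ranks_first(self):
        data = self._data()
        res = rf_shap_importance(
            data, "y", ["x1", "x2", "noise"], seed=0,
            n_estimators=100, n_simulations=10,
        )
        assert res.importance.iloc[0]["variable"] == "x1"

    def test_pure_noise_ranks_last(self):
        data = self._data(seed=1)
        data["y"] = data["x1"] + 0.5 * data["x2"] ** 2
        res = rf_shap_importance(
            data, "y", ["x1", "x2", "noise"], seed=1,
            n_estimators=100, n_simulations=10,
        )
        assert res.importance.iloc[-1]["variable"] == "noise"

    def test_deterministic_under_seed(self):
        data = self._data(seed=2)
        kwargs = dict(seed=5, n_estimators=50, n_simulations=5)
        a = rf_shap_importance(data, "y", ["x1", "x2", "noise"], **kwargs)
        b = rf_shap_importance(data, "y", ["x1", "x2", "noise"], **kwargs)
        pd.testing.assert_frame_equal(a.importance, b.importance)

    def test_additivity_gap_reported(self):
        data = self._data(seed=3)
        res = rf_shap_importance(
            data, "y", ["x1", "x2"], seed=0, n_estimators=50,
            n_simulations=20, shap_rows=50,
        )
        spread = float(data["y"].std())
        assert res.additivity_gap < spread  # coarse sanity of the diagnostic

    def test_too_few_predictors_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rf_shap_importance(self._data(), "y", ["x1"], seed=0)


class TestSensitivity:
    def _severity(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        richness = rng.integers(4, 30, n)
        total = richness + rng.integers(1, 4, n)
        p = expit(-0.5 - 0.08 * (richness - richness.mean()))
        nn = np.maximum(rng.binomial(total, p), 1)
        return pd.DataFrame(
            {
                "native_richness": richness,
                "total_species": total,
                "nn_species": nn,
                "presence": True,
                "mat": rng.normal(15, 5, n),
                "map": rng.normal(1200, 300, n),
            }
        )

    def _spec(self):
        return ModelSpec(
            response="nn_species", family="binomial-counts",
            predictors=["native_richness", "mat", "map"],
            trials="total_species",
        )

    def test_planted_c_recovered(self):
        two_census = simulate_richness_change(2000, c=-0.05, noise_sd=0.05,
                                              seed=0)
        res = sensitivity_preinvasion(
            two_census, self._severity(), self._spec(),
            change_covariates=("mat", "map"),
        )
        se = (res.c_hi - res.c) / 1.96
        assert abs(res.c - (-0.05)) < 3 * se

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")  # exact-zero residuals
    def test_zero_effect_means_zero_change(self):
        two_census = simulate_richness_change(500, c=0.0, seed=1)
        two_census["pct_change"] = 0.0  # exact null
        res = sensitivity_preinvasion(
            two_census, self._severity(), self._spec()
        )
        assert res.c == pytest.approx(0.0, abs=1e-12)
        assert res.relative_change["c"] == pytest.approx(0.0, abs=1e-9)

    def test_update_formula(self):
        # c = -0.05 on observed richness 20 restores 21 species
        assert 20 * (1 - (-0.05)) == pytest.approx(21.0)

    def test_relative_change_hand_value(self):
        assert relative_coefficient_change(-0.80, -0.75) == pytest.approx(
            0.0625
        )

    def test_no_invaded_two_census_rejected(self):
        two_census = simulate_richness_change(100, seed=2)
        two_census["invaded"] = 0
        with pytest.raises(InvalidArgumentError):
            sensitivity_preinvasion(
                two_census, self._severity(), self._spec()
            )


class TestSummaries:
    def test_long_table_shape_and_round_trip(self, tmp_path):
        data = _strategy_data(n=500)
        fit = fit_strategy_model(data, _strategy_spec())
        table = summarize_fits([fit, fit])
        assert len(table) == 2 * len(fit.params)
        path = tmp_path / "coef.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.12g")
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(
            back["estimate"], table["estimate"], rtol=1e-11
        )
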