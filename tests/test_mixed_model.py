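"""REML engine: standardization, likelihood correctness, reductions,
invariances, contrasts and counterfactuals."""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import toy_frame
from xylemkit.mixed_model import (
    ModelSpec,
    VarianceParams,
    counterfactual_predict,
    fit_reml,
    p_stars,
    prediction_table,
    restricted_loglik,
    site_contrasts,
    standardize,
)
from xylemkit.pipeline import fit_trait_model
from xylemkit.validation import dense_restricted_loglik, gls_ar1_beta, ols_beta

TOY_CLIMATE = ("summer_temp", "spring_prcp")


def toy_spec(**kw):
    base = dict(
        response="la",
        log_transform=False,
        climate=TOY_CLIMATE,
        random_terms=("intercept", "h"),
        ar1=True,
        tree_weights=True,
        interactions=False,
    )
    base.update(kw)
    return ModelSpec(**base)


@pytest.fixture(scope="module")
def small_fit(model_data):
    return fit_trait_model(model_data, "la", "ew", seed=0)


class TestStandardize:
    def test_zero_mean_unit_sd(self, model_data):
        spec = ModelSpec(response="cwt", portion="ew")
        sub = model_data[model_data.portion == "ew"].reset_index(drop=True)
        std, record = standardize(sub, spec)
        for col in ["y", "h", "h2", *spec.climate]:
            assert abs(std[col].mean()) < 1e-12
            assert std[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert "cwt" in record.log_vars  # CWT modelled on the log scale

    def test_round_trip(self, model_data):
        spec = ModelSpec(response="tb2", portion="lw")
        sub = model_data[model_data.portion == "lw"].reset_index(drop=True)
        std, record = standardize(sub, spec)
        back = record.inverse_value("tb2", std["y"].to_numpy())
        np.testing.assert_allclose(back, sub["tb2"].to_numpy(), rtol=1e-12)

    def test_known_zscore(self):
        record_vals = pd.Series([3.0, 5.0, 7.0])  # mean 5, sd 2 (ddof=1)
        df = pd.DataFrame(
            {
                "la": record_vals,
                "height_m": record_vals,
                "summer_temp": [1.0, 2.0, 3.0],
            }
        )
        spec = ModelSpec(
            response="la", log_transform=False, climate=("summer_temp",)
        )
        _, record = standardize(df, spec)
        assert record.transform_value("h", 9.0) == pytest.approx(2.0)

    def test_zero_variance_named(self):
        df = pd.DataFrame(
            {"la": [1.0, 2.0, 3.0], "height_m": [4.0, 4.0, 4.0], "x": [1.0, 2.0, 1.5]}
        )
        spec = ModelSpec(response="la", log_transform=False, climate=("x",))
        with pytest.raises(ValueError, match="'h'"):
            standardize(df, spec)

    def test_nonpositive_log_response_rejected(self):
        df = pd.DataFrame(
            {"tb2": [0.5, -0.1, 0.2], "height_m": [1.0, 2.0, 3.0], "x": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="log"):
            standardize(df, ModelSpec(response="tb2", climate=("x",)))


class TestReductions:
    def test_ols_degenerate_case(self):
        rng = np.random.default_rng(0)
        df = toy_frame(rng, n_trees=4, n_years=6)
        spec = toy_spec(random_terms=(), ar1=False, tree_weights=False)
        fit = fit_reml(df, spec)
        np.testing.assert_allclose(
            fit.coef_table["estimate"].to_numpy(), ols_beta(df, spec), atol=1e-6
        )

    def test_gls_ar1_closed_form(self):
        rng = np.random.default_rng(1)
        df = toy_frame(rng, n_trees=5, n_years=8)
        spec = toy_spec(random_terms=(), ar1=True, tree_weights=False)
        fit = fit_reml(df, spec)
        expected = gls_ar1_beta(df, spec, fit.params.phi)
        np.testing.assert_allclose(
            fit.coef_table["estimate"].to_numpy(), expected, atol=1e-8
        )


class TestLikelihood:
    @pytest.mark.parametrize("gaps", [False, True])
    def test_matches_dense_oracle_at_random_points(self, gaps):
        """Structured per-tree evaluation equals the explicitly assembled
        N x N multivariate-normal restricted likelihood."""
        rng = np.random.default_rng(11)
        df = toy_frame(rng, n_trees=4, n_years=7, year_gaps=gaps)
        spec = toy_spec(random_terms=("intercept", "h", "h2"))
        n_trees = df["tree_id"].nunique()
        for _ in range(20):
            params = VarianceParams(
                re_sd=rng.uniform(0.01, 1.0, 3),
                phi=rng.uniform(-0.85, 0.85),
                weights=np.concatenate([[1.0], rng.uniform(0.4, 2.5, n_trees - 1)]),
                sigma=rng.uniform(0.3, 2.0),
            )
            engine = restricted_loglik(df, spec, params)
            dense = dense_restricted_loglik(df, spec, params)
            assert engine == pytest.approx(dense, abs=1e-8)

    def test_profiled_optimum_matches_dense(self):
        rng = np.random.default_rng(12)
        df = toy_frame(rng, n_trees=3, n_years=6)
        spec = toy_spec(random_terms=("intercept",))
        fit = fit_reml(df, spec)
        dense = dense_restricted_loglik(df, spec, fit.params)
        assert fit.loglik == pytest.approx(dense, abs=1e-6)

    def test_tree_permutation_invariance(self):
        rng = np.random.default_rng(13)
        df = toy_frame(rng, n_trees=4, n_years=6)
        spec = toy_spec()
        fit1 = fit_reml(df, spec)
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        fit2 = fit_reml(shuffled, spec)
        np.testing.assert_allclose(
            fit1.coef_table["estimate"], fit2.coef_table["estimate"], atol=1e-6
        )
        assert fit1.params.phi == pytest.approx(fit2.params.phi, abs=1e-6)

    def test_year_shift_invariance(self):
        """Only year gaps enter the AR1 correlation, not absolute labels."""
        rng = np.random.default_rng(14)
        df = toy_frame(rng, n_trees=3, n_years=6)
        spec = toy_spec()
        params = VarianceParams(
            re_sd=np.array([0.5, 0.2]),
            phi=0.45,
            weights=np.array([1.0, 1.3, 0.8]),
            sigma=0.9,
        )
        shifted = df.assign(year=df["year"] + 137)
        assert restricted_loglik(df, spec, params) == pytest.approx(
            restricted_loglik(shifted, spec, params), abs=1e-10
        )

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(15)
        df = toy_frame(rng, n_trees=3, n_years=5)
        df["spring_prcp"] = df["summer_temp"]  # collinear
        with pytest.raises(ValueError, match="singular"):
            fit_reml(df, toy_spec())

    def test_boundary_fit_flagged_not_error(self):
        """Data with no tree-level heterogeneity drives the random-effect
        variance to the boundary; the fit reports it and still returns."""
        rng = np.random.default_rng(16)
        df = toy_frame(rng, n_trees=4, n_years=8)
        # pure iid noise response
        df["y"] = rng.normal(size=len(df))
        fit = fit_reml(df, toy_spec(ar1=False, tree_weights=False))
        assert fit.boundary or fit.params.re_sd.max() < 0.5


class TestInference:
    def test_significance_stars_follow_thresholds(self):
        assert p_stars(0.2) == ""
        assert p_stars(0.04) == "*"
        assert p_stars(0.009) == "**"
        assert p_stars(0.0009) == "***"

    def test_between_tree_terms_get_outer_df(self, small_fit):
        tab = small_fit.coef_table.set_index("term")
        assert tab.loc["site[C-D]", "df"] == small_fit.df_outer
        assert tab.loc["h", "df"] == small_fit.df_inner
        assert small_fit.df_outer == small_fit.n_trees - 3


class TestContrasts:
    def test_three_groups_three_pairs(self, small_fit):
        table, letters = site_contrasts(small_fit)
        assert len(table) == 3
        assert set(letters) == {"W-D", "C-D", "C-M"}
        assert table["p_adjusted"].between(0, 1).all()

    def test_null_site_effects_share_a_letter(self):
        rng = np.random.default_rng(17)
        df = toy_frame(rng, n_trees=6, n_years=8)
        df["y"] = rng.normal(size=len(df))
        fit = fit_reml(df, toy_spec(random_terms=(), tree_weights=False))
        # force exactly-zero site effects: adjusted p must be exactly 1
        mask = fit.coef_table["term"].str.startswith("site[")
        fit.coef_table.loc[mask, "estimate"] = 0.0
        table, letters = site_contrasts(fit)
        np.testing.assert_allclose(table["p_adjusted"], 1.0)
        assert len(set(letters.values())) == 1

    def test_injected_offset_recovered_and_separated(self):
        rng = np.random.default_rng(18)
        df = toy_frame(rng, n_trees=9, n_years=10)
        delta = 3.0
        df["y"] = rng.normal(0, 0.4, len(df)) + delta * (df["site"] == "S1")
        fit = fit_reml(df, toy_spec(random_terms=(), tree_weights=False, ar1=False))
        table, letters = site_contrasts(fit)
        pair = table[(table.site_a == "S0") & (table.site_b == "S1")].iloc[0]
        assert pair["estimate"] == pytest.approx(-delta, abs=0.5)
        assert letters["S0"] != letters["S1"]
        assert letters["S0"] == letters["S2"]


class TestCounterfactuals:
    def test_height_hold_identity(self, small_fit):
        """Full minus held-at-mean predictions equal exactly the height
        terms' fixed + random contributions."""
        fit = small_fit
        X = fit._X
        terms = fit._terms
        beta = fit.coef_table["estimate"].to_numpy()
        contrib = (
            X[:, terms.index("h")] * beta[terms.index("h")]
            + X[:, terms.index("h2")] * beta[terms.index("h2")]
        )
        b = fit.random_effects
        tree_ids = fit.data["tree_id"].astype(str).to_numpy()
        zt = list(fit._z_terms)
        if "h" in zt:
            contrib += fit._Z[:, zt.index("h")] * b.loc[tree_ids, "h"].to_numpy()
        if "h2" in zt:
            contrib += fit._Z[:, zt.index("h2")] * b.loc[tree_ids, "h2"].to_numpy()
        cf = counterfactual_predict(fit, "height")
        np.testing.assert_allclose(
            fit.fitted_conditional - cf, contrib, atol=1e-10
        )

    def test_null_held_variable_changes_nothing(self):
        rng = np.random.default_rng(19)
        df = toy_frame(rng, n_trees=4, n_years=8)
        df["y"] = 2.0 + 0.8 * df["summer_temp"] + rng.normal(0, 0.1, len(df))
        spec = toy_spec(random_terms=("intercept",), tree_weights=False, ar1=False)
        fit = fit_reml(df, spec)
        cf = counterfactual_predict(fit, "summer_temperature")
        # no height signal: holding height leaves predictions unchanged
        cf_h = counterfactual_predict(fit, "height")
        diff_h = np.abs(fit.fitted_conditional - cf_h).max()
        assert diff_h < 0.2  # only the (near-zero) estimated height terms move
        # holding summer temperature removes the injected signal
        assert np.std(cf) < np.std(fit.fitted_conditional)

    def test_unknown_hold_rejected(self, small_fit):
        with pytest.raises(ValueError, match="unknown hold"):
            counterfactual_predict(small_fit, "winter_moonlight")

    def test_prediction_table_alignment(self, small_fit):
        pt = prediction_table(small_fit)
        assert len(pt) == small_fit.n_obs
        assert {"observed", "fitted", "cf_height", "cf_summer_temp"} <= set(
            pt.columns
        )
        np.testing.assert_allclose(
            pt["observed"], small_fit.data["y"], atol=1e-12
        )
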