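"""Validation studies for the pipeline.

Self-contained experiments that exercise the package end to end: dense-
matrix likelihood sweeps, degenerate-reduction checks, brute-force oracles
for the deterministic stages, allometry recovery, counterfactual identities
and the replicated parameter-recovery / headline-pattern study.  Each
returns plain numbers so callers (tests, scripts) can assert or report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from xylemkit.climate_season import SEASON_MONTHS, aggregate_seasons
from xylemkit.mixed_model import (
    ModelSpec,
    VarianceParams,
    counterfactual_predict,
    fit_reml,
    restricted_loglik,
)
from xylemkit.pipeline import replicate_coefficient_table, simulate_and_fit
from xylemkit.ring_series import (
    IMPUTE_WINDOW,
    RingSeries,
    impute_missing_rings,
    interpolate_height,
    reconstruct_dbh,
)
from xylemkit.synthetic import SyntheticConfig, WeibullParams, default_truth
from xylemkit.validation import dense_restricted_loglik, gls_ar1_beta, ols_beta
from xylemkit.xylem_traits import (
    anatomical_density,
    conduit_reinforcement,
    morks_index,
)

TOY_CLIMATE = ("summer_temp", "spring_prcp")

#: models fitted in the replicated study and the sign/significance pattern
#: each must display (term, expected sign)
PATTERN_MODELS = (("la", "ew"), ("tb2", "ew"), ("cwt", "lw"), ("den", "lw"))
PATTERN_CHECKS = {
    "la_ew": (("h", +1),),
    "tb2_ew": (("h", -1),),
    "cwt_lw": (
        ("site[C-D]:summer_temp", +1),
        ("site[C-M]:summer_temp", +1),
    ),
    "den_lw": (
        ("site[C-D]:summer_temp", +1),
        ("site[C-M]:summer_temp", +1),
    ),
}


def _random_instance(rng, max_trees=5, max_years=8):
    """A small random mixed-model frame with arbitrary predictors."""
    n_trees = int(rng.integers(3, max_trees + 1))
    n_years = int(rng.integers(4, max_years + 1))
    rows = []
    for i in range(n_trees):
        years = np.arange(2000, 2000 + n_years)
        if n_years > 4 and rng.random() < 0.5:
            years = np.delete(years, rng.integers(1, n_years - 1))
        h = np.sort(rng.normal(0, 1, len(years)))
        for t, y in enumerate(years):
            row = {
                "tree_id": f"T{i}",
                "year": int(y),
                "site": f"S{i % 3}",
                "h": h[t],
                "h2": h[t] ** 2 - 1.0,
            }
            for c in TOY_CLIMATE:
                row[c] = rng.normal()
            rows.append(row)
    df = pd.DataFrame(rows)
    df["y"] = rng.normal(size=len(df))
    spec = ModelSpec(
        response="la",
        log_transform=False,
        climate=TOY_CLIMATE,
        random_terms=("intercept", "h", "h2"),
        ar1=True,
        tree_weights=True,
        interactions=False,
    )
    return df, spec


def dense_oracle_sweep(seed: int, n_instances: int = 20, points: int = 3) -> float:
    """Max |engine - dense oracle| restricted log-likelihood difference over
    random small instances and random variance-parameter points."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        df, spec = _random_instance(rng)
        n_trees = df["tree_id"].nunique()
        for _ in range(points):
            params = VarianceParams(
                re_sd=rng.uniform(0.01, 1.0, 3),
                phi=rng.uniform(-0.85, 0.85),
                weights=np.concatenate(
                    [[1.0], rng.uniform(0.4, 2.5, n_trees - 1)]
                ),
                sigma=rng.uniform(0.3, 2.0),
            )
            diff = abs(
                restricted_loglik(df, spec, params)
                - dense_restricted_loglik(df, spec, params)
            )
            worst = max(worst, diff)
    return worst


def reduction_checks(seed: int) -> dict:
    """Fixed effects under degenerate covariance match closed forms."""
    rng = np.random.default_rng(seed)
    df, spec0 = _random_instance(rng, max_trees=5, max_years=8)
    ols_spec = ModelSpec(
        **{**spec0.__dict__, "random_terms": (), "ar1": False, "tree_weights": False}
    )
    fit = fit_reml(df, ols_spec)
    ols_diff = float(
        np.abs(fit.coef_table["estimate"].to_numpy() - ols_beta(df, ols_spec)).max()
    )
    gls_spec = ModelSpec(
        **{**spec0.__dict__, "random_terms": (), "ar1": True, "tree_weights": False}
    )
    fit2 = fit_reml(df, gls_spec)
    gls_diff = float(
        np.abs(
            fit2.coef_table["estimate"].to_numpy()
            - gls_ar1_beta(df, gls_spec, fit2.params.phi)
        ).max()
    )
    return {"ols": ols_diff, "gls_ar1": gls_diff}


# ---------------------------------------------------------------------------
# deterministic-stage oracles (independent brute-force reimplementations)
# ---------------------------------------------------------------------------


def _oracle_impute(rw):
    out = np.asarray(rw, dtype=float).copy()
    src = np.asarray(rw, dtype=float)
    for i in range(src.size):
        if np.isnan(src[i]):
            vals = [
                src[j]
                for j in range(max(0, i - IMPUTE_WINDOW), min(src.size, i + IMPUTE_WINDOW + 1))
                if j != i and not np.isnan(src[j])
            ]
            out[i] = np.mean(vals)
    return out


def deterministic_stage_checks(seed: int, n_cases: int = 200) -> float:
    """Max absolute deviation of each deterministic stage from a
    brute-force oracle over random inputs (single worst value)."""
    rng = np.random.default_rng(seed)
    worst = 0.0

    for _ in range(n_cases // 4):
        n = int(rng.integers(5, 60))
        rw = rng.uniform(0.05, 5.0, n)
        gaps = rng.random(n) < 0.15
        gaps[0] = gaps[-1] = False
        rw_obs = rw.copy()
        rw_obs[gaps] = np.nan
        series = RingSeries(
            tree_id="T",
            years=np.arange(1950, 1950 + n),
            rw_mm=rw_obs,
            coring_height_m=1.0,
            # generous allowance: imputed widths may exceed the deleted ones
            sampling_dbh_cm=2 * (rw.sum() + 5.0 * gaps.sum()) / 10 + 1.0,
            sampling_height_m=rng.uniform(2.0, 12.0),
        )
        oracle = _oracle_impute(rw_obs)
        if np.isnan(oracle).any():
            continue
        filled = impute_missing_rings(series)
        worst = max(worst, float(np.abs(filled.rw_mm - oracle).max()))

        dbh = reconstruct_dbh(filled)
        # oracle: explicit backward recursion
        dbh_o = np.empty(n)
        dbh_o[-1] = series.sampling_dbh_cm
        for k in range(n - 2, -1, -1):
            dbh_o[k] = dbh_o[k + 1] - 2 * filled.rw_mm[k + 1] / 10.0
        worst = max(worst, float(np.abs(dbh - dbh_o).max()))

        traj = interpolate_height(filled, dbh)
        a = (series.sampling_height_m - series.coring_height_m) / series.sampling_dbh_cm
        h_o = series.coring_height_m + a * dbh_o
        worst = max(worst, float(np.abs(traj.height_m - h_o).max()))

    # per-cell traits
    n = n_cases
    cwt_rad = rng.uniform(0.3, 8.0, n)
    cwt_tan = rng.uniform(0.3, 8.0, n)
    ld_rad = rng.uniform(3.0, 45.0, n)
    wl_rad = rng.uniform(3.0, 45.0, n)
    wl_tan = rng.uniform(3.0, 45.0, n)
    la = rng.uniform(20.0, 1500.0, n)
    cwa = rng.uniform(20.0, 900.0, n)
    mi, portion = morks_index(cwt_rad, ld_rad)
    tb2 = conduit_reinforcement(cwt_rad, cwt_tan, wl_rad, wl_tan)
    den = anatomical_density(cwa, la)
    for k in range(n):
        mi_o = 4.0 * cwt_rad[k] / ld_rad[k]
        worst = max(worst, abs(mi[k] - mi_o))
        if (portion[k] == "lw") != (mi_o >= 1.0):
            worst = max(worst, 1.0)
        if cwt_rad[k] <= cwt_tan[k]:
            tb2_o = (2 * cwt_rad[k] / wl_rad[k]) ** 2
        else:
            tb2_o = (2 * cwt_tan[k] / wl_tan[k]) ** 2
        worst = max(worst, abs(tb2[k] - tb2_o))
        worst = max(worst, abs(den[k] - cwa[k] / (cwa[k] + la[k])))

    # seasonal aggregation against a month-picker oracle
    months = []
    for y in range(1999, 2005):
        for m in range(1, 13):
            months.append(
                {
                    "site": "A",
                    "year": y,
                    "month": m,
                    "tmean_c": float(rng.normal()),
                    "prcp_mm": float(rng.uniform(0, 60)),
                }
            )
    monthly = pd.DataFrame(months)
    idx = {
        (r.year, r.month): (r.tmean_c, r.prcp_mm) for r in monthly.itertuples()
    }
    out = aggregate_seasons(monthly)
    for _, row in out.iterrows():
        for season, mons in SEASON_MONTHS.items():
            keys = [(int(row["year"]) + off, m) for off, m in mons]
            t_o = np.mean([idx[k][0] for k in keys])
            p_o = np.sum([idx[k][1] for k in keys])
            worst = max(worst, abs(row[f"{season}_temp"] - t_o))
            worst = max(worst, abs(row[f"{season}_prcp"] - p_o))
    return worst


def allometry_checks(seed: int) -> dict:
    """Noise-free height-law recovery and the stationary regional curve."""
    from xylemkit.allometry import fit_regional_curve, fit_weibull

    rng = np.random.default_rng(seed)
    true = WeibullParams(
        h_max=rng.uniform(10, 20), a=-rng.uniform(1.5, 3.0), b=rng.uniform(0.05, 0.3)
    )
    dbh = np.linspace(0.5, 15.0, 40)
    fit = fit_weibull(dbh, true.height(dbh))
    rel = np.abs(
        np.array(
            [
                fit.h_max / true.h_max - 1,
                fit.a / true.a - 1,
                fit.b / true.b - 1,
            ]
        )
    ).max()

    rw = rng.uniform(0.3, 2.5)
    tab = pd.DataFrame({"cambial_age": np.tile(np.arange(1, 41), 3), "rw_mm": rw})
    curve = fit_regional_curve(tab)
    flat_err = float(np.abs(curve.rw_mm - rw).max())
    return {"weibull_max_rel_err": float(rel), "stationary_curve_err": flat_err}


def counterfactual_checks(seed: int) -> dict:
    """Held-variable identity and flattening under single-driver truth."""
    truth = default_truth()
    for key, tt in truth.traits.items():
        tt.beta_height = 0.0
        tt.beta_height2 = 0.0
        tt.site_offsets = {}
        tt.beta_climate = {}
        tt.beta_site_climate = {}
    truth.traits["la_ew"].beta_climate = {"summer_temp": 80.0}
    truth.re_sd_h = 0.0
    truth.re_sd_h2 = 0.0
    truth.re_sd_intercept = 0.5
    truth.phi = 0.2
    config = SyntheticConfig(
        truth=truth, anatomy_years=40, age_range=(50, 60), missing_ring_prob=0.0
    )
    fit, _ = simulate_and_fit(seed, config=config, trait="la", portion="ew")

    # identity: full - held predictions == held terms' contribution
    terms = fit._terms
    beta = fit.coef_table["estimate"].to_numpy()
    X = fit._X
    contrib = (
        X[:, terms.index("h")] * beta[terms.index("h")]
        + X[:, terms.index("h2")] * beta[terms.index("h2")]
    )
    zt = list(fit._z_terms)
    tree_ids = fit.data["tree_id"].astype(str).to_numpy()
    for name in ("h", "h2"):
        if name in zt:
            contrib += (
                fit._Z[:, zt.index(name)]
                * fit.random_effects.loc[tree_ids, name].to_numpy()
            )
    cf_h = counterfactual_predict(fit, "height")
    identity_err = float(np.abs(fit.fitted_conditional - cf_h - contrib).max())

    # flattening: holding the only signal-carrying driver leaves just the
    # intercept + site + tree structure
    cf_t = counterfactual_predict(fit, "summer_temperature")
    df = fit.data.assign(cf=cf_t, full=fit.fitted_conditional)
    within_tree_sd = df.groupby("tree_id")["cf"].transform(lambda x: x - x.mean())
    flatten_ratio = float(within_tree_sd.std() / df["full"].std())
    return {"identity_max_abs_err": identity_err, "flatten_ratio": flatten_ratio}


def recovery_and_pattern_study(n_replicates: int, seed: int) -> dict:
    """Replicated generate+fit study at the full design size.

    Returns the long coefficient table plus headline metrics: bias of the
    earlywood lumen-area height coefficient (in Monte-Carlo SEs), its Wald
    CI coverage, the pooled type-I error over truly-null coefficients, and
    the fraction of replicates reproducing the injected sign/significance
    pattern.
    """
    long = replicate_coefficient_table(
        n_replicates, seed, models=PATTERN_MODELS
    )
    la_h = long[(long.model == "la_ew") & (long.term == "h")]
    bias = la_h["estimate"].mean() - la_h["truth"].iloc[0]
    mc_se = la_h["estimate"].std(ddof=1) / np.sqrt(len(la_h))
    coverage = la_h["covered"].mean()

    nulls = long[(long.model == "la_ew") & (long.truth == 0.0)]
    type1 = nulls["rejected"].mean()

    ok = 0
    for rep, grp in long.groupby("replicate"):
        good = True
        for model, checks in PATTERN_CHECKS.items():
            sub = grp[grp.model == model].set_index("term")
            for term, sign in checks:
                row = sub.loc[term]
                if np.sign(row["estimate"]) != sign or not row["rejected"]:
                    good = False
        ok += good
    return {
        "long": long,
        "n_replicates": n_replicates,
        "height_bias": float(bias),
        "height_mc_se": float(mc_se),
        "height_bias_z": float(abs(bias) / mc_se),
        "height_coverage": float(coverage),
        "type1_error": float(type1),
        "n_null_tests": int(len(nulls)),
        "pattern_match_rate": ok / n_replicates,
    }
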