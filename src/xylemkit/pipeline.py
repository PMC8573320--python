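"""End-to-end orchestration: generate/load -> reconstruct -> derive ->
aggregate -> fit -> contrast/predict, plus the parameter-recovery harness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from xylemkit.allometry import fit_weibull
from xylemkit.climate_season import aggregate_seasons
from xylemkit.io import read_cells, read_climate, read_trees, series_from_long
from xylemkit.mixed_model import (
    ModelSpec,
    MixedModelFit,
    PORTIONS,
    TRAITS,
    fit_reml,
    prediction_table,
    site_contrasts,
    standardize,
)
from xylemkit.ring_series import reconstruct_heights
from xylemkit.synthetic import SyntheticConfig, TraitTruth, generate_dataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dataset assembly and per-trait fitting
# ---------------------------------------------------------------------------


def assemble_model_data(
    chronology: pd.DataFrame,
    heights: pd.DataFrame,
    seasonal: pd.DataFrame,
    trees: pd.DataFrame,
) -> pd.DataFrame:
    """Merge trait chronologies with heights, site labels and seasonal
    climate into one modelling frame (tree x year x portion rows)."""
    df = chronology.merge(heights, on=["tree_id", "year"], how="inner")
    df = df.merge(trees[["tree_id", "site"]], on="tree_id", how="left")
    df = df.merge(seasonal, on=["site", "year"], how="inner")
    if df["site"].isna().any():
        raise ValueError("trees missing site metadata")
    return df


def fit_trait_model(
    data: pd.DataFrame,
    trait: str,
    portion: str,
    *,
    seed: int = 0,
    **spec_kw,
) -> MixedModelFit:
    """Standardize and fit one trait x ring-portion mixed model."""
    sub = data[data["portion"] == portion].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no rows for portion {portion!r}")
    spec = ModelSpec(response=trait, portion=portion, **spec_kw)
    std, record = standardize(sub, spec)
    return fit_reml(std, spec, record=record, seed=seed)


def truth_coefficients(tt: TraitTruth, terms: list[str]) -> np.ndarray:
    """Truth fixed effects (analysis scale) aligned with fitted terms."""
    out = np.zeros(len(terms))
    for i, term in enumerate(terms):
        if term == "(Intercept)":
            out[i] = tt.intercept
        elif term == "h":
            out[i] = tt.beta_height
        elif term == "h2":
            out[i] = tt.beta_height2
        elif term.startswith("site[") and ":" not in term:
            out[i] = tt.site_offsets.get(term[5:-1], 0.0)
        elif ":" in term:
            s, c = term.split(":")
            out[i] = tt.beta_site_climate.get((s[5:-1], c), 0.0)
        else:
            out[i] = tt.beta_climate.get(term, 0.0)
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``synthetic`` (a seed plus optional generator overrides) or
    ``inputs`` (paths to cells/rings/climate/trees tables) must be present.
    """

    out_dir: str = "runs/latest"
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    traits: tuple = TRAITS
    portions: tuple = PORTIONS
    model: dict = field(default_factory=dict)
    make_plots: bool = True

    REQUIRED_INPUTS = ("cells", "rings", "climate", "trees")

    def validate(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "config must contain exactly one of 'synthetic' or 'inputs'"
            )
        if self.inputs is not None:
            missing = [k for k in self.REQUIRED_INPUTS if k not in self.inputs]
            if missing:
                raise ValueError(f"config inputs missing fields: {missing}")
        bad = set(self.traits) - set(TRAITS)
        if bad:
            raise ValueError(f"unknown traits {sorted(bad)}")
        bad = set(self.portions) - set(PORTIONS)
        if bad:
            raise ValueError(f"unknown portions {sorted(bad)}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.traits, list):
            cfg.traits = tuple(cfg.traits)
        if isinstance(cfg.portions, list):
            cfg.portions = tuple(cfg.portions)
        return cfg.validate()

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _load_inputs(cfg: RunConfig):
    from xylemkit.io import read_rwl
    from xylemkit.xylem_traits import build_chronology

    if cfg.synthetic is not None:
        overrides = dict(cfg.synthetic)
        seed = int(overrides.pop("seed", cfg.seed))
        syn = SyntheticConfig(**overrides) if overrides else SyntheticConfig()
        ds = generate_dataset(seed, syn)
        return ds.cells, ds.ring_series, ds.climate, ds.trees, ds
    paths = cfg.inputs
    cells = read_cells(paths["cells"])
    climate = read_climate(paths["climate"])
    trees = read_trees(paths["trees"])
    rings_path = str(paths["rings"])
    if rings_path.endswith(".rwl"):
        parsed = read_rwl(rings_path)
        rings = pd.concat(
            [
                pd.DataFrame({"tree_id": tid, "year": yrs, "rw_mm": rw})
                for tid, (yrs, rw) in parsed.items()
            ],
            ignore_index=True,
        )
    else:
        rings = pd.read_csv(rings_path)
    series = series_from_long(rings, trees)
    return cells, series, climate, trees, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Produces heights.csv, chronology.csv, seasonal.csv, one fit JSON per
    trait x portion, a coefficient matrix (table of all models), contrasts,
    predictions, a markdown report, and a manifest recording the config
    hash, seed, per-stage timings and row counts.  Stage failures keep the
    artifacts produced so far and are recorded in the manifest.
    """
    from xylemkit.xylem_traits import build_chronology

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
        "failures": [],
    }

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_.t0, 3)
                }
                if exc is not None:
                    manifest["failures"].append({"stage": name, "error": str(exc)})
                    _write_manifest(out, manifest)
                return False

        return _Timer()

    with stage("load"):
        cells, series, climate, trees, ds = _load_inputs(config)

    with stage("heights"):
        heights = reconstruct_heights(series)
        heights.to_csv(out / "heights.csv", index=False)

    with stage("chronology"):
        chronology = build_chronology(cells)
        chronology.to_csv(out / "chronology.csv", index=False)

    with stage("seasons"):
        seasonal = aggregate_seasons(climate)
        seasonal.to_csv(out / "seasonal.csv", index=False)

    with stage("allometry"):
        allom_results = {}
        for site, grp in trees.groupby("site"):
            if grp["dbh_cm"].nunique() >= 4:
                try:
                    allom_results[site] = fit_weibull(
                        grp["dbh_cm"], grp["height_m"], site_id=str(site)
                    )
                except ValueError as err:
                    logger.warning("allometry skipped for %s: %s", site, err)
        if allom_results:
            payload = {
                s: {
                    "h_max": a.h_max,
                    "a": a.a,
                    "b": a.b,
                    "residual_sd": a.residual_sd,
                    "n_obs": a.n_obs,
                }
                for s, a in allom_results.items()
            }
            with open(out / "allometry.json", "w") as fh:
                json.dump(payload, fh, indent=1)

    with stage("model"):
        data = assemble_model_data(chronology, heights, seasonal, trees)
        data.to_csv(out / "model_data.csv", index=False)
        fits = {}
        coef_frames = []
        contrast_frames = []
        pred_frames = []
        for trait in config.traits:
            for portion in config.portions:
                key = f"{trait}_{portion}"
                fit = fit_trait_model(
                    data, trait, portion, seed=config.seed, **config.model
                )
                fits[key] = fit
                _write_fit_json(out / f"fit_{key}.json", fit)
                tab = fit.coef_table.copy()
                tab.insert(0, "model", key)
                coef_frames.append(tab)
                ct, letters = site_contrasts(fit)
                ct.insert(0, "model", key)
                ct["letters"] = [
                    f"{letters[a]}/{letters[b]}"
                    for a, b in zip(ct["site_a"], ct["site_b"])
                ]
                contrast_frames.append(ct)
                pt = prediction_table(fit)
                pt.insert(0, "model", key)
                pred_frames.append(pt)
        pd.concat(coef_frames, ignore_index=True).to_csv(
            out / "table1.csv", index=False
        )
        pd.concat(contrast_frames, ignore_index=True).to_csv(
            out / "contrasts.csv", index=False
        )
        pd.concat(pred_frames, ignore_index=True).to_csv(
            out / "predictions.csv", index=False
        )

    if config.make_plots:
        with stage("plots"):
            _make_plots(out, trees, heights, fits, allom_results)

    with stage("report"):
        _write_report(out, config, manifest, fits)

    _write_manifest(out, manifest)
    return {"out_dir": str(out), "fits": fits, "manifest": manifest}


def _write_manifest(out: Path, manifest: dict):
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _write_fit_json(path, fit: MixedModelFit):
    payload = {
        "response": fit.spec.response,
        "portion": fit.spec.portion,
        "log_transform": bool(fit.spec.log_transform),
        "coefficients": fit.coef_table.to_dict(orient="records"),
        "re_sd": dict(zip(fit.re_sd_terms, map(float, fit.params.re_sd))),
        "phi": fit.params.phi,
        "sigma": fit.params.sigma,
        "tree_weights": fit.tree_weights,
        "loglik_restricted": fit.loglik,
        "converged": fit.converged,
        "boundary": fit.boundary,
        "n_obs": fit.n_obs,
        "n_trees": fit.n_trees,
        "df_inner": fit.df_inner,
        "df_outer": fit.df_outer,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _make_plots(out: Path, trees, heights, fits, allom_results):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # height-diameter scatter with fitted site curves
    fig, ax = plt.subplots(figsize=(5, 4))
    for site, grp in trees.groupby("site"):
        pts = ax.scatter(grp["dbh_cm"], grp["height_m"], label=str(site), s=18)
        if site in allom_results:
            a = allom_results[site]
            d = np.linspace(0, trees["dbh_cm"].max() * 1.05, 100)
            ax.plot(d, a.predict(d), color=pts.get_facecolor()[0])
    ax.set_xlabel("DBH (cm)")
    ax.set_ylabel("height (m)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "allometry.png", dpi=120)
    plt.close(fig)

    # predicted trait distributions per site (marginal of the counterfactuals)
    if fits:
        fig, axes = plt.subplots(
            2, max((len(fits) + 1) // 2, 1), figsize=(3 * ((len(fits) + 1) // 2), 6)
        )
        axes = np.atleast_1d(axes).ravel()
        for ax, (key, fit) in zip(axes, fits.items()):
            pt = prediction_table(fit)
            data = [
                pt.loc[pt[fit.spec.site_col] == s, "fitted"].to_numpy()
                for s in fit.sites
            ]
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(fit.sites) + 1), fit.sites, fontsize=7)
            ax.set_title(key, fontsize=8)
        for ax in axes[len(fits):]:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(out / "predicted_traits.png", dpi=120)
        plt.close(fig)


def _write_report(out: Path, config: RunConfig, manifest: dict, fits):
    lines = [
        "# Pipeline run report",
        "",
        f"- config hash: `{manifest['config_hash']}`",
        f"- seed: {config.seed}",
        "",
        "## Models",
        "",
    ]
    for key, fit in fits.items():
        lines.append(
            f"### {key}  (phi = {fit.params.phi:.3f}, sigma = {fit.params.sigma:.3f},"
            f" logLik = {fit.loglik:.2f}{', boundary' if fit.boundary else ''})"
        )
        lines.append("")
        tab = fit.coef_table
        lines.append("| term | estimate | se | p | |")
        lines.append("|---|---|---|---|---|")
        for _, row in tab.iterrows():
            lines.append(
                f"| {row['term']} | {row['estimate']:.4f} | {row['se']:.4f} "
                f"| {row['p']:.4g} | {row['stars']} |"
            )
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# parameter-recovery harness
# ---------------------------------------------------------------------------


def simulate_models(
    seed: int,
    *,
    config: SyntheticConfig | None = None,
    models: tuple = (("la", "ew"),),
    **spec_kw,
) -> tuple[dict, SyntheticConfig]:
    """Generate one synthetic study and fit the requested trait models
    through the full observed pipeline (imputation, reconstruction, Mork
    chronology, seasonal aggregation)."""
    from xylemkit.xylem_traits import build_chronology

    if config is None:
        config = SyntheticConfig()
    ds = generate_dataset(seed, config)
    heights = reconstruct_heights(ds.ring_series)
    chronology = build_chronology(ds.cells)
    seasonal = aggregate_seasons(ds.climate)
    data = assemble_model_data(chronology, heights, seasonal, ds.trees)
    fits = {
        f"{trait}_{portion}": fit_trait_model(
            data, trait, portion, seed=seed, **spec_kw
        )
        for trait, portion in models
    }
    return fits, config


def simulate_and_fit(
    seed: int,
    *,
    config: SyntheticConfig | None = None,
    trait: str = "la",
    portion: str = "ew",
    **spec_kw,
) -> tuple[MixedModelFit, SyntheticConfig]:
    """One synthetic study, one fitted trait model (convenience wrapper)."""
    fits, config = simulate_models(
        seed, config=config, models=((trait, portion),), **spec_kw
    )
    return fits[f"{trait}_{portion}"], config


def replicate_coefficient_table(
    n_replicates: int,
    seed: int,
    *,
    config: SyntheticConfig | None = None,
    models: tuple = (("la", "ew"),),
    alpha: float = 0.05,
    **spec_kw,
) -> pd.DataFrame:
    """Long table of fitted coefficients across replicated studies.

    Each replicate regenerates the whole synthetic study under a fresh
    substream of ``seed`` and refits the requested models.  Estimates and
    SEs are back-transformed to the analysis scale on which the generator's
    truth is defined; ``covered`` and ``rejected`` use Wald t intervals and
    tests at level ``alpha`` with each term's denominator df.
    """
    from scipy import stats as sps

    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rows = []
    for rep in range(n_replicates):
        rep_seed = (seed + 104729 * rep) % (2**31 - 1)
        fits, cfg = simulate_models(
            rep_seed, config=config, models=models, **spec_kw
        )
        for key, fit in fits.items():
            tt = cfg.truth.traits[key]
            terms = list(fit.coef_table["term"])
            truth = truth_coefficients(tt, terms)
            sd_y = fit.record.sd(fit.spec.response)
            est = fit.coef_table["estimate"].to_numpy() * sd_y
            est[terms.index("(Intercept)")] += fit.record.stats[
                fit.spec.response
            ][0]
            se = fit.coef_table["se"].to_numpy() * sd_y
            df = fit.coef_table["df"].to_numpy()
            tcrit = sps.t.ppf(1 - alpha / 2, df)
            cover = np.abs(est - truth) <= tcrit * se
            reject = fit.coef_table["p"].to_numpy() < alpha
            for term, tr, e, s, pv, c, r in zip(
                terms, truth, est, se, fit.coef_table["p"], cover, reject
            ):
                rows.append(
                    {
                        "replicate": rep,
                        "model": key,
                        "term": term,
                        "truth": tr,
                        "estimate": e,
                        "se": s,
                        "p": pv,
                        "covered": bool(c),
                        "rejected": bool(r),
                    }
                )
    return pd.DataFrame(rows)


def parameter_recovery_study(
    n_replicates: int,
    seed: int,
    *,
    config: SyntheticConfig | None = None,
    trait: str = "la",
    portion: str = "ew",
    alpha: float = 0.05,
    **spec_kw,
) -> pd.DataFrame:
    """Repeated generate+fit: per-coefficient bias, RMSE, CI coverage and
    rejection rate at level ``alpha``.

    Coefficients are compared on the analysis (original, possibly log)
    scale, where the generator's truth lives.  Coverage uses Wald t
    intervals with each term's denominator df.
    """
    long = replicate_coefficient_table(
        n_replicates,
        seed,
        config=config,
        models=((trait, portion),),
        alpha=alpha,
        **spec_kw,
    )
    summary = (
        long.groupby("term", sort=False)
        .agg(
            truth=("truth", "first"),
            mean_estimate=("estimate", "mean"),
            sd_estimate=("estimate", "std"),
            coverage=("covered", "mean"),
            rejection_rate=("rejected", "mean"),
            n=("estimate", "size"),
        )
        .reset_index()
    )
    summary["bias"] = summary["mean_estimate"] - summary["truth"]
    summary["rmse"] = np.sqrt(
        summary["bias"] ** 2 + summary["sd_estimate"].fillna(0.0) ** 2
    )
    summary["mc_se"] = summary["sd_estimate"] / np.sqrt(summary["n"])
    return summary
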