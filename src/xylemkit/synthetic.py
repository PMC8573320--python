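"""Synthetic study generator with known ground truth.

Emulates a three-site boreal treeline study of white-spruce xylem anatomy:
one warm, drought-limited site (W-D, the model reference) and two cold,
temperature-limited sites (C-D dry, C-M moist).  The generator produces all
four pipeline inputs -- monthly climate, per-tree ring-width series with
occasional missing rings, tree metadata, and per-tracheid anatomy tables --
from an explicit truth model, so every downstream stage can be tested
without any external data.

The truth model lives on annual earlywood/latewood trait means (the level
the statistical model addresses): for each trait x portion,

    mean_it = intercept + site offset + bh*z(h_it) + bh2*z(h_it^2)
              + sum_c beta_c * z(climate_c,site,t)  (+ site interactions)
              + b0_i + b1_i*z(h) + b2_i*z(h^2) + e_it,

with per-tree random effects (diagonal covariance), AR1(phi) errors whose
scale varies by tree, and traits TB^2 and CWT defined on the natural-log
scale.  Cells are then drawn around those means with independent
within-ring noise and assembled into mutually consistent lumen/wall
geometry (square lumen; wall lengths chosen so the thickness-to-span ratio
reproduces the cell's TB^2; wall area from the cell's density).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from xylemkit.climate_season import PREDICTOR_COLUMNS, aggregate_seasons
from xylemkit.io import rings_to_long, write_rwl
from xylemkit.mixed_model import LOG_TRAITS, PORTIONS, TRAITS
from xylemkit.ring_series import RingSeries
from xylemkit.units import mm_to_cm

REFERENCE_SITE = "W-D"
SITES = ("W-D", "C-D", "C-M")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class SiteConfig:
    """Climate regime and sampling intensity of one site."""

    site_id: str
    monthly_temp_means: tuple  # 12 values, degC, Jan..Dec
    monthly_precip_means: tuple  # 12 values, mm
    temp_sd: float = 1.5
    precip_cv: float = 0.35
    n_trees: int = 6
    reference: bool = False

    def __post_init__(self):
        if len(self.monthly_temp_means) != 12 or len(self.monthly_precip_means) != 12:
            raise ValueError(f"site {self.site_id}: need 12 monthly values")
        if self.n_trees <= 0:
            raise ValueError(f"site {self.site_id}: n_trees must be positive")


@dataclass
class WeibullParams:
    """Site height-diameter law h(D) = h_max * exp(a * exp(-b*D))."""

    h_max: float
    a: float
    b: float

    def __post_init__(self):
        if self.h_max <= 0 or self.a >= 0 or self.b <= 0:
            raise ValueError("need h_max > 0, a < 0, b > 0")

    def height(self, dbh_cm):
        return self.h_max * np.exp(self.a * np.exp(-self.b * np.asarray(dbh_cm, float)))


@dataclass
class RingGrowthParams:
    """Negative-exponential ring-width age trend rw(age) = r1*exp(-age/tau) + r_inf."""

    rw_juvenile_mm: float = 1.5
    tau_years: float = 30.0
    rw_mature_mm: float = 0.35
    noise_cv: float = 0.25  # lognormal multiplicative noise on ring width


@dataclass
class TraitTruth:
    """Truth coefficients for one trait x ring portion, on the analysis
    scale (natural log for TB^2 and CWT)."""

    intercept: float
    beta_height: float = 0.0
    beta_height2: float = 0.0
    site_offsets: dict = field(default_factory=dict)  # site -> offset
    beta_climate: dict = field(default_factory=dict)  # predictor -> coef
    beta_site_climate: dict = field(default_factory=dict)  # (site, predictor) -> coef
    sigma_resid: float = 0.0  # year-level AR1 residual SD
    within_ring_sd: float = 0.0  # cell-level noise (log-sd for log traits)


@dataclass
class TruthParams:
    """Full generative truth: per trait x portion coefficients plus the
    shared random-effect/correlation structure.

    ``re_sd_*`` are multipliers of each trait's ``sigma_resid`` (so the
    random-effect scale follows the trait's own units); ``phi`` is the AR1
    coefficient; ``sigma_tree`` the per-tree residual SD multipliers (all 1
    when omitted).
    """

    traits: dict  # f"{trait}_{portion}" -> TraitTruth
    re_sd_intercept: float = 0.0
    re_sd_h: float = 0.0
    re_sd_h2: float = 0.0
    phi: float = 0.0
    sigma_tree: dict | None = None  # tree_id -> multiplier

    def __post_init__(self):
        if not -1.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (-1, 1)")
        for v in (self.re_sd_intercept, self.re_sd_h, self.re_sd_h2):
            if v < 0:
                raise ValueError("random-effect SDs must be >= 0")
        if self.sigma_tree is not None and any(
            m <= 0 for m in self.sigma_tree.values()
        ):
            raise ValueError("sigma_tree multipliers must be positive")


@dataclass
class CellGeometryProfile:
    """Within-ring cell layout: counts, portion split and monotone gradients.

    ``lumen_gradient``/``wall_gradient`` set the relative amplitude of the
    linear within-portion ramps (lumen area shrinking, wall thickening from
    ring start to ring end); ramps are normalized to mean 1 within each
    portion so annual portion means are preserved.
    """

    cells_per_ring: int = 24
    ew_fraction: float = 2.0 / 3.0
    lumen_gradient: float = 0.18
    wall_gradient: float = 0.12

    def __post_init__(self):
        if not 0 < self.ew_fraction < 1:
            raise ValueError("ew_fraction must lie in (0, 1)")
        if self.cells_per_ring < 2:
            raise ValueError("need at least 2 cells per ring")
        if not (0 <= self.lumen_gradient < 1 and 0 <= self.wall_gradient < 1):
            raise ValueError("gradients must lie in [0, 1)")


# ---------------------------------------------------------------------------
# defaults emulating the study conditions
# ---------------------------------------------------------------------------


def default_sites() -> list[SiteConfig]:
    """Three contrasting treeline climate regimes (degC / mm month means)."""
    return [
        SiteConfig(
            "W-D",
            monthly_temp_means=(-22, -18, -10, 0, 9, 15, 17, 14, 7, -4, -15, -20),
            monthly_precip_means=(15, 12, 10, 10, 15, 35, 50, 45, 30, 20, 18, 15),
            reference=True,
        ),
        SiteConfig(
            "C-D",
            monthly_temp_means=(-24, -22, -16, -7, 3, 11, 13, 10, 3, -9, -18, -22),
            monthly_precip_means=(10, 10, 8, 8, 12, 30, 45, 40, 25, 15, 12, 10),
        ),
        SiteConfig(
            "C-M",
            monthly_temp_means=(-17, -14, -9, -2, 6, 12, 14, 11, 5, -5, -13, -16),
            monthly_precip_means=(25, 20, 18, 15, 25, 60, 80, 75, 50, 35, 28, 25),
        ),
    ]


def default_allometries() -> dict[str, WeibullParams]:
    # warm-dry trees grow taller for the same diameter
    return {
        "W-D": WeibullParams(h_max=18.0, a=-2.3, b=0.09),
        "C-D": WeibullParams(h_max=10.0, a=-2.2, b=0.07),
        "C-M": WeibullParams(h_max=12.0, a=-2.2, b=0.08),
    }


def default_growth() -> dict[str, RingGrowthParams]:
    return {
        "W-D": RingGrowthParams(2.0, 30.0, 0.5),
        "C-D": RingGrowthParams(1.2, 30.0, 0.3),
        "C-M": RingGrowthParams(1.5, 30.0, 0.35),
    }


def default_truth() -> TruthParams:
    """Truth coefficients encoding the headline qualitative pattern:
    positive height effect on earlywood lumen area, negative on TB^2,
    positive latewood summer-temperature effects on CWT/DEN at the cold
    sites, with weaker secondary effects elsewhere."""
    traits = {
        "la_ew": TraitTruth(
            intercept=900.0,
            beta_height=150.0,
            beta_height2=20.0,
            site_offsets={"C-D": 20.0, "C-M": 60.0},
            beta_climate={"summer_temp": 25.0},
            beta_site_climate={
                ("C-D", "summer_temp"): -20.0,
                ("C-M", "summer_temp"): -20.0,
            },
            sigma_resid=60.0,
            within_ring_sd=120.0,
        ),
        "la_lw": TraitTruth(
            intercept=120.0,
            beta_height=25.0,
            beta_climate={"prev_winter_prcp": 8.0, "spring_prcp": 8.0},
            sigma_resid=14.0,
            within_ring_sd=30.0,
        ),
        "tb2_ew": TraitTruth(
            intercept=-3.58,
            beta_height=-0.35,
            beta_height2=-0.02,
            beta_climate={"summer_prcp": -0.05, "summer_temp": 0.02},
            sigma_resid=0.10,
            within_ring_sd=0.15,
        ),
        "tb2_lw": TraitTruth(
            intercept=-0.19,
            beta_height=-0.10,
            beta_climate={"summer_prcp": -0.04},
            beta_site_climate={
                ("C-D", "summer_temp"): 0.04,
                ("C-M", "summer_temp"): 0.04,
            },
            sigma_resid=0.08,
            within_ring_sd=0.15,
        ),
        "den_ew": TraitTruth(
            intercept=0.27,
            site_offsets={"C-D": -0.02},
            beta_climate={"summer_temp": -0.008},
            sigma_resid=0.012,
            within_ring_sd=0.03,
        ),
        "den_lw": TraitTruth(
            intercept=0.72,
            beta_height=-0.004,
            beta_climate={"spring_temp": 0.006},
            beta_site_climate={
                ("C-D", "summer_temp"): 0.012,
                ("C-M", "summer_temp"): 0.012,
            },
            sigma_resid=0.010,
            within_ring_sd=0.025,
        ),
        "cwt_ew": TraitTruth(
            intercept=np.log(2.5),
            beta_height=0.04,
            beta_climate={"spring_temp": 0.02},
            sigma_resid=0.05,
            within_ring_sd=0.10,
        ),
        "cwt_lw": TraitTruth(
            intercept=np.log(5.0),
            beta_climate={"spring_temp": 0.02, "summer_prcp": -0.03},
            beta_site_climate={
                ("C-D", "summer_temp"): 0.06,
                ("C-M", "summer_temp"): 0.06,
            },
            sigma_resid=0.04,
            within_ring_sd=0.10,
        ),
    }
    return TruthParams(
        traits=traits,
        re_sd_intercept=0.8,
        re_sd_h=0.4,
        re_sd_h2=0.2,
        phi=0.4,
    )


@dataclass
class SyntheticConfig:
    """Everything the generator needs, with study-condition defaults."""

    sites: list = field(default_factory=default_sites)
    allometries: dict = field(default_factory=default_allometries)
    growth: dict = field(default_factory=default_growth)
    truth: TruthParams = field(default_factory=default_truth)
    profile: CellGeometryProfile = field(default_factory=CellGeometryProfile)
    climate_years: tuple = (1901, 2015)
    sampling_year: int = 2015
    age_range: tuple = (95, 115)
    anatomy_years: int = 80
    coring_height_m: float = 1.3
    height_noise_sd_m: float = 0.0
    pith_offset_cm: float = 0.0
    missing_ring_prob: float = 0.02
    sigma_tree_lognorm_sd: float = 0.25  # spread of per-tree residual scales


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    """Fan a single integer seed out into independent substreams."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def generate_climate(sites, years, seed: int) -> pd.DataFrame:
    """Monthly climate table for each site: one row per site x year x month.

    Temperatures are Gaussian around the site's monthly normals;
    precipitation draws are Gaussian with CV-scaled spread, truncated at 0.
    """
    if isinstance(sites, SiteConfig):
        sites = [sites]
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    rng = _rng_for(seed, 0)
    rows = []
    for cfg in sites:
        for year in years:
            for m in range(12):
                t = rng.normal(cfg.monthly_temp_means[m], cfg.temp_sd)
                p_mean = cfg.monthly_precip_means[m]
                p = rng.normal(p_mean, cfg.precip_cv * p_mean)
                rows.append(
                    {
                        "site": cfg.site_id,
                        "year": int(year),
                        "month": m + 1,
                        "tmean_c": t,
                        "prcp_mm": max(p, 0.0),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class TreeTruth:
    """Ground truth kept alongside each observed ring series."""

    tree_id: str
    site: str
    rw_true_mm: np.ndarray  # complete series, no gaps
    missing_mask: np.ndarray  # which rings were deleted from the observed file
    dbh_true_cm: np.ndarray  # end-of-year DBH from the complete series
    height_true_m: np.ndarray  # linear-in-DBH height trajectory
    years: np.ndarray


def generate_trees(
    config: SyntheticConfig, seed: int
) -> tuple[pd.DataFrame, list[RingSeries], dict[str, TreeTruth]]:
    """Tree metadata plus observed (gappy) and true ring-width series.

    Ring widths follow each site's negative-exponential age trend with
    lognormal noise; the sampling DBH is exactly twice the cumulative ring
    width plus the distance-to-pith allowance, and the sampling height is
    the site allometry evaluated at that DBH plus optional noise.  Missing
    rings are deleted from the observed series only; the truth keeps them.
    """
    rng = _rng_for(seed, 1)
    meta_rows, observed, truths = [], [], {}
    for cfg in config.sites:
        growth = config.growth[cfg.site_id]
        allom = config.allometries[cfg.site_id]
        for j in range(cfg.n_trees):
            tree_id = f"{cfg.site_id}-{j + 1:02d}"
            age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
            years = np.arange(config.sampling_year - age + 1, config.sampling_year + 1)
            cambial_age = np.arange(1, age + 1)
            trend = (
                growth.rw_juvenile_mm * np.exp(-cambial_age / growth.tau_years)
                + growth.rw_mature_mm
            )
            noise = rng.lognormal(
                -0.5 * np.log1p(growth.noise_cv**2), np.sqrt(np.log1p(growth.noise_cv**2)), age
            )
            rw = trend * noise
            dbh_true = config.pith_offset_cm + 2.0 * mm_to_cm(np.cumsum(rw))
            sampling_dbh = float(dbh_true[-1])
            h_samp = float(allom.height(sampling_dbh))
            if config.height_noise_sd_m > 0:
                h_samp = max(
                    h_samp + rng.normal(0.0, config.height_noise_sd_m),
                    config.coring_height_m + 0.1,
                )
            slope = (h_samp - config.coring_height_m) / sampling_dbh
            height_true = config.coring_height_m + slope * dbh_true

            missing = rng.random(age) < config.missing_ring_prob
            missing[-1] = False  # the sampling-year ring is always measured
            missing[0] = False
            rw_obs = rw.copy()
            rw_obs[missing] = np.nan

            observed.append(
                RingSeries(
                    tree_id=tree_id,
                    years=years,
                    rw_mm=rw_obs,
                    coring_height_m=config.coring_height_m,
                    sampling_dbh_cm=sampling_dbh,
                    sampling_height_m=h_samp,
                    pith_offset_cm=config.pith_offset_cm,
                )
            )
            truths[tree_id] = TreeTruth(
                tree_id=tree_id,
                site=cfg.site_id,
                rw_true_mm=rw,
                missing_mask=missing,
                dbh_true_cm=dbh_true,
                height_true_m=height_true,
                years=years,
            )
            meta_rows.append(
                {
                    "tree_id": tree_id,
                    "site": cfg.site_id,
                    "coring_height_m": config.coring_height_m,
                    "sampling_year": config.sampling_year,
                    "dbh_cm": sampling_dbh,
                    "height_m": h_samp,
                }
            )
    return pd.DataFrame(meta_rows), observed, truths


def _zscore_population(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1)
    if s <= 0:
        raise ValueError("zero variance in generator predictor")
    return (x - x.mean()) / s


def _linear_predictor(tt: TraitTruth, site, h_z, h2_z, clim_z: pd.DataFrame):
    eta = np.full(len(site), tt.intercept, dtype=float)
    for s, off in tt.site_offsets.items():
        eta += off * (site == s)
    eta += tt.beta_height * h_z + tt.beta_height2 * h2_z
    for c, b in tt.beta_climate.items():
        eta += b * clim_z[c].to_numpy()
    for (s, c), b in tt.beta_site_climate.items():
        eta += b * (site == s) * clim_z[c].to_numpy()
    return eta


def generate_cells(
    truth: TruthParams,
    profile: CellGeometryProfile,
    tree_truths: dict[str, TreeTruth],
    climate: pd.DataFrame,
    seed: int,
    *,
    anatomy_years: int = 80,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-level anatomy table realizing the truth model on annual means.

    For each tree the last ``anatomy_years`` rings with complete seasonal
    climate enter.  Per tree x year x portion, the truth linear predictor
    (with random effects and AR1 noise) defines the portion's annual mean;
    cells are then drawn around it with independent within-ring noise and
    a monotone within-ring gradient, and converted into consistent
    lumen/wall geometry.

    Returns ``(cells, truth_means)``: the observed cell table and the
    underlying annual means on the natural trait scale.
    """
    rng = _rng_for(seed, 2)
    seasonal = aggregate_seasons(climate)

    # assemble the tree x year frame the analysis will eventually see
    rows = []
    for tid, tt in tree_truths.items():
        avail = seasonal[seasonal["site"] == tt.site]["year"]
        ok = np.isin(tt.years, avail)
        years = tt.years[ok][-anatomy_years:]
        sel = np.isin(tt.years, years)
        for y, h in zip(tt.years[sel], tt.height_true_m[sel]):
            rows.append({"tree_id": tid, "site": tt.site, "year": int(y), "h": h})
    frame = pd.DataFrame(rows).sort_values(["tree_id", "year"]).reset_index(drop=True)
    frame = frame.merge(seasonal, on=["site", "year"], how="left")

    h_z = _zscore_population(frame["h"].to_numpy())
    h2_z = _zscore_population(frame["h"].to_numpy() ** 2)
    clim_z = pd.DataFrame(
        {c: _zscore_population(frame[c].to_numpy()) for c in PREDICTOR_COLUMNS}
    )
    site = frame["site"].to_numpy()
    tree = frame["tree_id"].to_numpy()
    tree_ids = list(tree_truths)
    sigma_tree = truth.sigma_tree or {t: 1.0 for t in tree_ids}

    # per-tree random effects and AR1 residuals, independent per trait model
    truth_cols = {}
    for key, tt in truth.traits.items():
        re = {
            t: rng.normal(
                0.0,
                [
                    truth.re_sd_intercept * tt.sigma_resid,
                    truth.re_sd_h * tt.sigma_resid,
                    truth.re_sd_h2 * tt.sigma_resid,
                ],
            )
            for t in tree_ids
        }
        eta = _linear_predictor(tt, site, h_z, h2_z, clim_z)
        eps = np.empty(len(frame))
        for t in tree_ids:
            idx = np.flatnonzero(tree == t)
            n = len(idx)
            scale = tt.sigma_resid * sigma_tree[t]
            innov_sd = scale * np.sqrt(1.0 - truth.phi**2)
            shocks = np.concatenate(
                [[rng.normal(0.0, scale)], rng.normal(0.0, innov_sd, n - 1)]
            )
            eps[idx] = lfilter([1.0], [1.0, -truth.phi], shocks)
            b0, b1, b2 = re[t]
            eta[idx] += b0 + b1 * h_z[idx] + b2 * h2_z[idx]
        truth_cols[key] = eta + eps

    # draw cells around the annual means
    n_ew = int(round(profile.cells_per_ring * profile.ew_fraction))
    n_ew = min(max(n_ew, 1), profile.cells_per_ring - 1)
    n_by_portion = {"ew": n_ew, "lw": profile.cells_per_ring - n_ew}

    def ramp(n, amplitude, increasing):
        if n == 1 or amplitude == 0:
            return np.ones(n)
        g = np.linspace(-amplitude, amplitude, n)
        return 1.0 + (g if increasing else -g)

    chunks = {c: [] for c in ("tree_id", "year", "la", "cwt_rad", "cwt_tan",
                              "cwa", "wall_rad", "wall_tan")}
    truth_rows = []
    tree_arr = frame["tree_id"].to_numpy()
    year_arr = frame["year"].to_numpy()
    for i in range(len(frame)):
        tid, yr = tree_arr[i], int(year_arr[i])
        for portion in PORTIONS:
            n = n_by_portion[portion]
            means = {tr: truth_cols[f"{tr}_{portion}"][i] for tr in TRAITS}
            trec = {"tree_id": tid, "year": yr, "portion": portion}
            for tr in TRAITS:
                trec[tr] = (
                    float(np.exp(means[tr])) if tr in LOG_TRAITS else float(means[tr])
                )
            truth_rows.append(trec)

            sds = {tr: truth.traits[f"{tr}_{portion}"].within_ring_sd for tr in TRAITS}
            # per-cell draws; multiplicative mean-one lognormal for log traits
            def draw(tr):
                mu = means[tr]
                sd = sds[tr]
                if tr in LOG_TRAITS:
                    base = np.exp(mu)
                    if sd == 0:
                        return np.full(n, base)
                    return base * rng.lognormal(-0.5 * sd**2, sd, n)
                if sd == 0:
                    return np.full(n, mu)
                return rng.normal(mu, sd, n)

            la = np.maximum(draw("la"), 1.0)
            cwt = np.maximum(draw("cwt"), 0.05)
            tb2 = np.maximum(draw("tb2"), 1e-6)
            den = np.clip(draw("den"), 0.01, 0.99)
            # monotone within-ring gradients (mean preserved per portion)
            la = la * ramp(n, profile.lumen_gradient, increasing=False)
            cwt = cwt * ramp(n, profile.wall_gradient, increasing=True)

            asym = rng.uniform(-0.04, 0.04, n)
            cwt_rad = cwt * (1.0 + asym)
            cwt_tan = cwt * (1.0 - asym)
            # wall length on each side reproduces the cell's TB^2 exactly
            sqrt_tb2 = np.sqrt(tb2)
            chunks["tree_id"].append(np.full(n, tid, dtype=object))
            chunks["year"].append(np.full(n, yr))
            chunks["la"].append(la)
            chunks["cwt_rad"].append(cwt_rad)
            chunks["cwt_tan"].append(cwt_tan)
            chunks["cwa"].append(la * den / (1.0 - den))
            chunks["wall_rad"].append(2.0 * cwt_rad / sqrt_tb2)
            chunks["wall_tan"].append(2.0 * cwt_tan / sqrt_tb2)
    cat = {k: np.concatenate(v) for k, v in chunks.items()}
    ld = np.sqrt(cat["la"])  # square lumen
    cells = pd.DataFrame(
        {
            "tree_id": cat["tree_id"].astype(str),
            "year": cat["year"].astype(int),
            "la_um2": cat["la"],
            "ld_rad_um": ld,
            "ld_tan_um": ld,
            "cwt_rad_um": cat["cwt_rad"],
            "cwt_tan_um": cat["cwt_tan"],
            "cwa_um2": cat["cwa"],
            "wall_len_rad_um": cat["wall_rad"],
            "wall_len_tan_um": cat["wall_tan"],
        }
    )
    truth_means = pd.DataFrame(truth_rows)
    return cells, truth_means


@dataclass
class SyntheticDataset:
    """Everything one generator run produced, observed and truth."""

    config: SyntheticConfig
    seed: int
    climate: pd.DataFrame
    trees: pd.DataFrame
    ring_series: list
    tree_truths: dict
    cells: pd.DataFrame
    truth_means: pd.DataFrame

    def write(self, outdir) -> None:
        """Write the observed tables (cells.csv, rings.rwl + rings.csv,
        climate.csv, trees.csv) and the truth (truth.json, truth_means.csv)."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False)
        self.climate.to_csv(out / "climate.csv", index=False)
        self.trees.to_csv(out / "trees.csv", index=False)
        rings_to_long(self.ring_series).to_csv(out / "rings.csv", index=False)
        write_rwl(self.ring_series, out / "rings.rwl")
        self.truth_means.to_csv(out / "truth_means.csv", index=False)
        truth = self.config.truth
        payload = {
            "seed": self.seed,
            "phi": truth.phi,
            "re_sd_intercept": truth.re_sd_intercept,
            "re_sd_h": truth.re_sd_h,
            "re_sd_h2": truth.re_sd_h2,
            "sigma_tree": truth.sigma_tree,
            "traits": {
                k: {
                    **asdict(v),
                    "beta_site_climate": {
                        f"{s}:{c}": b for (s, c), b in v.beta_site_climate.items()
                    },
                }
                for k, v in truth.traits.items()
            },
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def generate_dataset(
    seed: int, config: SyntheticConfig | None = None
) -> SyntheticDataset:
    """Run the full generator: climate -> trees/rings -> cells."""
    if config is None:
        config = SyntheticConfig()
    truth = config.truth
    if truth.sigma_tree is None and config.sigma_tree_lognorm_sd > 0:
        rng = _rng_for(seed, 3)
        n_total = sum(s.n_trees for s in config.sites)
        ids = [
            f"{s.site_id}-{j + 1:02d}" for s in config.sites for j in range(s.n_trees)
        ]
        draws = rng.lognormal(0.0, config.sigma_tree_lognorm_sd, n_total)
        draws[0] = 1.0  # first tree anchors the weight scale
        truth.sigma_tree = dict(zip(ids, draws))
    years = range(config.climate_years[0], config.climate_years[1] + 1)
    climate = generate_climate(config.sites, years, seed)
    trees, ring_series, tree_truths = generate_trees(config, seed)
    cells, truth_means = generate_cells(
        truth,
        config.profile,
        tree_truths,
        climate,
        seed,
        anatomy_years=config.anatomy_years,
    )
    return SyntheticDataset(
        config=config,
        seed=seed,
        climate=climate,
        trees=trees,
        ring_series=ring_series,
        tree_truths=tree_truths,
        cells=cells,
        truth_means=truth_means,
    )
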