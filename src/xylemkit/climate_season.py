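"""Seasonal climate predictors per ring year.

Ring formation integrates weather from the autumn preceding the growth year
through the growing season itself, so each ring year y gets four seasons:

* prev_fall   : Sep-Nov of year y-1
* prev_winter : Dec of year y-1 plus Jan-Feb of year y
* spring      : Mar-May of year y
* summer      : Jun-Aug of year y

Temperature is averaged over the three months of a season; precipitation is
summed (monthly values are totals; a seasonal mean is available as an option
and differs only by the constant factor 3, which later standardization
absorbs).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: season -> list of (year offset relative to ring year, month)
SEASON_MONTHS = {
    "prev_fall": [(-1, 9), (-1, 10), (-1, 11)],
    "prev_winter": [(-1, 12), (0, 1), (0, 2)],
    "spring": [(0, 3), (0, 4), (0, 5)],
    "summer": [(0, 6), (0, 7), (0, 8)],
}

SEASONS = list(SEASON_MONTHS)

#: the 8 predictor column names, in canonical order
PREDICTOR_COLUMNS = [f"{s}_{v}" for s in SEASONS for v in ("temp", "prcp")]


def aggregate_seasons(
    monthly: pd.DataFrame,
    years=None,
    *,
    precip_stat: str = "sum",
) -> pd.DataFrame:
    """Aggregate monthly climate into per-ring-year seasonal predictors.

    Parameters
    ----------
    monthly : DataFrame
        Columns site, year, month, tmean_c, prcp_mm.
    years : iterable of int, optional
        Ring years to produce.  If given, any missing contributing month is
        an error naming the gaps; if omitted, all ring years with complete
        coverage (previous September through current August) are produced
        and incomplete leading/trailing years are dropped with a warning.
    precip_stat : {'sum', 'mean'}
        Seasonal precipitation statistic.

    Returns
    -------
    DataFrame with columns site, year and the 8 predictors
    (``<season>_temp`` in degC, ``<season>_prcp`` in mm).
    """
    if precip_stat not in ("sum", "mean"):
        raise ValueError(f"unknown precip_stat {precip_stat!r}")
    need = {"site", "year", "month", "tmean_c", "prcp_mm"}
    missing_cols = need - set(monthly.columns)
    if missing_cols:
        raise ValueError(f"monthly table lacks columns: {sorted(missing_cols)}")
    if monthly.duplicated(["site", "year", "month"]).any():
        raise ValueError("duplicate site/year/month rows in monthly table")

    explicit = years is not None
    have = set(
        zip(monthly["site"], monthly["year"].astype(int), monthly["month"].astype(int))
    )
    frames = []
    for site, site_tab in monthly.groupby("site", sort=True):
        yr_lo, yr_hi = int(site_tab["year"].min()), int(site_tab["year"].max())
        if explicit:
            ring_years = sorted(int(y) for y in years)
        else:
            ring_years = list(range(yr_lo, yr_hi + 1))
        grid = pd.Index(range(min(ring_years) - 1, max(ring_years) + 1), name="year")
        wide_t = site_tab.pivot(index="year", columns="month", values="tmean_c")
        wide_p = site_tab.pivot(index="year", columns="month", values="prcp_mm")
        wide_t = wide_t.reindex(index=grid, columns=range(1, 13))
        wide_p = wide_p.reindex(index=grid, columns=range(1, 13))
        prev_t, prev_p = wide_t.shift(1), wide_p.shift(1)  # calendar year y-1

        rec = pd.DataFrame({"site": site, "year": grid})
        for season, months in SEASON_MONTHS.items():
            # explicit sums so that any missing month propagates as NaN
            t_parts = [
                (prev_t if off < 0 else wide_t)[m].to_numpy() for off, m in months
            ]
            p_parts = [
                (prev_p if off < 0 else wide_p)[m].to_numpy() for off, m in months
            ]
            rec[f"{season}_temp"] = np.sum(t_parts, axis=0) / len(months)
            psum = np.sum(p_parts, axis=0)
            rec[f"{season}_prcp"] = psum if precip_stat == "sum" else psum / len(
                months
            )
        rec = rec[rec["year"].isin(ring_years)]
        complete = ~rec[PREDICTOR_COLUMNS].isna().any(axis=1)
        if explicit and not complete.all():
            bad_year = int(rec.loc[~complete, "year"].iloc[0])
            gaps = [
                (bad_year + off, m)
                for months in SEASON_MONTHS.values()
                for off, m in months
                if (site, bad_year + off, m) not in have
            ]
            raise ValueError(
                f"site {site}, ring year {bad_year}: missing months "
                + ", ".join(f"{yy}-{mm:02d}" for yy, mm in sorted(gaps))
            )
        if not complete.all():
            dropped = rec.loc[~complete, "year"].astype(int).tolist()
            logger.warning(
                "site %s: dropped %d ring years with incomplete climate "
                "coverage (%s..%s)",
                site,
                len(dropped),
                dropped[0],
                dropped[-1],
            )
        frames.append(rec[complete])
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["site", "year"] + PREDICTOR_COLUMNS
    )
    return out[["site", "year"] + PREDICTOR_COLUMNS].reset_index(drop=True)
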