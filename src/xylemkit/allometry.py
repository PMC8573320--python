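"""Site-level growth allometry.

Two ingredients describe a site's ontogeny:

* a modified Weibull-type saturating height-diameter law
  ``h(D) = h_max * exp(a * exp(-b * D))`` with ``a < 0 < b``, rising from
  ``h_max * e**a`` at D = 0 toward the asymptote ``h_max``;
* a regional curve: the expected ring width as a function of cambial age,
  estimated as age-wise means smoothed by a penalized (Whittaker-type)
  smoother.  Because cumulative ring width is half the stem diameter, twice
  the cumulative curve is the mean diameter-age trajectory.

Composing the two yields the site's age -> (diameter, height) trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from xylemkit.units import mm_to_cm


@dataclass
class WeibullAllometry:
    """Fitted height-diameter relationship for one site.

    ``h(D) = h_max * exp(a * exp(-b * D))``: ``h_max`` is the height
    asymptote (m); ``a`` (< 0, dimensionless) sets the depth of the curve at
    D = 0 (``h(0) = h_max * e^a``) and ``b`` (> 0, per cm) the rate at which
    the asymptote is approached with DBH.
    """

    site_id: str
    h_max: float
    a: float
    b: float
    residual_sd: float
    n_obs: int
    converged: bool
    cost: float

    def predict(self, dbh_cm):
        return _weibull(dbh_cm, self.h_max, self.a, self.b)


def _weibull(dbh, h_max, a, b):
    dbh = np.asarray(dbh, dtype=float)
    return h_max * np.exp(a * np.exp(-b * dbh))


def fit_weibull(
    dbh_cm,
    height_m,
    start: tuple[float, float, float] | None = None,
    *,
    site_id: str = "",
    n_multistart: int = 20,
    seed: int = 0,
) -> WeibullAllometry:
    """Nonlinear least-squares fit of the saturating height-diameter law.

    Minimizes ``sum (h_obs - h_max * exp(a * exp(-b*D)))**2`` subject to
    ``h_max > 0``, ``a < 0``, ``b > 0``.  The objective can be multimodal,
    so a heuristic start (``h_max = 1.05 * max(h)``, rate ``b`` scaled to
    the mean DBH, ``a`` solving the mean point) is followed by jittered
    multistarts; the best converged solution wins.

    Raises
    ------
    ValueError
        On fewer than 4 distinct DBH values, non-positive heights, or if no
        start converges.
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.unique(dbh).size < 4:
        raise ValueError("need at least 4 distinct DBH values")
    if np.any(h <= 0):
        raise ValueError("heights must be positive")
    if np.any(dbh <= 0):
        raise ValueError("DBH values must be positive")

    if start is None:
        h_max0 = 1.05 * h.max()
        b0 = 1.0 / dbh.mean()
        a0 = np.log(h.mean() / h_max0) * np.exp(b0 * dbh.mean())
        start = (h_max0, min(a0, -1e-6), b0)

    def resid(p):
        return _weibull(dbh, *p) - h

    bounds = ([1e-8, -np.inf, 1e-8], [np.inf, -1e-12, np.inf])
    rng = np.random.default_rng(seed)
    starts = [np.asarray(start, dtype=float)]
    for _ in range(n_multistart):
        jitter = rng.uniform([0.7, 0.3, 0.3], [1.5, 3.0, 3.0])
        starts.append(np.asarray(start) * jitter)

    best = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            res = least_squares(resid, p0, bounds=bounds, xtol=1e-12, ftol=1e-12,
                                gtol=1e-12)
        except Exception:
            continue
        if not res.success:
            continue
        if best is None or res.cost < best.cost - 1e-14:
            best = res
    if best is None:
        raise ValueError(
            f"Weibull fit failed to converge for site {site_id!r} "
            f"after {len(starts)} starts"
        )
    n = dbh.size
    dof = max(n - 3, 1)
    residual_sd = float(np.sqrt(2.0 * best.cost / dof))
    h_max, a, b = best.x
    return WeibullAllometry(
        site_id=site_id,
        h_max=float(h_max),
        a=float(a),
        b=float(b),
        residual_sd=residual_sd,
        n_obs=n,
        converged=True,
        cost=float(best.cost),
    )


@dataclass
class RegionalCurve:
    """Expected ring width (mm) per cambial age for one site."""

    site_id: str
    ages: np.ndarray  # 1..max age
    rw_mm: np.ndarray
    span: float

    def cumulative_diameter_mm(self) -> np.ndarray:
        """Mean diameter (mm) at the end of each cambial age: 2x cumulative
        expected ring width."""
        return 2.0 * np.cumsum(self.rw_mm)


def _difference_matrix(n: int, order: int) -> np.ndarray:
    d = np.eye(n)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d


def fit_regional_curve(
    rw_by_age: pd.DataFrame,
    span: float | None = None,
    *,
    site_id: str = "",
) -> RegionalCurve:
    """Regional curve: age-wise mean ring width, then penalized smoothing.

    ``rw_by_age`` needs columns ``cambial_age`` (1-based ring count from the
    pith) and ``rw_mm``.  Age-wise means weighted by ring counts are smoothed
    by minimizing

        sum_a n_a (z_a - ybar_a)^2 + span^2 ||D1 z||^2 + span^4 ||D2 z||^2

    over the integer age grid.  ``span = 0`` returns the raw age-wise means;
    as ``span`` grows the curve stiffens and tends to the global mean ring
    width.  Default span is 10% of the maximum observed age.
    """
    if rw_by_age.empty:
        raise ValueError("empty ring-width table")
    need = {"cambial_age", "rw_mm"}
    if not need <= set(rw_by_age.columns):
        raise ValueError(f"table lacks columns: {sorted(need - set(rw_by_age.columns))}")
    grouped = rw_by_age.groupby("cambial_age")["rw_mm"]
    means = grouped.mean()
    counts = grouped.size()
    max_age = int(means.index.max())
    if int(means.index.min()) < 1:
        raise ValueError("cambial ages must start at 1")
    ages = np.arange(1, max_age + 1)
    ybar = np.full(max_age, np.nan)
    w = np.zeros(max_age)
    ybar[means.index.to_numpy(dtype=int) - 1] = means.to_numpy()
    w[counts.index.to_numpy(dtype=int) - 1] = counts.to_numpy()
    if np.isnan(ybar).any():
        # unrepresented interior ages carry zero weight; seed with overall mean
        ybar = np.where(np.isnan(ybar), np.nansum(ybar * w) / w.sum(), ybar)

    if span is None:
        span = 0.1 * max_age
    if span < 0:
        raise ValueError("span must be non-negative")
    if span == 0 or max_age < 3:
        z = ybar.copy()
    elif span > 50.0 * max_age:
        # stiff limit: the first-difference penalty forces a constant, and
        # the weighted constant fit is the global mean ring width
        z = np.full(max_age, float(np.sum(w * ybar) / w.sum()))
    else:
        W = np.diag(w)
        d1 = _difference_matrix(max_age, 1)
        d2 = _difference_matrix(max_age, 2)
        lhs = W + span**2 * d1.T @ d1 + span**4 * d2.T @ d2
        z = np.linalg.solve(lhs, w * ybar)
    z = np.maximum(z, 1e-9)  # expected ring width is strictly positive
    return RegionalCurve(site_id=site_id, ages=ages, rw_mm=z, span=float(span))


def ontogenetic_trajectory(
    curve: RegionalCurve, allom: WeibullAllometry
) -> pd.DataFrame:
    """Compose regional curve and height allometry into age -> (D, h).

    Row for age 0 anchors the trajectory at diameter 0 and the Weibull
    minimum height ``h_max * e^a``.  Diameter in cm, height in m.
    """
    if curve.site_id and allom.site_id and curve.site_id != allom.site_id:
        raise ValueError(
            f"site mismatch: curve {curve.site_id!r} vs allometry {allom.site_id!r}"
        )
    diam_cm = np.concatenate([[0.0], mm_to_cm(curve.cumulative_diameter_mm())])
    ages = np.concatenate([[0], curve.ages])
    height = allom.predict(diam_cm)
    return pd.DataFrame({"age": ages, "diameter_cm": diam_cm, "height_m": height})
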