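"""Per-tree ring-width series and reconstruction of annual DBH and height.

A cored tree contributes an ordered ring-width series (possibly with missing
rings), its coring height, and DBH/total height measured once at sampling.
From these we rebuild the tree's annual diameter by subtracting double ring
width backwards from the sampling DBH, and interpolate annual height linearly
in DBH between the coring height (at hypothetical DBH 0) and the measured
height at sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from xylemkit.units import mm_to_cm

#: calendar half-window (years) used when averaging around a missing ring
IMPUTE_WINDOW = 10


@dataclass
class RingSeries:
    """Ordered ring widths for one tree plus sampling metadata.

    Parameters
    ----------
    tree_id : str
        Unique tree identifier.
    years : ndarray of int
        Strictly increasing, contiguous calendar years; the last entry is the
        sampling year.
    rw_mm : ndarray of float
        Ring width per year in mm; ``nan`` marks a missing ring.
    coring_height_m : float
        Height above ground at which the core was taken.
    sampling_dbh_cm, sampling_height_m : float
        DBH and total height measured at sampling.
    pith_offset_cm : float
        Diameter already present inside the innermost measured ring
        (distance-to-pith allowance); default 0.
    imputed : ndarray of bool, optional
        Flags for rings filled in by :func:`impute_missing_rings`.
    """

    tree_id: str
    years: np.ndarray
    rw_mm: np.ndarray
    coring_height_m: float
    sampling_dbh_cm: float
    sampling_height_m: float
    pith_offset_cm: float = 0.0
    imputed: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.rw_mm = np.asarray(self.rw_mm, dtype=float)
        if self.years.size == 0:
            raise ValueError(f"tree {self.tree_id}: empty ring series")
        if self.years.size != self.rw_mm.size:
            raise ValueError(f"tree {self.tree_id}: years and rw length differ")
        if not np.all(np.diff(self.years) == 1):
            raise ValueError(
                f"tree {self.tree_id}: years must be contiguous and increasing"
            )
        present = ~np.isnan(self.rw_mm)
        if np.any(self.rw_mm[present] <= 0):
            raise ValueError(f"tree {self.tree_id}: non-positive ring width")
        if self.imputed is None:
            self.imputed = np.zeros(self.years.size, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)

    @property
    def sampling_year(self) -> int:
        return int(self.years[-1])

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.rw_mm).sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0


def impute_missing_rings(series: RingSeries) -> RingSeries:
    """Fill missing rings by averaging measured widths around the gap.

    Each missing ring is replaced by the mean of the measured (non-missing)
    ring widths within the ``IMPUTE_WINDOW`` calendar years before and after
    it.  Fewer years are used near the series ends.  Only originally measured
    values enter the average, so consecutive gaps are imputed jointly and the
    result does not depend on fill-in order.

    Raises
    ------
    ValueError
        If the series has no measured rings at all, or if for some missing
        ring the surrounding window contains no measured value.
    """
    rw = series.rw_mm
    missing = np.isnan(rw)
    if not missing.any():
        return series
    if missing.all():
        raise ValueError(f"tree {series.tree_id}: all rings missing")

    filled = rw.copy()
    flags = series.imputed.copy()
    n = rw.size
    for i in np.flatnonzero(missing):
        lo = max(0, i - IMPUTE_WINDOW)
        hi = min(n, i + IMPUTE_WINDOW + 1)
        window = np.r_[rw[lo:i], rw[i + 1 : hi]]
        window = window[~np.isnan(window)]
        if window.size == 0:
            raise ValueError(
                f"tree {series.tree_id}: no measured ring within "
                f"{IMPUTE_WINDOW} years of missing ring {series.years[i]}"
            )
        filled[i] = window.mean()
        flags[i] = True
    return replace(series, rw_mm=filled, imputed=flags)


def reconstruct_dbh(series: RingSeries) -> np.ndarray:
    """Reconstruct end-of-year DBH (cm) by backward subtraction of 2x ring width.

    The DBH in the sampling year equals the measured sampling DBH; stepping
    backwards, each earlier year's DBH is the later one minus twice that
    later year's ring width.  The diameter remaining inside the first ring
    (sampling DBH minus twice the total ring-width sum) is the
    distance-to-pith allowance; after imputation it may undershoot zero by a
    little, but any truly negative end-of-year DBH signals inconsistent
    inputs.

    Returns an array aligned with ``series.years``.
    """
    if not series.is_complete:
        raise ValueError(
            f"tree {series.tree_id}: impute missing rings before DBH reconstruction"
        )
    incr_cm = 2.0 * mm_to_cm(series.rw_mm)
    # dbh[k] = sampling_dbh - sum of increments after year k
    dbh = series.sampling_dbh_cm - (incr_cm[::-1].cumsum()[::-1] - incr_cm)
    if np.any(dbh < -1e-9):
        raise ValueError(
            f"tree {series.tree_id}: negative reconstructed DBH "
            f"(sampling DBH {series.sampling_dbh_cm:.2f} cm inconsistent with "
            "ring widths)"
        )
    return np.maximum(dbh, 0.0)


@dataclass
class HeightTrajectory:
    """Annual DBH and interpolated height for one tree."""

    tree_id: str
    years: np.ndarray
    dbh_cm: np.ndarray
    height_m: np.ndarray
    slope_m_per_cm: float
    imputed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": self.tree_id,
                "year": self.years,
                "dbh_cm": self.dbh_cm,
                "height_m": self.height_m,
                "imputed_flag": self.imputed.astype(int),
            }
        )


def interpolate_height(series: RingSeries, dbh_cm: np.ndarray) -> HeightTrajectory:
    """Interpolate annual tree height linearly in reconstructed DBH.

    The line is anchored at the coring height for a hypothetical DBH of zero
    and at the measured total height for the sampling-year DBH, so the slope
    for tree *i* is ``(sampling height - coring height) / sampling DBH``
    (m per cm) and ``h_it = h_i0 + a_i * DBH_it``.
    """
    if series.sampling_dbh_cm <= 0:
        raise ValueError(f"tree {series.tree_id}: sampling DBH must be positive")
    if series.sampling_height_m < series.coring_height_m:
        raise ValueError(
            f"tree {series.tree_id}: sampling height below coring height"
        )
    a_i = (series.sampling_height_m - series.coring_height_m) / series.sampling_dbh_cm
    height = series.coring_height_m + a_i * np.asarray(dbh_cm, dtype=float)
    return HeightTrajectory(
        tree_id=series.tree_id,
        years=series.years.copy(),
        dbh_cm=np.asarray(dbh_cm, dtype=float),
        height_m=height,
        slope_m_per_cm=a_i,
        imputed=series.imputed.copy(),
    )


def reconstruct_heights(series_list: list[RingSeries]) -> pd.DataFrame:
    """Impute, reconstruct DBH and interpolate height for a set of trees.

    Returns the long table written to ``heights.csv``:
    tree_id, year, dbh_cm, height_m, imputed_flag.
    """
    frames = []
    for series in series_list:
        complete = impute_missing_rings(series)
        dbh = reconstruct_dbh(complete)
        traj = interpolate_height(complete, dbh)
        frames.append(traj.to_frame())
    if not frames:
        return pd.DataFrame(
            columns=["tree_id", "year", "dbh_cm", "height_m", "imputed_flag"]
        )
    return pd.concat(frames, ignore_index=True)
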