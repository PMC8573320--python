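"""Readers and writers for the on-disk formats used by the pipeline.

Ring widths travel either as Tucson decadal text (``.rwl``, integer units of
0.01 mm, per-series stop marker) or as a long CSV (tree_id, year, rw_mm).
Cell tables, climate tables and tree metadata are plain CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from xylemkit.ring_series import RingSeries
from xylemkit.units import RWL_SCALE

#: stop markers accepted when parsing Tucson files; the first is written
RWL_STOP = (999, -9999)
#: in-file code for a missing (locally absent) ring
RWL_MISSING = 0

#: canonical cell-table columns, in writing order
CELL_COLUMNS = [
    "tree_id",
    "year",
    "la_um2",
    "ld_rad_um",
    "ld_tan_um",
    "cwt_rad_um",
    "cwt_tan_um",
    "cwa_um2",
    "wall_len_rad_um",
    "wall_len_tan_um",
]

#: ROXAS-style export headers mapped onto canonical names; extend via the
#: ``header_map`` argument of :func:`read_cells`
DEFAULT_HEADER_MAP = {
    "ID": "tree_id",
    "YEAR": "year",
    "LA": "la_um2",
    "DRAD": "ld_rad_um",
    "DTAN": "ld_tan_um",
    "CWTRAD": "cwt_rad_um",
    "CWTTAN": "cwt_tan_um",
    "CWA": "cwa_um2",
    "WALLLENRAD": "wall_len_rad_um",
    "WALLLENTAN": "wall_len_tan_um",
}


def write_rwl(series_list: list[RingSeries], path) -> None:
    """Write ring-width series in Tucson decadal layout.

    Each line holds an 8-character series ID, the decade's first year, and up
    to ten 6-character integer values in 0.01 mm; a ``999`` stop marker
    follows the final value of each series.  Missing rings are coded ``0``.
    """
    with open(path, "w") as fh:
        for s in series_list:
            sid = str(s.tree_id)[:8]
            vals = [
                RWL_MISSING if np.isnan(w) else int(round(w * RWL_SCALE))
                for w in s.rw_mm
            ]
            vals.append(RWL_STOP[0])
            years = list(range(int(s.years[0]), int(s.years[0]) + len(vals)))
            i = 0
            while i < len(vals):
                decade_end = (years[i] // 10 + 1) * 10
                j = i
                fields = []
                while j < len(vals) and years[j] < decade_end:
                    fields.append(f"{vals[j]:6d}")
                    j += 1
                fh.write(f"{sid:<8s}{years[i]:4d}" + "".join(fields) + "\n")
                i = j


def read_rwl(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Parse a Tucson ``.rwl`` file.

    Returns ``{series_id: (years, rw_mm)}`` with missing rings as ``nan``.
    Both ``999`` and ``-9999`` are accepted as stop markers.
    """
    raw: dict[str, list[tuple[int, float]]] = {}
    stopped: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            sid = line[:8].strip()
            year = int(line[8:12])
            body = line[12:].rstrip("\n")
            fields = [body[k : k + 6] for k in range(0, len(body), 6)]
            for off, f in enumerate(fields):
                f = f.strip()
                if not f:
                    continue
                v = int(f)
                if v in RWL_STOP and sid not in stopped:
                    stopped.add(sid)
                    break
                if sid in stopped:
                    break
                w = np.nan if v <= 0 else v / RWL_SCALE
                raw.setdefault(sid, []).append((year + off, w))
    out = {}
    for sid, pairs in raw.items():
        pairs.sort()
        years = np.array([p[0] for p in pairs], dtype=int)
        rw = np.array([p[1] for p in pairs], dtype=float)
        out[sid] = (years, rw)
    return out


def rings_to_long(series_list: list[RingSeries]) -> pd.DataFrame:
    """Long-format ring table (tree_id, year, rw_mm); missing rings as NaN."""
    frames = [
        pd.DataFrame({"tree_id": s.tree_id, "year": s.years, "rw_mm": s.rw_mm})
        for s in series_list
    ]
    return pd.concat(frames, ignore_index=True)


def series_from_long(
    rings: pd.DataFrame, trees: pd.DataFrame
) -> list[RingSeries]:
    """Assemble :class:`RingSeries` objects from long rings + tree metadata.

    ``trees`` must carry tree_id, coring_height_m, dbh_cm, height_m (at
    sampling) and optionally pith_offset_cm.
    """
    meta = trees.set_index("tree_id")
    out = []
    for tid, grp in rings.groupby("tree_id", sort=True):
        grp = grp.sort_values("year")
        row = meta.loc[tid]
        out.append(
            RingSeries(
                tree_id=str(tid),
                years=grp["year"].to_numpy(),
                rw_mm=grp["rw_mm"].to_numpy(),
                coring_height_m=float(row["coring_height_m"]),
                sampling_dbh_cm=float(row["dbh_cm"]),
                sampling_height_m=float(row["height_m"]),
                pith_offset_cm=float(row.get("pith_offset_cm", 0.0)),
            )
        )
    return out


def read_cells(path, header_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a cell-level anatomy CSV, renaming known headers to canonical ones.

    Rows flagged non-tracheid (optional boolean/0-1 column ``tracheid``) are
    dropped: derived traits are defined for tracheids only.
    """
    df = pd.read_csv(path)
    mapping = dict(DEFAULT_HEADER_MAP)
    if header_map:
        mapping.update(header_map)
    df = df.rename(columns={c: mapping.get(c, c) for c in df.columns})
    if "tracheid" in df.columns:
        df = df[df["tracheid"].astype(bool)].drop(columns=["tracheid"])
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table lacks columns: {missing}")
    return df.reset_index(drop=True)


def read_climate(path) -> pd.DataFrame:
    """Read monthly climate CSV (site, year, month, tmean_c, prcp_mm)."""
    df = pd.read_csv(path)
    need = ["site", "year", "month", "tmean_c", "prcp_mm"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"climate table lacks columns: {missing}")
    return df


def read_trees(path) -> pd.DataFrame:
    """Read tree metadata CSV (tree_id, site, coring_height_m, sampling_year,
    dbh_cm, height_m)."""
    df = pd.read_csv(path)
    need = ["tree_id", "site", "coring_height_m", "sampling_year", "dbh_cm", "height_m"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"tree table lacks columns: {missing}")
    return df
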