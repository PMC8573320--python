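"""Shared fixtures: a small synthetic study and toy mixed-model frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from xylemkit.climate_season import aggregate_seasons
from xylemkit.pipeline import assemble_model_data
from xylemkit.ring_series import reconstruct_heights
from xylemkit.synthetic import (
    CellGeometryProfile,
    SiteConfig,
    SyntheticConfig,
    generate_dataset,
)
from xylemkit.xylem_traits import build_chronology


def small_sites(n_trees: int = 2) -> list[SiteConfig]:
    from xylemkit.synthetic import default_sites

    sites = default_sites()
    for s in sites:
        s.n_trees = n_trees
    return sites


def small_config(**overrides) -> SyntheticConfig:
    """A fast, reduced-size synthetic study for unit tests."""
    kw = dict(
        sites=small_sites(),
        climate_years=(1970, 2015),
        sampling_year=2015,
        age_range=(40, 46),
        anatomy_years=30,
        profile=CellGeometryProfile(cells_per_ring=12),
        missing_ring_prob=0.02,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(42, small_config())


@pytest.fixture(scope="session")
def model_data(small_dataset):
    ds = small_dataset
    heights = reconstruct_heights(ds.ring_series)
    chronology = build_chronology(ds.cells)
    seasonal = aggregate_seasons(ds.climate)
    return assemble_model_data(chronology, heights, seasonal, ds.trees)


def toy_frame(
    rng: np.random.Generator,
    n_trees: int = 4,
    n_years: int = 6,
    n_sites: int = 3,
    climate: tuple[str, ...] = ("summer_temp", "spring_prcp"),
    year_gaps: bool = False,
) -> pd.DataFrame:
    """A small balanced frame with arbitrary (already 'standardized')
    predictors for likelihood-level tests."""
    rows = []
    sites = [f"S{k}" for k in range(n_sites)]
    for i in range(n_trees):
        years = np.arange(2000, 2000 + n_years)
        if year_gaps and n_years > 3:
            years = np.delete(years, rng.integers(1, n_years - 1))
        h = np.sort(rng.normal(0, 1, len(years)))
        for t, y in enumerate(years):
            row = {
                "tree_id": f"T{i}",
                "year": int(y),
                "site": sites[i % n_sites],
                "h": h[t],
                "h2": h[t] ** 2 - 1.0,
            }
            for c in climate:
                row[c] = rng.normal()
            rows.append(row)
    df = pd.DataFrame(rows)
    df["y"] = rng.normal(size=len(df))
    return df
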