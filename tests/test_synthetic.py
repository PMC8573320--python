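"""Generator correctness: determinism, zero-noise limits, trend and
autocorrelation structure, and recoverability of injected effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter
from scipy.stats import spearmanr

from tests.conftest import small_config, small_sites
from xylemkit.synthetic import (
    SiteConfig,
    SyntheticConfig,
    TraitTruth,
    TruthParams,
    WeibullParams,
    default_sites,
    generate_climate,
    generate_dataset,
    generate_trees,
)


class TestClimate:
    def test_row_count(self):
        tab = generate_climate(default_sites(), range(1970, 2017), seed=1)
        assert len(tab) == 3 * 47 * 12

    def test_zero_noise_reproduces_monthly_normals(self):
        sites = default_sites()
        for s in sites:
            s.temp_sd = 0.0
            s.precip_cv = 0.0
        tab = generate_climate(sites, range(2000, 2003), seed=4)
        jan = tab[(tab.site == "W-D") & (tab.month == 1)]
        assert np.allclose(jan["tmean_c"], sites[0].monthly_temp_means[0])
        jul = tab[(tab.site == "C-M") & (tab.month == 7)]
        assert np.allclose(jul["prcp_mm"], sites[2].monthly_precip_means[6])

    def test_same_seed_identical(self):
        a = generate_climate(default_sites(), range(1990, 2000), seed=9)
        b = generate_climate(default_sites(), range(1990, 2000), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_precipitation_nonnegative(self):
        sites = default_sites()
        for s in sites:
            s.precip_cv = 2.0  # heavy spread to exercise truncation
        tab = generate_climate(sites, range(1950, 2000), seed=2)
        assert (tab["prcp_mm"] >= 0).all()

    def test_empty_years_raise(self):
        with pytest.raises(ValueError, match="empty year range"):
            generate_climate(default_sites(), [], seed=0)


class TestTrees:
    def test_no_missing_when_probability_zero(self):
        cfg = small_config(missing_ring_prob=0.0)
        _, series, truths = generate_trees(cfg, seed=3)
        assert all(s.is_complete for s in series)
        assert all(not t.missing_mask.any() for t in truths.values())

    def test_noise_free_height_follows_allometry(self):
        cfg = small_config(height_noise_sd_m=0.0)
        trees, _, _ = generate_trees(cfg, seed=5)
        for _, row in trees.iterrows():
            params = cfg.allometries[row["site"]]
            assert row["height_m"] == pytest.approx(
                float(params.height(row["dbh_cm"])), rel=1e-12
            )

    def test_sampling_dbh_is_twice_ring_sum_plus_pith(self):
        cfg = small_config(pith_offset_cm=0.9)
        _, series, truths = generate_trees(cfg, seed=6)
        for s in series:
            total = truths[s.tree_id].rw_true_mm.sum()
            assert s.sampling_dbh_cm == pytest.approx(2 * total / 10 + 0.9)

    def test_ring_width_declines_with_cambial_age(self):
        cfg = SyntheticConfig(
            sites=small_sites(4), age_range=(60, 70), missing_ring_prob=0.0
        )
        _, _, truths = generate_trees(cfg, seed=8)
        rhos = []
        for t in truths.values():
            rw = t.rw_true_mm[:50]
            rho, _ = spearmanr(np.arange(rw.size), rw)
            rhos.append(rho)
        assert np.mean(rhos) < 0

    def test_determinism(self):
        cfg = small_config()
        a = generate_trees(cfg, seed=11)[0]
        b = generate_trees(cfg, seed=11)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_zero_trees_rejected(self):
        with pytest.raises(ValueError, match="n_trees"):
            SiteConfig(
                "X",
                monthly_temp_means=tuple([0.0] * 12),
                monthly_precip_means=tuple([10.0] * 12),
                n_trees=0,
            )


def flat_truth(**kw) -> TruthParams:
    """All-zero effect truth around the default intercepts."""
    from xylemkit.synthetic import default_truth

    truth = default_truth()
    for tt in truth.traits.values():
        tt.beta_height = 0.0
        tt.beta_height2 = 0.0
        tt.site_offsets = {}
        tt.beta_climate = {}
        tt.beta_site_climate = {}
        tt.sigma_resid = 0.0
        tt.within_ring_sd = 0.0
    truth.re_sd_intercept = 0.0
    truth.re_sd_h = 0.0
    truth.re_sd_h2 = 0.0
    truth.phi = 0.0
    truth.sigma_tree = None
    for k, v in kw.items():
        setattr(truth, k, v)
    return truth


class TestCells:
    def test_all_zero_truth_gives_constant_ew_means(self):
        truth = flat_truth()
        cfg = small_config(truth=truth, sigma_tree_lognorm_sd=0.0)
        cfg.profile.lumen_gradient = 0.0
        cfg.profile.wall_gradient = 0.0
        ds = generate_dataset(21, cfg)
        ew = ds.truth_means[ds.truth_means.portion == "ew"]
        assert np.allclose(ew["la"], truth.traits["la_ew"].intercept)
        from xylemkit.xylem_traits import build_chronology

        chron = build_chronology(ds.cells)
        ew_obs = chron[chron.portion == "ew"]
        assert np.allclose(ew_obs["la"], truth.traits["la_ew"].intercept, rtol=1e-9)

    def test_height_slope_recovered_by_ols(self):
        """Injecting only a height effect, OLS of EW LA means on
        standardized height recovers the slope."""
        truth = flat_truth()
        truth.traits["la_ew"].beta_height = 1.0
        truth.traits["la_ew"].within_ring_sd = 0.5
        cfg = SyntheticConfig(
            sites=small_sites(6),
            truth=truth,
            sigma_tree_lognorm_sd=0.0,
            missing_ring_prob=0.0,
            anatomy_years=80,
        )
        ds = generate_dataset(23, cfg)
        ew = ds.truth_means[ds.truth_means.portion == "ew"].reset_index(drop=True)
        frame = []
        for tid, tt in ds.tree_truths.items():
            sel = np.isin(tt.years, ew[ew.tree_id == tid]["year"])
            frame.append(
                pd.DataFrame(
                    {"tree_id": tid, "year": tt.years[sel], "h": tt.height_true_m[sel]}
                )
            )
        merged = ew.merge(pd.concat(frame), on=["tree_id", "year"])
        h = merged["h"].to_numpy()
        hz = (h - h.mean()) / h.std(ddof=1)
        slope = np.polyfit(hz, merged["la"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_ar1_residual_autocorrelation(self):
        """A long AR1(0.5) residual stream has lag-1 autocorrelation 0.5."""
        rng = np.random.default_rng(31)
        phi, n = 0.5, 10_000
        shocks = np.concatenate(
            [[rng.normal(0.0, 1.0)], rng.normal(0.0, np.sqrt(1 - phi**2), n - 1)]
        )
        e = lfilter([1.0], [1.0, -phi], shocks)
        r1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert r1 == pytest.approx(phi, abs=0.03)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            TruthParams(traits={}, phi=1.2)

    def test_cell_geometry_internally_consistent(self, small_dataset):
        """Wall area implied by density tracks the rectangular-geometry
        wall area (perimeter x thickness): centred near 1, and within a
        factor 2.5 for 95% of cells at default noise."""
        cells = small_dataset.cells
        geo = (
            cells.ld_rad_um + 2 * cells.cwt_rad_um
        ) * (cells.ld_tan_um + 2 * cells.cwt_tan_um) - cells.la_um2
        ratio = cells.cwa_um2 / geo
        assert 0.75 < ratio.median() < 1.33
        assert ratio.between(0.4, 2.5).mean() > 0.95

    def test_dataset_determinism_and_seed_sensitivity(self):
        cfg = small_config()
        a = generate_dataset(42, cfg)
        b = generate_dataset(42, small_config())
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.climate, b.climate)
        c = generate_dataset(43, small_config())
        assert not a.cells["la_um2"].equals(c.cells["la_um2"])

    def test_write_round_trip(self, small_dataset, tmp_path):
        from xylemkit.io import read_cells, read_climate, read_rwl, read_trees

        small_dataset.write(tmp_path)
        cells = read_cells(tmp_path / "cells.csv")
        assert len(cells) == len(small_dataset.cells)
        trees = read_trees(tmp_path / "trees.csv")
        assert len(trees) == len(small_dataset.trees)
        rwl = read_rwl(tmp_path / "rings.rwl")
        assert len(rwl) == len(small_dataset.ring_series)
        s0 = small_dataset.ring_series[0]
        years, rw = rwl[s0.tree_id]
        np.testing.assert_array_equal(years, s0.years)
        # rwl stores 0.01 mm integers; missing rings come back as NaN
        mask = ~np.isnan(s0.rw_mm)
        np.testing.assert_allclose(rw[mask], s0.rw_mm[mask], atol=0.005 + 1e-9)
        assert np.isnan(rw[~mask]).all()
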