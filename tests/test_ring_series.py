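"""Missing-ring imputation, DBH back-calculation and height interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xylemkit.ring_series import (
    IMPUTE_WINDOW,
    RingSeries,
    impute_missing_rings,
    interpolate_height,
    reconstruct_dbh,
    reconstruct_heights,
)


def make_series(rw, sampling_dbh=None, coring=1.3, height=6.0, start=2000, **kw):
    rw = np.asarray(rw, dtype=float)
    if sampling_dbh is None:
        sampling_dbh = 2.0 * np.nansum(rw) / 10.0 + 1.0
    return RingSeries(
        tree_id="T1",
        years=np.arange(start, start + rw.size),
        rw_mm=rw,
        coring_height_m=coring,
        sampling_dbh_cm=sampling_dbh,
        sampling_height_m=height,
        **kw,
    )


def brute_force_impute(rw):
    """Windowed-mean oracle: mean of measured values within 10 calendar
    years on each side of the gap."""
    rw = np.asarray(rw, dtype=float)
    out = rw.copy()
    for i in np.flatnonzero(np.isnan(rw)):
        vals = []
        for j in range(max(0, i - IMPUTE_WINDOW), min(rw.size, i + IMPUTE_WINDOW + 1)):
            if j != i and not np.isnan(rw[j]):
                vals.append(rw[j])
        out[i] = np.mean(vals)
    return out


class TestImputation:
    def test_constant_series_gap_imputes_constant(self):
        rw = np.full(21, 1.0)
        rw[10] = np.nan
        filled = impute_missing_rings(make_series(rw))
        assert filled.rw_mm[10] == pytest.approx(1.0)
        assert filled.imputed[10] and filled.imputed.sum() == 1

    def test_full_window_mean(self):
        # widths 1..10 before the gap and 12..21 after: mean = (55+165)/20
        rw = np.concatenate([np.arange(1.0, 11.0), [np.nan], np.arange(12.0, 22.0)])
        filled = impute_missing_rings(make_series(rw))
        assert filled.rw_mm[10] == pytest.approx(11.0)

    def test_edge_gap_uses_available_years(self):
        # gap in year 3: only 2 prior values exist; 10 following are used
        rw = np.concatenate([[1.0, 2.0], [np.nan], np.full(12, 4.0)])
        filled = impute_missing_rings(make_series(rw))
        expected = (1.0 + 2.0 + 10 * 4.0) / 12.0
        assert filled.rw_mm[2] == pytest.approx(expected)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="all rings missing"):
            impute_missing_rings(make_series(np.full(5, np.nan), sampling_dbh=5.0))

    def test_empty_window_names_year(self):
        rw = np.full(30, np.nan)
        rw[0] = 1.0
        rw[-1] = 1.0
        # the first gap whose window holds no measured ring is year 2011
        with pytest.raises(ValueError, match="2011"):
            impute_missing_rings(make_series(rw, sampling_dbh=5.0, start=2000))

    def test_consecutive_gaps_do_not_feed_each_other(self):
        rw = np.array([2.0] * 8 + [np.nan, np.nan] + [4.0] * 8)
        filled = impute_missing_rings(make_series(rw))
        oracle = brute_force_impute(rw)
        np.testing.assert_allclose(filled.rw_mm, oracle)

    @settings(max_examples=100, deadline=None)
    @given(
        rw=st.lists(
            st.floats(min_value=0.05, max_value=9.0, allow_nan=False),
            min_size=3,
            max_size=40,
        ),
        gaps=st.sets(st.integers(min_value=0, max_value=39), max_size=8),
    )
    def test_matches_brute_force_oracle(self, rw, gaps):
        rw = np.asarray(rw)
        gaps = {g for g in gaps if g < rw.size}
        if len(gaps) >= rw.size:
            return
        full = rw.copy()
        for g in gaps:
            full[g] = np.nan
        oracle = brute_force_impute(full)
        if np.isnan(oracle).any():  # some window entirely missing
            with pytest.raises(ValueError):
                impute_missing_rings(make_series(full, sampling_dbh=99.0))
            return
        filled = impute_missing_rings(make_series(full, sampling_dbh=99.0))
        np.testing.assert_allclose(filled.rw_mm, oracle, rtol=0, atol=1e-12)


class TestDbhReconstruction:
    def test_hand_recursion(self):
        # five 1.0 cm rings (10 mm), sampling DBH 10 cm -> 10, 8, 6, 4, 2
        s = make_series(np.full(5, 10.0), sampling_dbh=10.0)
        np.testing.assert_allclose(reconstruct_dbh(s), [2.0, 4.0, 6.0, 8.0, 10.0])

    def test_telescoping_identity(self):
        rng = np.random.default_rng(0)
        rw = rng.uniform(0.2, 3.0, 40)
        s = make_series(rw, sampling_dbh=2 * rw.sum() / 10 + 0.7)
        dbh = reconstruct_dbh(s)
        # diameter left inside the innermost ring = sampling DBH - 2*sum(rw)
        assert dbh[0] - 2 * rw[0] / 10 == pytest.approx(
            s.sampling_dbh_cm - 2 * rw.sum() / 10
        )
        assert dbh[-1] == pytest.approx(s.sampling_dbh_cm)

    def test_monotone_for_positive_widths(self):
        rng = np.random.default_rng(1)
        rw = rng.uniform(0.1, 4.0, 60)
        s = make_series(rw, sampling_dbh=2 * rw.sum() / 10 + 0.2)
        assert np.all(np.diff(reconstruct_dbh(s)) >= 0)

    def test_inconsistent_inputs_raise(self):
        s = make_series(np.full(5, 10.0), sampling_dbh=3.0)
        with pytest.raises(ValueError, match="negative reconstructed DBH"):
            reconstruct_dbh(s)

    def test_incomplete_series_rejected(self):
        rw = np.array([1.0, np.nan, 1.0])
        with pytest.raises(ValueError, match="impute"):
            reconstruct_dbh(make_series(rw, sampling_dbh=5.0))


class TestHeightInterpolation:
    def test_linear_interpolation_example(self):
        # coring 1.3 m, sampling 5.3 m at DBH 8 cm -> slope 0.5 m/cm
        s = make_series(np.full(4, 10.0), sampling_dbh=8.0, height=5.3)
        traj = interpolate_height(s, np.array([0.0, 4.0, 8.0, 8.0]))
        assert traj.slope_m_per_cm == pytest.approx(0.5)
        np.testing.assert_allclose(traj.height_m, [1.3, 3.3, 5.3, 5.3])

    def test_endpoints_reproduced(self):
        rng = np.random.default_rng(2)
        rw = rng.uniform(0.3, 2.0, 30)
        s = make_series(rw, sampling_dbh=2 * rw.sum() / 10, height=7.7, coring=0.8)
        dbh = reconstruct_dbh(s)
        traj = interpolate_height(s, dbh)
        assert traj.height_m[-1] == pytest.approx(7.7)
        # hypothetical DBH 0 maps to the coring height
        assert interpolate_height(s, np.zeros(30)).height_m[0] == pytest.approx(0.8)

    def test_sampling_below_coring_raises(self):
        s = make_series(np.full(3, 5.0), height=0.5, coring=1.3)
        with pytest.raises(ValueError, match="below coring height"):
            interpolate_height(s, np.arange(3.0))


class TestRoundTrip:
    def test_zero_noise_generator_round_trip(self):
        """With no missing rings and no pith offset, reconstruction returns
        the generator's true DBH and height trajectories exactly."""
        from tests.conftest import small_config
        from xylemkit.synthetic import generate_dataset

        cfg = small_config(missing_ring_prob=0.0, height_noise_sd_m=0.0)
        ds = generate_dataset(7, cfg)
        heights = reconstruct_heights(ds.ring_series)
        for tid, tt in ds.tree_truths.items():
            got = heights[heights.tree_id == tid].sort_values("year")
            np.testing.assert_allclose(
                got["dbh_cm"].to_numpy(), tt.dbh_true_cm, rtol=0, atol=1e-10
            )
            np.testing.assert_allclose(
                got["height_m"].to_numpy(), tt.height_true_m, rtol=0, atol=1e-10
            )
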