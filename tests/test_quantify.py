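"""Measurement procedures: profiles, loop sizes, rates, MSD, flow speed."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import dna_polyline_px
from loopblock import quantify as q
from loopblock import synthetic as syn
from loopblock.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    OutOfFieldError,
    UndefinedMeasurementError,
)


class TestExtractProfile:
    def test_uniform_image_gives_zero_profile(self):
        img = np.full((40, 40), 7.5)
        poly = np.array([[5.0, 20.0], [35.0, 20.0]])
        prof = q.extract_profile(img, poly)
        assert np.allclose(prof.intensity, 0.0)
        assert np.all(np.diff(prof.arc_position_um) > 0)

    def test_single_loop_plateau_is_twice_the_tether_level(
        self, nontopo_kin, nontopo_noiseless, optics
    ):
        poly = dna_polyline_px(nontopo_kin, optics)
        prof = q.extract_profile(nontopo_noiseless.dna[-1], poly, 11, optics.pixel_size_um)
        a1 = np.asarray(nontopo_kin.geometry["anchor1_um"])
        stem = np.asarray(nontopo_kin.geometry["stem_um"])
        arm = float(np.hypot(*(stem - a1)))
        rel_px = (prof.arc_position_um - arm) / optics.pixel_size_um
        tether = np.median(prof.intensity[(rel_px < -8) & (rel_px > -14)])
        loop = np.median(prof.intensity[(rel_px > 3) & (rel_px < 8)])
        assert loop / tether == pytest.approx(2.0, rel=0.01)

    def test_double_loop_plateau_is_four_times_tether(
        self, pseudo_kin, pseudo_noiseless, optics
    ):
        poly = dna_polyline_px(pseudo_kin, optics)
        prof = q.extract_profile(pseudo_noiseless.dna[-1], poly, 11, optics.pixel_size_um)
        a1 = np.asarray(pseudo_kin.geometry["anchor1_um"])
        stem = np.asarray(pseudo_kin.geometry["stem_um"])
        arm = float(np.hypot(*(stem - a1)))
        rel_px = (prof.arc_position_um - arm) / optics.pixel_size_um
        tether = np.median(prof.intensity[(rel_px < -8) & (rel_px > -14)])
        # loop-2 is 6 kb -> ~3.9 px of doubled region; sample its interior
        near_stem = np.max(prof.intensity[(rel_px > 0.5) & (rel_px < 3)])
        assert near_stem / tether > 3.3

    def test_polyline_outside_image_rejected(self):
        with pytest.raises(OutOfFieldError):
            q.extract_profile(np.zeros((20, 20)), np.array([[5.0, 5.0], [30.0, 5.0]]))

    def test_even_width_rejected(self):
        with pytest.raises(InvalidArgumentError):
            q.extract_profile(np.zeros((20, 20)), np.array([[1.0, 1.0], [5.0, 5.0]]), width_px=10)


class TestLoopSizeFormula:
    def test_half_intensity_is_half_genome(self):
        assert q.loop_size_from_intensity(50.0, 100.0) == pytest.approx(24.25)

    def test_zero_loop_intensity(self):
        assert q.loop_size_from_intensity(0.0, 100.0) == 0.0

    @given(st.floats(0.01, 1.0), st.floats(1e-3, 1e6))
    def test_invariant_under_global_rescaling(self, frac, scale):
        base = q.loop_size_from_intensity(frac * 100.0, 100.0)
        scaled = q.loop_size_from_intensity(frac * 100.0 * scale, 100.0 * scale)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_total_is_undefined(self):
        with pytest.raises(UndefinedMeasurementError):
            q.loop_size_from_intensity(1.0, 0.0)

    def test_loop_exceeding_total_rejected(self):
        with pytest.raises(InvalidArgumentError):
            q.loop_size_from_intensity(101.0, 100.0)


class TestCalibration:
    def test_ten_pixels_is_one_point_o_eight_um(self):
        assert q.pixel_to_um(10) == pytest.approx(1.08)
        assert q.pixel_to_um(0) == 0.0

    def test_round_trip_identity(self):
        assert q.um_to_pixel(q.pixel_to_um(17.3)) == pytest.approx(17.3)

    def test_negative_rejected(self):
        with pytest.raises(InvalidArgumentError):
            q.pixel_to_um(-1.0)

    def test_distance_examples(self):
        assert q.roadblock_stem_distance((1.0, 1.0), (1.0, 1.0)) == 0.0
        assert q.roadblock_stem_distance((1.08, 0.0), (0.0, 0.0)) == pytest.approx(1.08)
        assert np.isnan(q.roadblock_stem_distance((np.nan, 0.0), (0.0, 0.0)))


class TestExtrusionRate:
    def test_linear_series_recovers_slope(self):
        loop = 0.5 * np.arange(60)
        rate = q.extrusion_rate(loop, 1.0)
        assert np.nanmean(rate) == pytest.approx(0.5, abs=1e-9)
        assert np.allclose(rate[np.isfinite(rate)], 0.5)

    def test_constant_series_gives_zero(self):
        rate = q.extrusion_rate(np.full(40, 12.0), 0.5)
        assert np.allclose(rate[np.isfinite(rate)], 0.0)

    def test_edges_are_truncated_not_padded(self):
        rate = q.extrusion_rate(0.5 * np.arange(40), 1.0, window=20)
        assert np.isnan(rate[:9]).all() and np.isnan(rate[-10:]).all()

    def test_noisy_recovery(self):
        rng = np.random.default_rng(5)
        loop = 0.5 * np.arange(120) + rng.normal(0, 1.0, 120)
        rate = q.extrusion_rate(loop, 1.0)
        assert np.nanmean(rate) == pytest.approx(0.5, abs=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            q.extrusion_rate(np.arange(10), 1.0, window=20)


def _brute_force_msd(xy, dt, max_lag):
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    n = np.zeros(max_lag + 1, dtype=int)
    n[0] = int(np.all(np.isfinite(xy), axis=1).sum())
    for tau in range(1, max_lag + 1):
        sq = []
        for i in range(len(xy) - tau):
            a, b = xy[i], xy[i + tau]
            if np.all(np.isfinite(a)) and np.all(np.isfinite(b)):
                sq.append((b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2)
        n[tau] = len(sq)
        msd[tau] = np.mean(sq) if sq else np.nan
    return lags * dt, msd, n


class TestMSD:
    def test_stationary_track_has_zero_msd(self):
        xy = np.zeros((30, 2))
        curve = q.msd_curve(xy, 0.5)
        assert np.allclose(curve.msd_um2, 0.0)

    def test_ballistic_track_matches_closed_form(self):
        v, dt = 0.07, 0.5
        t = np.arange(50) * dt
        xy = np.column_stack([v * t, np.zeros_like(t)])
        curve = q.msd_curve(xy, dt, max_lag=20)
        assert np.allclose(curve.msd_um2, (v * curve.lag_s) ** 2, rtol=1e-10)

    def test_matches_brute_force_pair_enumeration_with_gaps(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = rng.integers(5, 50)
            xy = rng.normal(0, 1, (n, 2))
            gaps = rng.random(n) < 0.2
            xy[gaps] = np.nan
            if np.all(np.isfinite(xy), axis=1).sum() < 2:
                continue
            curve = q.msd_curve(xy, 1.0, max_lag=n - 1)
            lag_b, msd_b, n_b = _brute_force_msd(xy, 1.0, n - 1)
            assert np.array_equal(curve.n_pairs, n_b)
            both = np.isfinite(curve.msd_um2) & np.isfinite(msd_b)
            assert np.allclose(curve.msd_um2[both], msd_b[both], rtol=1e-10)
            assert np.array_equal(np.isfinite(curve.msd_um2), np.isfinite(msd_b))

    def test_diffusive_track_slope_recovers_4d(self):
        rng = np.random.default_rng(3)
        D, dt = 0.05, 0.1
        xy = np.cumsum(rng.normal(0, np.sqrt(2 * D * dt), (10_000, 2)), axis=0)
        slope = q.fit_msd_slope(q.msd_curve(xy, dt, max_lag=10), 5)
        assert slope == pytest.approx(4 * D, rel=0.15)

    def test_all_gap_track_rejected(self):
        with pytest.raises(InsufficientDataError):
            q.msd_curve(np.full((10, 2), np.nan), 1.0)


class TestFlowSpeed:
    def test_noiseless_tracks_recover_exactly(self):
        tr = syn.make_flyby_tracks(79.0, 5, 8, 0.0, seed=0)
        est = q.estimate_flow_speed(tr)
        assert est.mean_um_s == pytest.approx(79.0, abs=1e-9)
        assert est.sd_um_s == pytest.approx(0.0, abs=1e-9)
        assert est.n_tracks == 5

    def test_two_tracks_average(self):
        rows = []
        for p, v in ((0, 50.0), (1, 100.0)):
            for f in range(4):
                rows.append({"particle": p, "frame": f, "time_s": f * 0.1,
                             "x_um": 0.0, "y_um": v * f * 0.1})
        est = q.estimate_flow_speed(pd.DataFrame(rows))
        assert est.mean_um_s == pytest.approx(75.0)

    def test_recovery_within_two_sem(self):
        tr = syn.make_flyby_tracks(79.0, 20, 10, 0.5, seed=0)
        est = q.estimate_flow_speed(tr)
        assert abs(est.mean_um_s - 79.0) <= 2 * est.sem_um_s

    def test_no_usable_track_rejected(self):
        df = pd.DataFrame({"particle": [0], "frame": [0], "time_s": [0.0],
                           "x_um": [0.0], "y_um": [0.0]})
        with pytest.raises(InsufficientDataError):
            q.estimate_flow_speed(df)


class TestLoopSeries:
    def test_noiseless_recovery_with_supplied_stem(
        self, nontopo_kin, nontopo_noiseless
    ):
        stem = nontopo_kin.frames[["stem_x_um", "stem_y_um"]].to_numpy()
        ser = q.measure_loop_series(nontopo_noiseless, stem_xy_um=stem)
        true = nontopo_kin.frames["total_loop_kb"].to_numpy()
        sel = true >= 6.0
        rel = (ser["loop_kb"].to_numpy()[sel] - true[sel]) / true[sel]
        assert np.abs(rel).max() < 0.02

    def test_loop_length_tracks_ground_truth(self, nontopo_kin, nontopo_noiseless):
        stem = nontopo_kin.frames[["stem_x_um", "stem_y_um"]].to_numpy()
        ser = q.measure_loop_series(nontopo_noiseless, stem_xy_um=stem)
        true = nontopo_kin.frames["loop_length_um"].to_numpy()
        sel = true > 0.8
        assert np.allclose(ser["loop_length_um"].to_numpy()[sel], true[sel], atol=0.2)

    def test_auto_stem_detection_close_to_truth(self, nontopo_kin, nontopo_noiseless):
        ser = q.measure_loop_series(nontopo_noiseless)
        i = len(ser) - 1
        truth = nontopo_kin.frames.iloc[i]
        assert abs(ser["stem_x_um"].iloc[i] - truth["stem_x_um"]) < 0.25
        assert abs(ser["stem_y_um"].iloc[i] - truth["stem_y_um"]) < 0.6

    def test_roadblock_distance_column(self, nontopo_kin, nontopo_noiseless):
        stem = nontopo_kin.frames[["stem_x_um", "stem_y_um"]].to_numpy()
        rb = nontopo_kin.frames[["roadblock_x_um", "roadblock_y_um"]].to_numpy()
        ser = q.measure_loop_series(nontopo_noiseless, stem_xy_um=stem, roadblock_xy_um=rb)
        truth = nontopo_kin.measurement_series()["roadblock_distance_um"]
        assert np.allclose(ser["roadblock_distance_um"], truth, atol=1e-9)
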