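"""Angle conventions, rates, heatmaps, and axis/onset calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from junctrack.kinematics import (angle_at_unit_length, angle_difference,
                                  calibrate, compute_rates, fold_angle,
                                  interface_angle, rate_heatmap,
                                  smooth_lengths, unwrap_angles)
from junctrack.synthetic import TrackGenParams, generate_interface_tracks
from junctrack.tracks import TrackSet, build_tracks_table


def _trackset_from_arrays(l_um, theta_deg, dt_frame=30.0):
    n = len(l_um)
    pf = pd.DataFrame({
        "track_id": np.zeros(n, dtype=int),
        "cell_a": np.zeros(n, dtype=int),
        "cell_b": np.ones(n, dtype=int),
        "frame": np.arange(n),
        "l_um": np.asarray(l_um, dtype=float),
        "theta_deg": np.asarray(theta_deg, dtype=float),
    })
    return TrackSet(pf, build_tracks_table(pf), dt_frame=dt_frame)


# ------------------------------------------------------------------- folding
class TestFoldAngle:
    def test_quadrants(self):
        assert fold_angle(0.0) == 0.0
        assert fold_angle(90.0) == 90.0
        assert fold_angle(-90.0) == 90.0        # half-open boundary
        assert fold_angle(180.0) == 0.0
        assert fold_angle(135.0) == -45.0
        assert fold_angle(-135.0) == 45.0

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-1e4, max_value=1e4))
    def test_idempotent_and_in_range(self, alpha):
        f = fold_angle(alpha)
        assert -90.0 < f <= 90.0
        assert fold_angle(f) == pytest.approx(f, abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-1e3, max_value=1e3))
    def test_period_180(self, alpha):
        assert fold_angle(alpha + 180.0) == pytest.approx(
            fold_angle(alpha), abs=1e-9)


class TestAngleDifference:
    def test_wraparound(self):
        assert angle_difference(80.0, -80.0) == pytest.approx(20.0)

    def test_zero(self):
        assert angle_difference(10.0, 10.0) == 0.0

    def test_boundary_tie_positive(self):
        assert angle_difference(-45.0, 45.0) == 90.0

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=-89.9, max_value=90.0),
           st.floats(min_value=-89.9, max_value=90.0))
    def test_antisymmetry_mod_tie(self, a, b):
        d1, d2 = angle_difference(a, b), angle_difference(b, a)
        if abs(d1) != 90.0:
            assert d1 == pytest.approx(-d2, abs=1e-9)


class TestInterfaceAngle:
    def test_vertical(self):
        assert interface_angle((0, 0), (0, 2)) == pytest.approx(0.0)

    def test_horizontal(self):
        assert interface_angle((0, 0), (2, 0)) == pytest.approx(90.0)

    def test_offset_cancels(self):
        assert interface_angle((0, 0), (1, 1), delta_deg=45.0) == \
            pytest.approx(0.0)

    def test_direction_independent(self):
        a = interface_angle((1, 2), (4, 7))
        b = interface_angle((4, 7), (1, 2))
        assert a == pytest.approx(b)

    def test_coincident_is_nan(self):
        assert np.isnan(interface_angle((3, 3), (3, 3)))

    def test_pixel_aspect(self):
        # anisotropic pixels: y twice as tall makes a 45° pixel diagonal steeper
        th = interface_angle((0, 0), (1, 1), pixel_aspect=2.0)
        assert th == pytest.approx(np.degrees(np.arctan2(1, 2)))


class TestUnwrap:
    def test_refold_reproduces(self):
        rng = np.random.default_rng(0)
        theta = fold_angle(np.cumsum(rng.normal(0, 30, 50)))
        unw = unwrap_angles(theta)
        assert np.allclose(fold_angle(unw), theta, atol=1e-9)

    def test_continuous_through_wrap(self):
        unw = unwrap_angles(np.array([80.0, 88.0, -88.0, -80.0]))
        assert np.allclose(np.diff(unw), [8.0, 4.0, 8.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=-89.0, max_value=90.0),
                    min_size=2, max_size=30))
    def test_refold_property(self, seq):
        # compare on the orientation circle: ±90 are the same orientation
        theta = np.asarray(seq)
        refold = fold_angle(unwrap_angles(theta))
        assert np.allclose(angle_difference(refold, theta), 0.0, atol=1e-6)


# --------------------------------------------------------------------- rates
class TestComputeRates:
    def test_contraction_rate(self):
        ts = compute_rates(_trackset_from_arrays([2.0, 1.5], [0.0, 0.0]))
        assert ts.per_frame["rl_um_min"].iloc[0] == pytest.approx(-1.0)
        assert np.isnan(ts.per_frame["rl_um_min"].iloc[1])

    def test_rotation_wraps(self):
        ts = compute_rates(_trackset_from_arrays([1.0, 1.0], [85.0, -85.0]))
        assert ts.per_frame["rtheta_deg_min"].iloc[0] == pytest.approx(20.0)

    def test_constant_track_zero(self):
        ts = compute_rates(_trackset_from_arrays([2.0] * 5, [30.0] * 5))
        rl = ts.per_frame["rl_um_min"].to_numpy()
        assert np.allclose(rl[:-1], 0.0) and np.isnan(rl[-1])

    def test_dt_must_divide(self):
        ts = _trackset_from_arrays([1.0, 1.0], [0.0, 0.0], dt_frame=25.0)
        with pytest.raises(ValueError, match="multiple"):
            compute_rates(ts, dt_s=30.0)

    def test_rate_representation_invariance(self):
        # rotation rate unchanged when an angle is re-represented by ±180°
        a = compute_rates(_trackset_from_arrays([1, 1], [40.0, 50.0]))
        b = compute_rates(_trackset_from_arrays(
            [1, 1], [fold_angle(40.0 - 180.0), 50.0]))
        assert a.per_frame["rtheta_deg_min"].iloc[0] == pytest.approx(
            b.per_frame["rtheta_deg_min"].iloc[0])

    def test_zero_noise_generator_rates_exact(self):
        params = TrackGenParams(n_interfaces=20, duration_min=5,
                                angle_noise_sd=0.0, length_noise_sd=0.0,
                                oscillation=None, seed=1)
        tracks, truth = generate_interface_tracks(params)
        rated = compute_rates(tracks, dt_s=30.0)
        merged = rated.per_frame.merge(
            truth.interfaces, on=["track_id", "frame"], suffixes=("", "_t"))
        ok = np.isfinite(merged["rl_um_min"])
        # forward-difference over one Euler step reproduces the applied rates
        assert np.allclose(merged.loc[ok, "rl_um_min"],
                           merged.loc[ok, "rate_l"], atol=1e-9)
        assert np.allclose(merged.loc[ok, "rtheta_deg_min"],
                           merged.loc[ok, "rate_theta"], atol=1e-9)


class TestSmoothing:
    def test_window_one_is_identity(self):
        x = np.array([1.0, 4.0, 2.0])
        assert np.array_equal(smooth_lengths(x, 1), x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_lengths(np.ones(5), 4)

    def test_centered_average(self):
        out = smooth_lengths(np.array([0.0, 3.0, 6.0, 9.0]), 3)
        assert out == pytest.approx([1.5, 3.0, 6.0, 7.5])

    def test_nan_tolerant(self):
        out = smooth_lengths(np.array([1.0, np.nan, 3.0]), 3)
        assert out[1] == pytest.approx(2.0)


# ------------------------------------------------------------------- heatmap
class TestRateHeatmap:
    def test_single_column(self):
        ts = compute_rates(_trackset_from_arrays(
            [3.0, 2.5, 2.0, 1.5], [0.0] * 4))
        field = rate_heatmap(ts, time_bin_min=2.0, angle_bin_deg=10.0)
        occupied = np.nonzero(np.isfinite(field.mean))
        cols = np.unique(occupied[1])
        assert len(cols) == 1
        assert np.allclose(field.mean[occupied], -1.0)

    def test_counts_conserve_samples(self, quiet_tracks):
        _, tracks, _ = quiet_tracks
        rated = compute_rates(tracks, dt_s=30.0)
        field = rate_heatmap(rated)
        pf = rated.per_frame
        n_defined = int((np.isfinite(pf["rl_um_min"]) &
                         np.isfinite(pf["theta_deg"])).sum())
        assert field.count.sum() == n_defined

    def test_empty_input_all_missing(self):
        ts = _trackset_from_arrays([1.0], [0.0])
        ts = compute_rates(ts)  # single frame → no rates
        field = rate_heatmap(ts)
        assert not np.isfinite(field.mean).any()

    def test_unknown_statistic_error(self):
        ts = compute_rates(_trackset_from_arrays([1.0, 1.0], [0.0, 0.0]))
        with pytest.raises(ValueError, match="absent"):
            rate_heatmap(ts, statistic="m")

    def test_sign_pattern_after_onset(self, quiet_tracks):
        _, tracks, _ = quiet_tracks
        rated = compute_rates(tracks, dt_s=30.0)
        field = rate_heatmap(rated, time_bin_min=5.0, angle_bin_deg=10.0)
        centers = field.angle_centers
        vertical = np.abs(centers) < 30.0
        horizontal = np.abs(centers) > 60.0
        row = field.mean[0]
        assert np.nanmean(row[vertical]) < 0.0
        assert np.nanmean(row[horizontal]) > 0.0


# --------------------------------------------------------------- calibration
class TestCalibration:
    def test_isotropic_tracks_no_onset(self):
        params = TrackGenParams(
            n_interfaces=100, duration_min=10,
            rate_l_law=lambda th: np.zeros_like(th),
            rate_theta_law=lambda th: np.zeros_like(th),
            angle_noise_sd=2.0, length_noise_sd=0.05,
            oscillation=None, seed=2)
        tracks, _ = generate_interface_tracks(params)
        rated = compute_rates(tracks, dt_s=30.0)
        calib = calibrate(rated)
        assert calib.t0_min is None

    def test_delta_in_range(self, small_tissue_tracks):
        tracks, _, _ = small_tissue_tracks
        rated = compute_rates(tracks, dt_s=30.0, smooth_window=3)
        calib = calibrate(rated)
        assert -90.0 < calib.delta_deg <= 90.0


# --------------------------------------------------- angle at unit length
class TestAngleAtUnitLength:
    def test_contracting(self):
        tf = pd.DataFrame({"frame": [0, 1, 2], "l_um": [1.4, 0.9, 0.3],
                           "theta_deg": [10.0, 8.0, np.nan]})
        assert angle_at_unit_length(tf, "contracting") == pytest.approx(10.0)

    def test_elongating(self):
        tf = pd.DataFrame({"frame": [0, 1, 2], "l_um": [0.4, 1.1, 1.8],
                           "theta_deg": [70.0, 80.0, 82.0]})
        assert angle_at_unit_length(tf, "elongating") == pytest.approx(80.0)

    def test_never_reaches(self):
        tf = pd.DataFrame({"frame": [0, 1, 2], "l_um": [0.4, 0.8, 0.6],
                           "theta_deg": [10.0, 10.0, 10.0]})
        assert np.isnan(angle_at_unit_length(tf, "contracting"))

    def test_bad_kind(self):
        tf = pd.DataFrame({"frame": [0], "l_um": [1.0], "theta_deg": [0.0]})
        with pytest.raises(ValueError, match="kind"):
            angle_at_unit_length(tf, "shrinking")
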