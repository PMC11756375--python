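"""Oscillation-phase extraction, cycle detection and ratchet curves."""

import numpy as np
import pandas as pd
import pytest

from junctrack.phase import (PHASE_GRID_DEG, PhaseSeries, _cycle_dl_on_grid,
                             detect_cycles, extract_phase,
                             phase_series_from_cell_table, ratchet_curve)
from junctrack.synthetic import (OscillationParams, TrackGenParams,
                                 generate_interface_tracks)


def _circ_err(a, b):
    """Absolute circular difference of two phase arrays (degrees)."""
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


class TestExtractPhase:
    def test_convention_on_random_sinusoids(self):
        # A(ϕ) = b − c·cos ϕ with ϕ = 360 t/T + ψ0: the assigned phase must
        # match the true phase within 10° away from the series endpoints
        rng = np.random.default_rng(42)
        for _ in range(50):
            period = rng.uniform(60.0, 240.0)
            dt = period / rng.integers(24, 60)
            b = rng.uniform(20.0, 60.0)
            c = rng.uniform(1.0, 6.0)
            psi0 = rng.uniform(0.0, 360.0)
            t = np.arange(0.0, 4.0 * period, dt)
            true_phase = (360.0 * t / period + psi0) % 360.0
            area = b - c * np.cos(np.radians(true_phase))
            series = extract_phase(area, dt)
            n_edge = int(round(period / dt))
            interior = slice(n_edge, -n_edge)
            err = _circ_err(series.phase_deg[interior], true_phase[interior])
            assert np.max(err) <= 10.0
            assert abs(series.period_s - period) / period <= 0.1

    def test_fastest_decrease_is_270(self):
        dt = 3.0
        t = np.arange(0.0, 360.0, dt)
        area = 10.0 - 2.0 * np.cos(2 * np.pi * t / 120.0)
        series = extract_phase(area, dt)
        dadt = np.gradient(area, dt)
        assert _circ_err(series.phase_deg[np.argmin(dadt)], 270.0) <= 10.0
        assert _circ_err(series.phase_deg[np.argmax(dadt)], 90.0) <= 10.0
        assert _circ_err(series.phase_deg[np.argmax(area)], 180.0) <= 10.0

    def test_noise_only_series_invalid(self):
        rng = np.random.default_rng(7)
        series = extract_phase(rng.normal(50.0, 0.5, 120), 5.0)
        assert not series.valid
        assert np.isnan(series.phase_deg).all()
        assert detect_cycles(series) == []

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="at least 4"):
            extract_phase(np.array([1.0, 2.0, 3.0]), 5.0)

    def test_shorter_than_one_period(self):
        # a pure trend: the dominant period exceeds the series duration
        area = 10.0 + 0.1 * np.arange(10)
        with pytest.raises(ValueError, match="shorter than"):
            extract_phase(area, 5.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="no detectable oscillation"):
            extract_phase(np.full(50, 30.0), 5.0)


class TestDetectCycles:
    def _series(self, n_periods=3.0, psi0=45.0, period=120.0, dt=5.0):
        t = np.arange(0.0, n_periods * period, dt)
        phase = (360.0 * t / period + psi0) % 360.0
        return extract_phase(40.0 - 3.0 * np.cos(np.radians(phase)), dt)

    def test_counts_complete_cycles(self):
        series = self._series(n_periods=3.4)
        cycles = detect_cycles(series)
        assert len(cycles) in (2, 3)

    def test_cycle_length_matches_period(self):
        series = self._series()
        for c0, c1 in detect_cycles(series):
            n = c1 - c0 + 1
            assert abs(n - 24) <= 2    # 120 s / 5 s per cycle

    def test_cycles_ordered_and_disjoint(self):
        cycles = detect_cycles(self._series(n_periods=4.0))
        for (a0, a1), (b0, b1) in zip(cycles, cycles[1:]):
            assert a1 < b0
            assert a0 <= a1


class TestDlOnGrid:
    def test_grid_is_40_points_9_deg(self):
        assert PHASE_GRID_DEG.shape == (40,)
        assert np.allclose(np.diff(PHASE_GRID_DEG), 9.0)
        assert PHASE_GRID_DEG[0] == 0.0
        assert PHASE_GRID_DEG[-1] == 351.0

    def test_origin_exactly_zero(self):
        phi = np.linspace(0.0, 355.0, 72)
        l = 3.0 + 0.2 * np.sin(np.radians(phi))
        dl = _cycle_dl_on_grid(phi, l)
        assert dl[0] == 0.0

    def test_interpolation_accuracy(self):
        phi = np.linspace(0.0, 359.0, 120)
        l = 4.0 + 0.4 * (1.0 - np.cos(np.radians(phi))) / 2.0
        dl = _cycle_dl_on_grid(phi, l)
        expect = 0.4 * (1.0 - np.cos(np.radians(PHASE_GRID_DEG))) / 2.0
        assert np.max(np.abs(dl - expect)) <= 0.02

    def test_too_few_samples(self):
        assert _cycle_dl_on_grid(np.array([0.0, 100.0]),
                                 np.array([1.0, 2.0])) is None


def _truth_phase_series(tracks, truth, period_s=120.0):
    """Ground-truth PhaseSeries per generator cell (cell id = track id)."""
    out = {}
    for tid, grp in truth.interfaces.groupby("track_id"):
        grp = grp.sort_values("frame")
        phase = np.full(int(tracks.per_frame["frame"].max()) + 1, np.nan)
        phase[grp["frame"].to_numpy(dtype=int)] = grp["phase_deg"].to_numpy()
        t_min = np.arange(len(phase)) * tracks.dt_frame / 60.0
        out[int(tid)] = PhaseSeries(int(tid), t_min, np.zeros_like(phase),
                                    phase, period_s, 1.0,
                                    np.zeros_like(phase), valid=True)
    return out


class TestRatchetCurve:
    def test_pure_excursion_reproduced(self):
        # no core dynamics: ΔL(ϕ) is exactly the oscillatory excursion
        params = TrackGenParams(
            n_interfaces=5, duration_min=6.0, dt_s=5.0,
            rate_l_law=lambda th: np.zeros_like(th),
            rate_theta_law=lambda th: np.zeros_like(th),
            angle_noise_sd=0.0, length_noise_sd=0.0,
            oscillation=OscillationParams(period_s=120.0, amplitude=0.2,
                                          ratchet_bias=0.0),
            theta0_deg=np.zeros(5), l0_range_um=(4.0, 4.0), seed=6)
        tracks, truth = generate_interface_tracks(params)
        ps = _truth_phase_series(tracks, truth)
        curves = ratchet_curve(tracks, ps)
        assert len(curves) == 1
        curve = curves[0]
        assert curve.angle_bin == (0.0, 30.0)
        assert curve.mean_dl_um[0] == 0.0
        expect = 0.2 * 4.0 * (1.0 - np.cos(np.radians(PHASE_GRID_DEG))) / 2.0
        assert np.max(np.abs(curve.mean_dl_um - expect)) <= 0.05

    def test_ratchet_asymmetry_vertical(self):
        # biased gate: the contraction half-cycle loses more length
        params = TrackGenParams(
            n_interfaces=8, duration_min=6.0, dt_s=5.0,
            angle_noise_sd=0.0, length_noise_sd=0.0,
            oscillation=OscillationParams(period_s=120.0, amplitude=0.05,
                                          ratchet_bias=0.8),
            theta0_deg=np.zeros(8), l0_range_um=(30.0, 30.0), seed=6)
        tracks, truth = generate_interface_tracks(params)
        curves = ratchet_curve(tracks, _truth_phase_series(tracks, truth))
        curve = curves[0]
        i180 = np.argmin(np.abs(PHASE_GRID_DEG - 180.0))
        first_half = curve.mean_dl_um[i180] - curve.mean_dl_um[0]
        second_half = curve.mean_dl_um[-1] - curve.mean_dl_um[i180]
        assert second_half < first_half
        assert curve.mean_dl_um[-1] < 0.0    # net loss over the cycle

    def test_sample_counts(self):
        params = TrackGenParams(
            n_interfaces=4, duration_min=6.0, dt_s=5.0,
            rate_l_law=lambda th: np.zeros_like(th),
            rate_theta_law=lambda th: np.zeros_like(th),
            angle_noise_sd=0.0, length_noise_sd=0.0,
            oscillation=OscillationParams(period_s=120.0, amplitude=0.2),
            theta0_deg=np.zeros(4), l0_range_um=(4.0, 4.0), seed=1)
        tracks, truth = generate_interface_tracks(params)
        ps = _truth_phase_series(tracks, truth)
        n_cycles = sum(len(detect_cycles(s)) for s in ps.values())
        curves = ratchet_curve(tracks, ps)
        assert sum(c.n_samples for c in curves) == n_cycles


class TestPhaseSeriesFromCellTable:
    def test_oscillating_cells_extracted(self):
        dt = 5.0
        t = np.arange(0.0, 600.0, dt)
        rows = []
        for cid, psi0 in ((1, 0.0), (2, 120.0)):
            area = 500.0 - 40.0 * np.cos(np.radians(360.0 * t / 120.0 + psi0))
            for f, a in enumerate(area):
                rows.append((cid, f, 0.0, 0.0, a))
        # a constant-area cell must be skipped, not crash
        for f in range(len(t)):
            rows.append((3, f, 0.0, 0.0, 400.0))
        table = pd.DataFrame(rows, columns=["cell_id", "frame", "x", "y",
                                            "area_px"])
        out = phase_series_from_cell_table(table, dt_s=dt)
        assert set(out) == {1, 2}
        assert all(s.valid for s in out.values())
        # relative phase offset between the two cells is preserved
        interior = slice(30, -30)
        d = _circ_err(out[2].phase_deg[interior], out[1].phase_deg[interior])
        assert np.median(d) == pytest.approx(120.0, abs=10.0)
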