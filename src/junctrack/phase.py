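"""Cell-area oscillation phase and phase-resolved interface-length ratchet.

Phase convention: the area time course relates to phase as
A(ϕ) = b − c·cos ϕ — ϕ = 0°/360° at the area minimum, ϕ = 180° at the area
maximum, fastest contraction (area decrease) at ϕ = 270°, fastest expansion
at ϕ = 90°; ϕ increases in time.

The extractor embeds the locally detrended area series in the
(c·cos ϕ, c·sin ϕ) plane — cosine axis b̂ − A with b̂ a rolling baseline,
sine axis the scaled time derivative — and reads ϕ = atan2(s·dA/dt, b̂ − A).
Any implementation meeting the convention above (within ±10° away from cycle
endpoints on clean sinusoids) is conforming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import TrackSet


@dataclass
class PhaseSeries:
    """Oscillation phase of one cell's area time course."""

    cell_id: int
    t_min: np.ndarray
    area: np.ndarray
    phase_deg: np.ndarray       # [0, 360)
    period_s: float             # dominant period estimate
    amplitude: float            # c, same units as area
    baseline: np.ndarray        # b̂(t)
    valid: bool = True          # False when amplitude is below the noise floor


def _dominant_period(x: np.ndarray, dt_s: float) -> float:
    """Dominant oscillation period via the discrete Fourier spectrum."""
    x = x - x.mean()
    n = x.size
    n_fft = 8 * n  # zero-pad for frequency resolution on short series
    spec = np.abs(np.fft.rfft(x * np.hanning(n), n=n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=dt_s)
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if freqs[k] == 0:
        raise ValueError("area series has no detectable oscillation")
    return float(1.0 / freqs[k])


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    window = max(3, window | 1)  # odd, >= 3
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def extract_phase(area: np.ndarray, dt_s: float, cell_id: int = -1,
                  smooth_window_s: float | None = None,
                  amplitude_floor_factor: float = 2.0) -> PhaseSeries:
    """Assign an oscillation phase to every sample of a cell-area series.

    The series is lightly smoothed, a rolling baseline b̂ of one period is
    removed, and the phase is the angle of (b̂ − A, s·dA/dt) with s chosen to
    equalize the RMS of the two embedding axes.  Cells whose oscillation
    amplitude c is below ``amplitude_floor_factor`` × the residual SD after
    removing the dominant sinusoid are flagged invalid (phase undefined).
    """
    area = np.asarray(area, dtype=float)
    if area.ndim != 1 or area.size < 4:
        raise ValueError("need a 1D area series with at least 4 samples")
    t_min = np.arange(area.size) * dt_s / 60.0

    period_s = _dominant_period(area, dt_s)
    if area.size * dt_s < 1.5 * period_s:
        # a windowed spectrum caps the period estimate at the series
        # duration, so a bare trend estimates period ≈ duration; demanding
        # 1.5 estimated periods separates oscillation from trend
        raise ValueError(
            "series shorter than 1.5 oscillation periods; cannot assign phases")
    if smooth_window_s is None:
        smooth_window_s = max(dt_s, period_s / 12.0)
    a_s = _rolling_mean(area, int(round(smooth_window_s / dt_s)))
    baseline = _rolling_mean(a_s, int(round(period_s / dt_s)))
    resid = a_s - baseline

    dadt = np.gradient(a_s, dt_s)
    rms_r = float(np.sqrt(np.mean(resid ** 2)))
    rms_d = float(np.sqrt(np.mean(dadt ** 2)))
    scale = rms_r / rms_d if rms_d > 0 else 1.0
    phase = np.degrees(np.arctan2(scale * dadt, -resid)) % 360.0

    # amplitude floor: fit the dominant sinusoid and compare to the leftover
    w = 2 * np.pi / period_s * (t_min * 60.0)
    design = np.stack([np.cos(w), np.sin(w), np.ones_like(w)], axis=1)
    coef, *_ = np.linalg.lstsq(design, resid, rcond=None)
    c_amp = float(np.hypot(coef[0], coef[1]))
    leftover = resid - design @ coef
    valid = c_amp >= amplitude_floor_factor * float(np.std(leftover))
    if not valid:
        phase = np.full_like(phase, np.nan)
    return PhaseSeries(cell_id, t_min, area, phase, period_s,
                       c_amp, baseline, valid)


def detect_cycles(series: PhaseSeries) -> list[tuple[int, int]]:
    """Complete oscillation cycles as (start, end) sample indices.

    Cycle boundaries are the downward wraps of ϕ (360 → 0); the partial
    leading and trailing cycles are discarded.  The end index is the last
    sample belonging to the cycle (the sample before the next wrap).
    """
    if not series.valid:
        return []
    phi = series.phase_deg
    wraps = np.nonzero(np.diff(phi) < -180.0)[0] + 1
    cycles = []
    for i in range(len(wraps) - 1):
        cycles.append((int(wraps[i]), int(wraps[i + 1] - 1)))
    # leading partial cycle kept only when sampling starts at ϕ ≈ 0
    if len(wraps) >= 1 and phi[0] <= np.diff(phi[:2]).item() * 1.5 and phi[0] < 15.0:
        cycles.insert(0, (0, int(wraps[0] - 1)))
    return cycles


# ------------------------------------------------------------------- ratchet
PHASE_GRID_DEG = np.arange(0.0, 360.0, 9.0)  # 40 points, half-open [0°, 360°)


@dataclass
class RatchetCurve:
    """Phase-resolved mean interface length change ΔL(ϕ) for one angle bin."""

    angle_bin: tuple[float, float]    # |θ| interval, degrees
    phase_deg: np.ndarray             # the common 40-point grid
    mean_dl_um: np.ndarray
    n_samples: int                    # (interface, cycle) samples averaged


def _cycle_dl_on_grid(phi: np.ndarray, l_um: np.ndarray) -> np.ndarray | None:
    """Interpolate one cycle's length change onto the common phase grid.

    ΔL is measured relative to the interpolated length at ϕ = 0, so the first
    grid point is exactly 0 by construction.
    """
    ok = np.isfinite(phi) & np.isfinite(l_um)
    phi, l_um = phi[ok], l_um[ok]
    if phi.size < 3:
        return None
    # enforce monotonic phase within the cycle (unwrap small backward jitter)
    phi = np.maximum.accumulate(phi)
    grid_l = np.interp(PHASE_GRID_DEG, phi, l_um)
    return grid_l - grid_l[0]


def ratchet_curve(tracks: TrackSet, phase_series: dict[int, PhaseSeries],
                  angle_bin_edges: np.ndarray | None = None,
                  ) -> list[RatchetCurve]:
    """Phase-resolved interface length change, averaged per angle bin.

    Every (interface, adjacent cell, cycle) combination for which the
    interface is present over the entire cycle contributes one ΔL(ϕ) sample
    (an interface borders two cells and can contribute once per cell).  Each
    sample is interpolated to the common 40-point 9°-spaced phase vector with
    ΔL = 0 at ϕ = 0, then averaged within bins of the interface's mean |θ|
    over the cycle.
    """
    if angle_bin_edges is None:
        angle_bin_edges = np.array([0.0, 30.0, 60.0, 90.0])
    angle_bin_edges = np.asarray(angle_bin_edges, dtype=float)
    nb = len(angle_bin_edges) - 1
    sums = [np.zeros(PHASE_GRID_DEG.size) for _ in range(nb)]
    counts = [0] * nb

    for _, grp in tracks.iter_tracks():
        frames = grp["frame"].to_numpy(dtype=int)
        l_um = grp["l_um"].to_numpy(dtype=float)
        theta = grp["theta_deg"].to_numpy(dtype=float)
        for cid in (int(grp["cell_a"].iloc[0]), int(grp["cell_b"].iloc[0])):
            ps = phase_series.get(cid)
            if ps is None or not ps.valid:
                continue
            for c0, c1 in detect_cycles(ps):
                if c1 - c0 < 3:
                    continue
                if frames.min() > c0 or frames.max() < c1:
                    continue  # interface must be present for the entire cycle
                sel = (frames >= c0) & (frames <= c1)
                dl = _cycle_dl_on_grid(ps.phase_deg[c0:c1 + 1], l_um[sel])
                if dl is None:
                    continue
                mean_abs_th = float(np.nanmean(np.abs(theta[sel])))
                if not np.isfinite(mean_abs_th):
                    continue
                b = int(np.clip(np.digitize(mean_abs_th, angle_bin_edges) - 1,
                                0, nb - 1))
                sums[b] += dl
                counts[b] += 1

    curves = []
    for b in range(nb):
        if counts[b] == 0:
            continue
        curves.append(RatchetCurve(
            (float(angle_bin_edges[b]), float(angle_bin_edges[b + 1])),
            PHASE_GRID_DEG.copy(), sums[b] / counts[b], counts[b]))
    return curves


def phase_series_from_cell_table(cell_table: pd.DataFrame, dt_s: float,
                                 pixel_size: float = 1.0
                                 ) -> dict[int, PhaseSeries]:
    """Extract a PhaseSeries per cell from a (cell_id, frame, area_px) table.

    Cells whose area series is too short or non-oscillatory are skipped.
    """
    out: dict[int, PhaseSeries] = {}
    for cid, grp in cell_table.groupby("cell_id"):
        grp = grp.sort_values("frame")
        area = grp["area_px"].to_numpy(dtype=float) * pixel_size ** 2
        if len(area) < 8:
            continue
        try:
            ps = extract_phase(area, dt_s, cell_id=int(cid))
        except ValueError:
            continue
        out[int(cid)] = ps
    return out
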