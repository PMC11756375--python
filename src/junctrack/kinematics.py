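"""Interface orientation-angle conventions and length/angle kinematics.

Angle convention
----------------
Interfaces are undirected line segments, so orientation lives on a 180°-period
circle represented by the half-open interval (-90, 90].  θ = 0° is *vertical*
(aligned with the dorsoventral axis), θ = ±90° *horizontal* (anteroposterior);
intermediate angles are called transverse.  Measured image angles are
corrected by the embryo-axis offset δ so that θ is expressed in embryo
coordinates.

Rates
-----
Rates of length change are finite differences r_L(t) = [l(t+Δt) − l(t)]/Δt
with Δt = 30 s by default, reported in µm/min; rotation rates use the minimal
signed angle difference and are reported in °/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import TrackSet

DEFAULT_DT_S = 30.0


# --------------------------------------------------------------------- angles
def fold_angle(alpha):
    """Fold any angle (degrees) into the half-open interval (-90, 90].

    The two representations of an undirected segment (α and α±180°) fold to
    the same value; -90 maps to +90 so the interval is half-open.
    """
    alpha = np.asarray(alpha, dtype=float)
    out = np.mod(alpha + 90.0, 180.0) - 90.0
    out = np.where(out == -90.0, 90.0, out)
    return out if out.ndim else float(out)


def angle_difference(theta1, theta2):
    """Minimal signed difference θ2 − θ1 on the 180°-period circle, in (-90, 90].

    Wraparound example: from 80° to -80° the short way is +20° (through 90).
    On the exact tie (|difference| = 90) the positive representative is chosen.
    """
    return fold_angle(np.asarray(theta2, dtype=float) - np.asarray(theta1, dtype=float))


def interface_angle(p1, p2, delta_deg: float = 0.0, pixel_aspect: float = 1.0):
    """Orientation angle of the segment p1→p2 in embryo coordinates.

    Points are (x, y) pixel coordinates (x = column, y = row, y along the
    image's dorsoventral direction).  θ = fold(atan2(Δx, Δy·aspect) − δ):
    a purely vertical segment gives 0°, a horizontal one 90°.  Coincident
    endpoints (higher-order vertex configurations) yield NaN, not an error.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    dx, dy = d[..., 0], d[..., 1] * pixel_aspect
    raw = np.degrees(np.arctan2(dx, dy))
    theta = fold_angle(raw - delta_deg)
    undefined = (dx == 0) & (dy == 0)
    if np.ndim(theta) == 0:
        return float("nan") if undefined else theta
    return np.where(undefined, np.nan, theta)


def unwrap_angles(theta: np.ndarray) -> np.ndarray:
    """Cumulative (unwrapped) angle trajectory from a folded θ sequence.

    Successive minimal signed differences are summed, removing the 180° wrap;
    re-folding the result reproduces the input.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        return theta.copy()
    steps = angle_difference(theta[:-1], theta[1:])
    return theta[0] + np.concatenate([[0.0], np.cumsum(steps)])


# ---------------------------------------------------------------------- rates
def smooth_lengths(l: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with shrinking windows at the ends; window=1 is identity."""
    if window <= 1:
        return np.asarray(l, dtype=float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    l = np.asarray(l, dtype=float)
    half = window // 2
    out = np.empty_like(l)
    for i in range(l.size):
        lo, hi = max(0, i - half), min(l.size, i + half + 1)
        window = l[lo:hi]
        finite = np.isfinite(window)
        out[i] = window[finite].mean() if finite.any() else np.nan
    return out


def compute_rates(tracks: TrackSet, dt_s: float = DEFAULT_DT_S,
                  smooth_window: int = 1) -> TrackSet:
    """Attach finite-difference rates to a TrackSet.

    Adds columns ``rl_um_min`` (rate of length change, µm/min) and
    ``rtheta_deg_min`` (rotation rate, °/min) evaluated at each frame that has
    a successor Δt later within the same track; elsewhere NaN.  ``dt_s`` must
    be an integer multiple of the frame interval.  ``smooth_window`` applies a
    centered moving average to l before differencing (1 disables).
    """
    step = dt_s / tracks.dt_frame
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ValueError(
            f"dt ({dt_s} s) must be a positive integer multiple of the frame "
            f"interval ({tracks.dt_frame} s)")
    step = int(round(step))
    dt_min = dt_s / 60.0

    pf = tracks.per_frame
    rl = np.full(len(pf), np.nan)
    rth = np.full(len(pf), np.nan)
    for _, grp in pf.groupby("track_id", sort=False):
        idx = grp.index.to_numpy()
        frames = grp["frame"].to_numpy()
        # frames are contiguous within a track; guard anyway
        l = smooth_lengths(grp["l_um"].to_numpy(), smooth_window)
        th = grp["theta_deg"].to_numpy(dtype=float)
        n = len(idx)
        if n <= step:
            continue
        pos = np.arange(n - step)
        ok = frames[pos + step] - frames[pos] == step
        rl[idx[pos[ok]]] = (l[pos + step] - l[pos])[ok] / dt_min
        rth[idx[pos[ok]]] = angle_difference(th[pos], th[pos + step])[ok] / dt_min

    out = tracks.copy()
    out.per_frame["rl_um_min"] = rl
    out.per_frame["rtheta_deg_min"] = rth
    out.rate_dt_s = dt_s  # remembered so calibrate() can attribute samples
    return out


# --------------------------------------------------------------- rate fields
@dataclass
class RateField:
    """Binned mean of a rate (or intensity) over (time, angle) or (length, angle)."""

    x_edges: np.ndarray       # time (min) or length (µm) bin edges
    angle_edges: np.ndarray   # degrees
    mean: np.ndarray          # (n_x, n_angle); NaN where empty
    count: np.ndarray
    std: np.ndarray
    statistic: str = "rl_um_min"
    x_name: str = "t_min"

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def angle_centers(self) -> np.ndarray:
        return 0.5 * (self.angle_edges[:-1] + self.angle_edges[1:])


def _binned_field(x, theta, values, x_edges, angle_edges) -> tuple[np.ndarray, ...]:
    ok = np.isfinite(x) & np.isfinite(theta) & np.isfinite(values)
    x, theta, values = x[ok], theta[ok], values[ok]
    ix = np.digitize(x, x_edges) - 1
    ia = np.digitize(theta, angle_edges) - 1
    # samples exactly on the last edge belong to the last bin
    ix = np.where((x == x_edges[-1]) & (ix == len(x_edges) - 1), ix - 1, ix)
    ia = np.where((theta == angle_edges[-1]) & (ia == len(angle_edges) - 1), ia - 1, ia)
    nb_x, nb_a = len(x_edges) - 1, len(angle_edges) - 1
    keep = (ix >= 0) & (ix < nb_x) & (ia >= 0) & (ia < nb_a)
    ix, ia, values = ix[keep], ia[keep], values[keep]
    flat = ix * nb_a + ia
    count = np.bincount(flat, minlength=nb_x * nb_a).astype(float)
    s1 = np.bincount(flat, weights=values, minlength=nb_x * nb_a)
    s2 = np.bincount(flat, weights=values ** 2, minlength=nb_x * nb_a)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / count, np.nan)
        var = np.where(count > 1, (s2 - s1 ** 2 / np.maximum(count, 1)) /
                       np.maximum(count - 1, 1), np.nan)
    shape = (nb_x, nb_a)
    return (mean.reshape(shape), count.reshape(shape).astype(int),
            np.sqrt(np.maximum(var, 0.0)).reshape(shape))


def rate_heatmap(tracks: TrackSet, time_bin_min: float = 1.0,
                 angle_bin_deg: float = 10.0, statistic: str = "rl_um_min",
                 absolute_angle: bool = False) -> RateField:
    """Mean rate (or myosin) over (time, orientation angle) bins.

    ``statistic`` names a per-frame column ('rl_um_min', 'rtheta_deg_min' or
    'm').  Empty bins are NaN with count 0.  ``absolute_angle`` bins |θ| over
    [0, 90] instead of signed θ over (-90, 90].
    """
    pf = tracks.per_frame
    if statistic not in pf.columns:
        raise ValueError(
            f"statistic column {statistic!r} absent; available: "
            f"{sorted(set(pf.columns) & {'rl_um_min', 'rtheta_deg_min', 'm'})}")
    t = tracks.t_min
    theta = pf["theta_deg"].to_numpy(dtype=float)
    if absolute_angle:
        theta = np.abs(theta)
        angle_edges = np.arange(0.0, 90.0 + angle_bin_deg / 2, angle_bin_deg)
    else:
        angle_edges = np.arange(-90.0, 90.0 + angle_bin_deg / 2, angle_bin_deg)
    vals = pf[statistic].to_numpy(dtype=float)
    ok = np.isfinite(t) & np.isfinite(vals)
    if not ok.any():
        x_edges = np.array([0.0, time_bin_min])
    else:
        lo = np.floor(t[ok].min() / time_bin_min) * time_bin_min
        hi = np.ceil(t[ok].max() / time_bin_min) * time_bin_min
        hi = hi if hi > lo else lo + time_bin_min
        x_edges = np.arange(lo, hi + time_bin_min / 2, time_bin_min)
    mean, count, std = _binned_field(t, theta, vals, x_edges, angle_edges)
    return RateField(x_edges, angle_edges, mean, count, std, statistic, "t_min")


# ---------------------------------------------------------------- calibration
@dataclass
class CalibrationResult:
    """Embryo-axis offset δ, germband-extension onset t0 and the polarity trace."""

    delta_deg: float
    t0_min: float | None
    polarity_time_min: np.ndarray
    polarity_score: np.ndarray
    threshold: float
    delta_scores: pd.DataFrame | None = None  # per-candidate-δ mean vertical r_L


def calibrate(tracks: TrackSet, time_bin_min: float = 1.0,
              vertical_halfwidth_deg: float = 15.0,
              onset_sd_factor: float = 2.0, onset_persistence: int = 3,
              min_bin_samples: int = 50) -> CalibrationResult:
    """Recover the embryo-axis offset δ and the onset time t0 of germband extension.

    δ: grid search over (-90, 90] in 0.25° steps; δ is chosen to maximize the
    projection of the observed rates onto the vertical-contraction template,
    i.e. to make the time-averaged mean of r_L·cos 2(θ−δ) most negative —
    vertical interfaces contract fastest, horizontal ones elongate fastest.
    (A hard ±15° vertical-bin mean is also reported per candidate; the smooth
    projection is used for the argmin because it weights every sample and is
    robust when the orientation distribution is uneven.)

    t0: with δ fixed, the planar-polarity score
    P(t) = mean r_L(|θ| > 60°) − mean r_L(|θ| < 30°) is computed in time bins,
    each rate sample attributed to the *end* of its differencing interval (a
    finite-difference rate is only fully measured then, so post-onset signal
    cannot leak into pre-onset bins).  t0 is the left edge of the
    post-onset segment of the least-squares two-segment (step) fit of P(t),
    accepted only when the fitted jump exceeds ``onset_sd_factor`` times its
    standard error (Welch-style, from the two segments' variances) and the
    post segment spans at least ``onset_persistence`` bins; otherwise t0 is
    None.
    """
    pf = tracks.per_frame
    if "rl_um_min" not in pf.columns:
        raise ValueError("run compute_rates before calibrate")
    theta_raw = fold_angle(pf["theta_deg"].to_numpy(dtype=float) + tracks.delta_deg)
    rl = pf["rl_um_min"].to_numpy(dtype=float)
    t = pf["frame"].to_numpy(dtype=float) * tracks.dt_frame_min
    ok = np.isfinite(theta_raw) & np.isfinite(rl)
    theta_raw, rl, t = theta_raw[ok], rl[ok], t[ok]
    if theta_raw.size == 0:
        raise ValueError("no finite (angle, rate) samples to calibrate on")

    if theta_raw.size < min_bin_samples:
        raise ValueError(
            f"only {theta_raw.size} (angle, rate) samples; calibration needs "
            f"at least {min_bin_samples}")
    step = 0.25
    deltas = np.arange(-90.0 + step, 90.0 + step / 2, step)
    # mean(r_L·cos 2(θ−δ)) = C·cos 2δ + S·sin 2δ — two moments suffice
    c_mom = float(np.mean(rl * np.cos(2 * np.radians(theta_raw))))
    s_mom = float(np.mean(rl * np.sin(2 * np.radians(theta_raw))))
    proj = c_mom * np.cos(2 * np.radians(deltas)) + \
        s_mom * np.sin(2 * np.radians(deltas))
    window = np.full(deltas.shape, np.nan)
    for i, d in enumerate(deltas):
        mask = np.abs(fold_angle(theta_raw - d)) <= vertical_halfwidth_deg
        if mask.sum() >= min_bin_samples:
            window[i] = rl[mask].mean()
    delta = float(deltas[np.argmin(proj)])
    delta_scores = pd.DataFrame({"delta_deg": deltas, "projection": proj,
                                 "mean_vertical_rl": window})

    theta = fold_angle(theta_raw - delta)
    # attribute each rate sample to the end of its differencing interval
    rate_dt_min = getattr(tracks, "rate_dt_s", DEFAULT_DT_S) / 60.0
    t_end = t + rate_dt_min
    edges = np.arange(0.0, t_end.max() + time_bin_min, time_bin_min)
    nb = len(edges) - 1
    ib = np.clip(np.digitize(t_end, edges) - 1, 0, nb - 1)
    p = np.full(nb, np.nan)
    for b in range(nb):
        in_bin = ib == b
        horiz = in_bin & (np.abs(theta) > 60.0)
        vert = in_bin & (np.abs(theta) < 30.0)
        if horiz.sum() >= min_bin_samples and vert.sum() >= min_bin_samples:
            p[b] = rl[horiz].mean() - rl[vert].mean()

    t0 = None
    thr = np.nan
    finite = np.isfinite(p)
    pv = p[finite]
    left_edges = edges[:-1][finite]
    if pv.size >= onset_persistence + 1:
        # least-squares two-segment (step) fit of the polarity score
        best_sse, best_b = np.inf, None
        for b in range(1, pv.size - onset_persistence + 1):
            pre, post = pv[:b], pv[b:]
            sse = float(((pre - pre.mean()) ** 2).sum()
                        + ((post - post.mean()) ** 2).sum())
            if post.mean() > pre.mean() and sse < best_sse:
                best_sse, best_b = sse, b
        if best_b is not None:
            pre, post = pv[:best_b], pv[best_b:]
            var_pre = float(pre.var(ddof=1)) if pre.size > 1 else float(pv.var(ddof=1))
            var_post = float(post.var(ddof=1)) if post.size > 1 else float(pv.var(ddof=1))
            se_jump = np.sqrt(var_pre / pre.size + var_post / post.size)
            thr = onset_sd_factor * max(float(se_jump), 1e-9)
            if post.mean() - pre.mean() > thr:
                t0 = float(left_edges[best_b])
    return CalibrationResult(delta, t0, 0.5 * (edges[:-1] + edges[1:]), p,
                             thr if np.isfinite(np.atleast_1d(thr)).all() else np.nan,
                             delta_scores)


def apply_calibration(tracks: TrackSet, calib: CalibrationResult) -> TrackSet:
    """Re-express angles in the calibrated embryo frame and set the onset time."""
    out = tracks.copy()
    raw = fold_angle(out.per_frame["theta_deg"].to_numpy(dtype=float) + out.delta_deg)
    out.per_frame["theta_deg"] = fold_angle(raw - calib.delta_deg)
    out.delta_deg = calib.delta_deg
    out.t0_min = calib.t0_min
    return out


# ------------------------------------------------------- unit-length crossing
def angle_at_unit_length(track_frames: pd.DataFrame, kind: str,
                         l_star: float = 1.0) -> float:
    """Orientation angle where a track crosses the reference length l*.

    For a contracting interface: θ at the last frame before death with
    l ≥ l*.  For an elongating one: θ at the first frame with l ≥ l*.
    Returns NaN when the track never reaches l*.
    """
    if kind not in ("contracting", "elongating"):
        raise ValueError("kind must be 'contracting' or 'elongating'")
    grp = track_frames.sort_values("frame")
    l = grp["l_um"].to_numpy(dtype=float)
    th = grp["theta_deg"].to_numpy(dtype=float)
    idx = np.where(l >= l_star)[0]
    if idx.size == 0:
        return float("nan")
    return float(th[idx[-1]] if kind == "contracting" else th[idx[0]])
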