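"""Interface-rotation analyses: angular MSD, rate-vs-angle curves, rotating
cohorts, and the (length, angle) phase portrait with streamlines.

The angular mean-squared displacement distinguishes systematic rotation from
random angular wander: a power-law fit MSD(τ) ∝ τ^γ gives γ = 1 for a random
walk and γ = 2 for ballistic (constant-rate) rotation; γ > 1 indicates
super-diffusive, i.e. directed, rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import ks_2samp

from .kinematics import angle_difference, unwrap_angles
from .tracks import TrackSet


# ------------------------------------------------------------------------ MSD
@dataclass
class MSDCurve:
    """Mean squared angular displacement for one starting-angle bin."""

    angle_bin: tuple[float, float]    # |θ| interval, degrees
    lags_min: np.ndarray
    msd_deg2: np.ndarray
    n_tracks: int
    gamma: float | None = None
    fit_range_min: tuple[float, float] | None = None


def angular_msd(tracks: TrackSet, bin_width_deg: float = 15.0,
                tau_max_min: float | None = None,
                selection_window_min: float = 5.0,
                min_tracks: int = 3) -> list[MSDCurve]:
    """Angular MSD per starting-|θ| bin.

    Tracks are binned by their mean |θ| during their first
    ``selection_window_min`` minutes.  Each track contributes its unwrapped
    angle trajectory Θ(t) (cumulative minimal signed differences, removing
    the 180° wrap); MSD(τ) averages (Θ(t_start+τ) − Θ(t_start))² over tracks,
    with t_start the first frame of the track (single-origin).  Bins with
    fewer than ``min_tracks`` tracks are omitted.
    """
    dt_min = tracks.dt_frame_min
    win_frames = max(1, int(round(selection_window_min / dt_min)))
    edges = np.arange(0.0, 90.0 + bin_width_deg / 2, bin_width_deg)
    per_bin: dict[int, list[np.ndarray]] = {}
    for _, grp in tracks.iter_tracks():
        th = grp["theta_deg"].to_numpy(dtype=float)
        th = th[np.isfinite(th)]
        if th.size < 2:
            continue
        start_angle = np.abs(th[:win_frames]).mean()
        b = min(int(start_angle // bin_width_deg), len(edges) - 2)
        per_bin.setdefault(b, []).append(unwrap_angles(th))

    curves: list[MSDCurve] = []
    for b in sorted(per_bin):
        trajs = per_bin[b]
        if len(trajs) < min_tracks:
            continue
        max_len = max(len(tr) for tr in trajs)
        if tau_max_min is not None:
            max_len = min(max_len, int(round(tau_max_min / dt_min)) + 1)
        sq_sum = np.zeros(max_len)
        count = np.zeros(max_len)
        for tr in trajs:
            disp = (tr[:max_len] - tr[0]) ** 2
            sq_sum[:len(disp)] += disp
            count[:len(disp)] += 1
        with np.errstate(invalid="ignore"):
            msd = np.where(count > 0, sq_sum / np.maximum(count, 1), np.nan)
        lags = np.arange(max_len) * dt_min
        curves.append(MSDCurve((edges[b], edges[b + 1]), lags, msd, len(trajs)))
    return curves


def fit_msd_exponent(curve: MSDCurve,
                     fit_range_min: tuple[float, float] = (1.0, 8.0)) -> float:
    """Power-law exponent γ: least-squares slope of log MSD against log τ.

    τ = 0 is excluded by construction; all MSD values in the range must be
    positive.  The fitted γ and range are stored on the curve and returned.
    """
    lo, hi = fit_range_min
    sel = (curve.lags_min >= lo) & (curve.lags_min <= hi) & \
        np.isfinite(curve.msd_deg2)
    if sel.sum() < 3:
        raise ValueError("need at least 3 lags inside the fit range")
    msd = curve.msd_deg2[sel]
    if np.any(msd <= 0):
        bad = curve.lags_min[sel][msd <= 0][0]
        raise ValueError(f"non-positive MSD at lag {bad} min; cannot fit log-log")
    gamma = float(np.polyfit(np.log(curve.lags_min[sel]), np.log(msd), 1)[0])
    curve.gamma = gamma
    curve.fit_range_min = (lo, hi)
    return gamma


# -------------------------------------------------------------- rate vs angle
def rate_vs_angle(tracks: TrackSet, angle_bin_deg: float = 10.0
                  ) -> pd.DataFrame:
    """Binned mean rates keyed by current orientation angle.

    Returns a table with one row per angle bin: bin center, mean and SD of
    the rate of length change (µm/min) and of the rotation rate (°/min), and
    sample counts.  Instantaneous samples are pooled over all tracks/frames.
    """
    pf = tracks.per_frame
    for col in ("rl_um_min", "rtheta_deg_min"):
        if col not in pf.columns:
            raise ValueError("run compute_rates first")
    edges = np.arange(-90.0, 90.0 + angle_bin_deg / 2, angle_bin_deg)
    th = pf["theta_deg"].to_numpy(dtype=float)
    rows = []
    for b in range(len(edges) - 1):
        m = (th > edges[b]) & (th <= edges[b + 1])
        row = {"theta_center": 0.5 * (edges[b] + edges[b + 1])}
        for col, name in (("rl_um_min", "rl"), ("rtheta_deg_min", "rtheta")):
            v = pf[col].to_numpy(dtype=float)[m]
            v = v[np.isfinite(v)]
            row[f"{name}_mean"] = v.mean() if v.size else np.nan
            row[f"{name}_sd"] = v.std(ddof=1) if v.size > 1 else np.nan
            row[f"{name}_n"] = v.size
        rows.append(row)
    return pd.DataFrame(rows)


def rotation_zero_crossings(curve: pd.DataFrame) -> list[float]:
    """Angles where the binned mean rotation rate changes sign (linear interp)."""
    th = curve["theta_center"].to_numpy()
    r = curve["rtheta_mean"].to_numpy()
    ok = np.isfinite(r)
    th, r = th[ok], r[ok]
    out = []
    for i in range(len(r) - 1):
        if r[i] == 0.0:
            out.append(float(th[i]))
        if r[i] * r[i + 1] < 0:
            out.append(float(th[i] - r[i] * (th[i + 1] - th[i]) / (r[i + 1] - r[i])))
    if len(r) and r[-1] == 0.0:
        out.append(float(th[-1]))
    return out


# -------------------------------------------------------------------- cohorts
@dataclass
class CohortResult:
    """Subpopulations of a starting-angle cohort followed over a fixed window."""

    members: pd.DataFrame          # track_id, theta_start, theta_end, d_abs_theta, label
    counts: dict[str, int]
    start_frame: int
    end_frame: int
    cdfs: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def ks_end_rate(self, a: str, b: str) -> tuple[float, float]:
        """Two-sample KS test between end-of-window r_L distributions."""
        xa, xb = self.cdfs[a]["rl_end"], self.cdfs[b]["rl_end"]
        res = ks_2samp(xa, xb)
        return float(res.statistic), float(res.pvalue)


def cohort_analysis(tracks: TrackSet,
                    parent_angle_range: tuple[float, float] = (30.0, 50.0),
                    t_select_min: float = 5.0, t_select_tol_min: float = 2.0,
                    follow_min: float = 10.0,
                    rotation_threshold_deg: float = 15.0) -> CohortResult:
    """Classify a starting-angle cohort into rotation subpopulations.

    Parent cohort: tracks whose |θ| falls inside ``parent_angle_range`` at
    some frame within t_select ± tol and that remain visible over
    [t_select, t_select + follow].  Classification by the change of |θ| over
    the window: |Δ|θ|| < threshold → 'minimal'; decrease ≥ threshold →
    'vertical' (rotating toward vertical); increase ≥ threshold →
    'horizontal'.  Empirical distributions of θ and r_L at window start and
    end are kept per subpopulation.
    """
    dt_min = tracks.dt_frame_min
    t = tracks.time_min(np.array([0.0]))[0]  # offset of frame 0
    f_select = int(round((t_select_min - t) / dt_min))
    f_tol = int(round(t_select_tol_min / dt_min))
    f_end = f_select + int(round(follow_min / dt_min))
    has_rl = "rl_um_min" in tracks.per_frame.columns

    rows = []
    cdfs: dict[str, dict[str, list]] = {
        k: {"theta_start": [], "theta_end": [], "rl_start": [], "rl_end": []}
        for k in ("minimal", "vertical", "horizontal")}
    for tid, grp in tracks.iter_tracks():
        frames = grp["frame"].to_numpy()
        if frames.min() > f_select or frames.max() < f_end:
            continue
        sel = grp[(frames >= f_select - f_tol) & (frames <= f_select + f_tol)]
        lo, hi = parent_angle_range
        th_sel = np.abs(sel["theta_deg"].to_numpy(dtype=float))
        if not np.any((th_sel >= lo) & (th_sel <= hi)):
            continue
        row_s = grp[grp["frame"] == f_select].iloc[0]
        row_e = grp[grp["frame"] == f_end].iloc[0]
        th_s, th_e = float(row_s["theta_deg"]), float(row_e["theta_deg"])
        if not (np.isfinite(th_s) and np.isfinite(th_e)):
            continue
        d_abs = abs(th_e) - abs(th_s)
        if abs(d_abs) < rotation_threshold_deg:
            label = "minimal"
        elif d_abs < 0:
            label = "vertical"
        else:
            label = "horizontal"
        rows.append((tid, th_s, th_e, d_abs, label))
        cdfs[label]["theta_start"].append(th_s)
        cdfs[label]["theta_end"].append(th_e)
        if has_rl:
            cdfs[label]["rl_start"].append(float(row_s["rl_um_min"]))
            cdfs[label]["rl_end"].append(float(row_e["rl_um_min"]))

    members = pd.DataFrame(rows, columns=[
        "track_id", "theta_start", "theta_end", "d_abs_theta", "label"])
    counts = {k: int((members["label"] == k).sum())
              for k in ("minimal", "vertical", "horizontal")}
    cdf_arrays = {k: {kk: np.sort(np.asarray(vv, dtype=float))
                      for kk, vv in d.items()} for k, d in cdfs.items()}
    return CohortResult(members, counts, f_select, f_end, cdf_arrays)


# --------------------------------------------------------------- phase portrait
@dataclass
class PhasePortrait:
    """Mean (dl/dt, dθ/dt) field on a (length, angle) grid, with streamlines."""

    l_edges: np.ndarray
    theta_edges: np.ndarray
    dl_dt: np.ndarray        # (n_l, n_theta) µm/min, NaN-free after fill
    dtheta_dt: np.ndarray    # °/min
    count: np.ndarray
    streamlines: list[np.ndarray] = field(default_factory=list)

    @property
    def l_centers(self):
        return 0.5 * (self.l_edges[:-1] + self.l_edges[1:])

    @property
    def theta_centers(self):
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])


def phase_portrait(tracks: TrackSet, l_max_um: float = 6.0,
                   n_l_bins: int = 12, n_theta_bins: int = 18) -> PhasePortrait:
    """Bin instantaneous (dl/dt, dθ/dt) samples on the (l, θ) plane.

    Empty bins are filled by nearest-neighbor interpolation from occupied
    bins so streamlines can be integrated anywhere on the grid.
    """
    pf = tracks.per_frame
    l = pf["l_um"].to_numpy(dtype=float)
    th = pf["theta_deg"].to_numpy(dtype=float)
    rl = pf["rl_um_min"].to_numpy(dtype=float)
    rt = pf["rtheta_deg_min"].to_numpy(dtype=float)
    ok = np.isfinite(l) & np.isfinite(th) & np.isfinite(rl) & np.isfinite(rt) \
        & (l <= l_max_um)
    if not ok.any():
        raise ValueError("no finite samples for the phase portrait")
    l_edges = np.linspace(0.0, l_max_um, n_l_bins + 1)
    th_edges = np.linspace(-90.0, 90.0, n_theta_bins + 1)
    il = np.clip(np.digitize(l[ok], l_edges) - 1, 0, n_l_bins - 1)
    it = np.clip(np.digitize(th[ok], th_edges) - 1, 0, n_theta_bins - 1)
    flat = il * n_theta_bins + it
    nbins = n_l_bins * n_theta_bins
    cnt = np.bincount(flat, minlength=nbins).astype(float)
    sum_rl = np.bincount(flat, weights=rl[ok], minlength=nbins)
    sum_rt = np.bincount(flat, weights=rt[ok], minlength=nbins)
    with np.errstate(invalid="ignore"):
        mrl = np.where(cnt > 0, sum_rl / np.maximum(cnt, 1), np.nan)
        mrt = np.where(cnt > 0, sum_rt / np.maximum(cnt, 1), np.nan)
    mrl = mrl.reshape(n_l_bins, n_theta_bins)
    mrt = mrt.reshape(n_l_bins, n_theta_bins)
    cnt = cnt.reshape(n_l_bins, n_theta_bins)

    # nearest-neighbor fill of empty bins
    occ = np.isfinite(mrl)
    if not occ.any():
        raise ValueError("phase portrait field is entirely empty")
    lc = 0.5 * (l_edges[:-1] + l_edges[1:])
    tc = 0.5 * (th_edges[:-1] + th_edges[1:])
    gl, gt = np.meshgrid(lc, tc, indexing="ij")
    pts = np.stack([gl[occ] / l_max_um, gt[occ] / 90.0], axis=1)
    need = ~occ
    if need.any():
        q = np.stack([gl[need] / l_max_um, gt[need] / 90.0], axis=1)
        d2 = ((q[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        mrl[need] = mrl[occ][nearest]
        mrt[need] = mrt[occ][nearest]
    return PhasePortrait(l_edges, th_edges, mrl, mrt, cnt.astype(int))


def integrate_streamline(portrait: PhasePortrait, l0_um: float, theta0_deg: float,
                         step_min: float = 0.1, max_steps: int = 2000
                         ) -> np.ndarray:
    """Fixed-step RK4 streamline through the binned field from a seed point.

    Integration stops when the trajectory leaves [0, l_max] in length or
    after ``max_steps`` steps; angle wraps on its 180° circle.  Returns an
    (n, 2) array of (l, θ) points.
    """
    lc, tc = portrait.l_centers, portrait.theta_centers
    interp_l = RegularGridInterpolator((lc, tc), portrait.dl_dt,
                                       bounds_error=False, fill_value=None)
    interp_t = RegularGridInterpolator((lc, tc), portrait.dtheta_dt,
                                       bounds_error=False, fill_value=None)

    def f(state):
        l, th = state
        th = ((th + 90.0) % 180.0) - 90.0
        p = np.array([[np.clip(l, lc[0], lc[-1]), np.clip(th, tc[0], tc[-1])]])
        return np.array([interp_l(p).item(), interp_t(p).item()])

    l_max = portrait.l_edges[-1]
    state = np.array([l0_um, theta0_deg], dtype=float)
    out = [state.copy()]
    for _ in range(max_steps):
        k1 = f(state)
        k2 = f(state + 0.5 * step_min * k1)
        k3 = f(state + 0.5 * step_min * k2)
        k4 = f(state + step_min * k3)
        state = state + (step_min / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        state[1] = ((state[1] + 90.0) % 180.0) - 90.0
        out.append(state.copy())
        if state[0] <= 0.0 or state[0] >= l_max:
            break
    return np.array(out)
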