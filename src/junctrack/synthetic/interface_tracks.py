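"""Track-level generator: interface length/angle trajectories with known laws.

Each synthetic interface evolves by explicit Euler steps of prescribed
angle-dependent laws,

    dθ/dt = rate_theta_law(θ)        (°/min,  default −ω·sin 2θ)
    dl/dt = rate_l_law(θ) · gate(ϕ)  (µm/min, default −v·cos 2θ)

so vertical interfaces (θ≈0) contract, horizontal ones (θ≈±90°) elongate, and
transverse interfaces rotate toward vertical — the rectifying planar-polarized
kinematics the analysis pipeline is designed to measure.  An optional cell
area oscillation modulates length change through a phase gate
``gate(ϕ) = 1 − bias·sin ϕ`` (amplified during the area-contraction half of
the cycle, ϕ≈270°, attenuated during expansion, ϕ≈90°), producing phase-locked
ratcheted length change; a zero-mean oscillatory term of fractional amplitude
``amplitude·l(0)`` is added to the *observed* length so ratchet curves see a
within-cycle excursion.

All laws, noise draws and phases are recorded in the returned GroundTruth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ..kinematics import fold_angle
from ..tracks import GroundTruth, TrackSet, build_tracks_table

RateLaw = Callable[[np.ndarray], np.ndarray]


def default_rate_l_law(v_um_min: float = 2.0) -> RateLaw:
    """dl/dt = −v·cos 2θ: maximal contraction at vertical, elongation at horizontal."""
    return lambda theta_deg: -v_um_min * np.cos(2 * np.radians(theta_deg))


def default_rate_theta_law(omega_deg_min: float = 3.0) -> RateLaw:
    """dθ/dt = −ω·sin 2θ: rotation toward whichever of ±0° is closer (rectification)."""
    return lambda theta_deg: -omega_deg_min * np.sin(2 * np.radians(theta_deg))


@dataclass
class OscillationParams:
    """Cell-area oscillation coupled to interface length change.

    period is in seconds; amplitude is the fractional (0–1) length excursion
    relative to the initial length; ratchet_bias in [0, 1] sets the asymmetry
    between contraction-phase and expansion-phase length-change increments.
    """

    period_s: float = 120.0
    amplitude: float = 0.1
    ratchet_bias: float = 0.5

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("oscillation period must be positive")
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("oscillation amplitude must be in [0, 1)")
        if not 0.0 <= self.ratchet_bias <= 1.0:
            raise ValueError("ratchet_bias must be in [0, 1]")


@dataclass
class TrackGenParams:
    """Conditions for :func:`generate_interface_tracks`."""

    n_interfaces: int = 100
    duration_min: float = 20.0
    dt_s: float = 30.0
    rate_l_law: RateLaw = field(default_factory=default_rate_l_law)
    rate_theta_law: RateLaw = field(default_factory=default_rate_theta_law)
    angle_noise_sd: float = 2.0      # °/step
    length_noise_sd: float = 0.05    # µm/step
    oscillation: OscillationParams | None = field(default_factory=OscillationParams)
    l0_range_um: tuple[float, float] = (2.0, 6.0)
    theta0_deg: np.ndarray | None = None  # initial angles; default uniform(-90, 90]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_s <= 0 or self.duration_min <= 0:
            raise ValueError("dt and duration must be positive")
        if self.n_interfaces < 1:
            raise ValueError("need at least one interface")


def generate_interface_tracks(params: TrackGenParams) -> tuple[TrackSet, GroundTruth]:
    """Generate interface tracks by Euler integration of the prescribed laws.

    Per step (Δt = params.dt_s):
    θ ← fold(θ + rate_theta_law(θ)·Δt + angle noise),
    l ← l + rate_l_law(θ)·Δt·gate(ϕ) + length noise, floored at 0; a track
    whose core length reaches 0 terminates and a contraction event is recorded.
    The observed length adds the zero-mean oscillatory excursion on top of the
    core length.  Identical seed and params give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_interfaces
    dt_min = params.dt_s / 60.0
    n_steps = int(round(params.duration_min / dt_min))

    lo, hi = params.l0_range_um
    l = rng.uniform(lo, hi, size=n)
    l0 = l.copy()
    if params.theta0_deg is None:
        theta = rng.uniform(-90.0, 90.0, size=n)
        theta = fold_angle(theta)
    else:
        theta = fold_angle(np.asarray(params.theta0_deg, dtype=float))
        if theta.shape != (n,):
            raise ValueError("theta0_deg must have length n_interfaces")

    osc = params.oscillation
    if osc is not None:
        phi0 = rng.uniform(0.0, 360.0, size=n)
        omega_phi = 360.0 * params.dt_s / osc.period_s  # °/step
    else:
        phi0 = np.zeros(n)
        omega_phi = 0.0

    alive = np.ones(n, dtype=bool)
    rows = []
    truth_rows = []
    events = []
    for k in range(n_steps + 1):
        t_min = k * dt_min
        phi = np.mod(phi0 + k * omega_phi, 360.0)
        # observed length: core + oscillatory excursion (zero at phase 0)
        if osc is not None:
            osc_term = osc.amplitude * l0 * 0.5 * (1.0 - np.cos(np.radians(phi)))
        else:
            osc_term = np.zeros(n)
        l_obs = np.where(alive, l + osc_term, np.nan)

        r_theta = np.asarray(params.rate_theta_law(theta), dtype=float)
        gate = 1.0 - (osc.ratchet_bias if osc is not None else 0.0) * \
            np.sin(np.radians(phi))
        r_l = np.asarray(params.rate_l_law(theta), dtype=float)
        if not (np.all(np.isfinite(r_theta[alive])) and np.all(np.isfinite(r_l[alive]))):
            raise ValueError("rate law returned a non-finite value")

        for i in np.where(alive)[0]:
            rows.append((i, i, -1, k, l_obs[i], theta[i]))
            truth_rows.append((i, k, t_min, l_obs[i], l[i], theta[i],
                               r_l[i] * gate[i], r_theta[i], phi[i]))
        if k == n_steps:
            break

        theta_new = theta + r_theta * dt_min
        if params.angle_noise_sd > 0:
            theta_new = theta_new + rng.normal(0.0, params.angle_noise_sd, size=n)
        theta = fold_angle(theta_new)
        dl = r_l * gate * dt_min
        if params.length_noise_sd > 0:
            dl = dl + rng.normal(0.0, params.length_noise_sd, size=n)
        l = l + np.where(alive, dl, 0.0)
        died = alive & (l <= 0.0)
        for i in np.where(died)[0]:
            events.append(("contraction", i, -1, (k + 1) * dt_min))
        l = np.maximum(l, 0.0)
        alive = alive & ~died

    per_frame = pd.DataFrame(
        rows, columns=["track_id", "cell_a", "cell_b", "frame", "l_um", "theta_deg"])
    end_cause = {}
    for kind, a, b, t in events:
        end_cause[a] = "contracted"
    tracks_tab = build_tracks_table(per_frame, end_cause=end_cause)
    ts = TrackSet(per_frame, tracks_tab, dt_frame=params.dt_s)

    truth = pd.DataFrame(truth_rows, columns=[
        "track_id", "frame", "t_min", "l_um", "l_core_um", "theta_deg",
        "rate_l", "rate_theta", "phase_deg"])
    ev = pd.DataFrame(events, columns=["kind", "cell_a", "cell_b", "t_min"])
    gt = GroundTruth(interfaces=truth, events=ev, params={
        "n_interfaces": n, "duration_min": params.duration_min,
        "dt_s": params.dt_s, "angle_noise_sd": params.angle_noise_sd,
        "length_noise_sd": params.length_noise_sd, "seed": params.seed,
        "oscillation": None if osc is None else {
            "period_s": osc.period_s, "amplitude": osc.amplitude,
            "ratchet_bias": osc.ratchet_bias},
    })
    return ts, gt
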