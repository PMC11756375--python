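"""Synthetic epithelial tissue movies with scripted intercalation kinematics.

A honeycomb cell sheet is evolved by *scripted* (prescribed, not force-based)
kinematics and rasterized into a label movie plus membrane and myosin
intensity channels:

* After the onset time t0, every interior interface follows the planar-
  polarized laws dl/dt = −v·cos 2θ and dθ/dt = −ω·sin 2θ (θ in embryo
  coordinates): vertical interfaces contract, horizontal ones elongate, and
  transverse interfaces rotate toward vertical.  Edge-wise prescriptions are
  converted to vertex velocities by averaging the contributions of the edges
  incident to each vertex.
* t1 transitions occur either on a script (named interface contracts to a
  higher-order vertex at t_vertex and resolves into the transverse contact by
  t_resolve) or automatically whenever an unscripted interior interface
  contracts below a threshold length — so interfaces that must first rotate
  toward vertical undergo their neighbor exchange later.
* Cell areas oscillate sinusoidally with per-cell uniform random phase under
  the convention A(ϕ) = b − c·cos ϕ (area minimum at ϕ = 0°), implemented as
  a display-time vertex displacement field.
* The membrane channel is the blurred cell-boundary mask; the myosin channel
  paints each interface with m0 + m1·cos 2θ (bright on vertical interfaces),
  decayed by photobleaching 2^(−t/halflife), on a ~4-px band, plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian

from ..kinematics import fold_angle
from ..tracks import GroundTruth
from .mesh import Pair, PolygonMesh


@dataclass
class ScriptedT1:
    """One scripted neighbor exchange: interface (cell_a, cell_b) contracts
    from t_contract_start, reaches the higher-order vertex at t_vertex and the
    new transverse contact is fully grown at t_resolve (minutes)."""

    cell_a: int
    cell_b: int
    t_contract_start_min: float
    t_vertex_min: float
    t_resolve_min: float

    def __post_init__(self) -> None:
        if not (self.t_contract_start_min < self.t_vertex_min < self.t_resolve_min):
            raise ValueError(
                "scripted t1 times must satisfy t_contract_start < t_vertex < t_resolve")

    @property
    def pair(self) -> frozenset:
        return Pair((self.cell_a, self.cell_b))


@dataclass
class TissueGenParams:
    """Conditions for :func:`generate_tissue_movie`."""

    grid: tuple[int, int] = (12, 12)
    edge_len_um: float = 2.5
    pixel_size: float = 0.15          # µm/px; 4 px ≈ 0.6 µm ROI geometry
    frame_interval_s: float = 15.0
    duration_min: float = 20.0
    image_shape: tuple[int, int] | None = None

    axis_offset_deg: float = 0.0      # true embryo-axis rotation δ
    t0_min: float = 5.0               # onset of the planar-polarized laws
    v_um_min: float = 0.5             # contraction-law amplitude
    omega_deg_min: float = 2.5        # rotation-law amplitude

    pos_jitter: float = 0.12          # quenched vertex jitter, fraction of edge length

    scripted_t1s: list[ScriptedT1] = field(default_factory=list)
    auto_t1: bool = True
    min_edge_um: float = 0.35         # flip threshold for automatic t1s
    resolved_len_um: float = 1.5      # scripted new-contact length at t_resolve

    osc_period_s: float = 120.0
    osc_amplitude: float = 0.1        # fractional cell-area oscillation

    myosin_m0: float = 1.0
    myosin_m1: float = 0.8            # m(θ) = m0 + m1·cos 2θ
    bleach_halflife_min: float = 10.0
    myosin_noise_sd: float = 20.0     # 16-bit counts
    membrane_noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid[0] < 4 or self.grid[1] < 4:
            raise ValueError("grid must be at least 4x4 so interior cells exist")
        if not 0.0 <= self.osc_amplitude < 1.0:
            raise ValueError("oscillation amplitude must be in [0, 1)")


@dataclass
class TissueMovie:
    """Rasterized movie stack: labels plus membrane and myosin channels."""

    labels: np.ndarray      # (T, H, W) uint16; 0 = boundary/background
    membrane: np.ndarray    # (T, H, W) uint16
    myosin: np.ndarray      # (T, H, W) uint16
    pixel_size: float       # µm/px
    dt_frame: float         # s

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


# --------------------------------------------------------------------- helpers
def _rotate_about(points: np.ndarray, center: np.ndarray, deg: float) -> np.ndarray:
    th = np.radians(deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (points - center) @ rot.T + center


def _rasterize(mesh: PolygonMesh, positions: np.ndarray, shape: tuple[int, int],
               pixel_size: float) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.uint16)
    count = np.zeros(shape, dtype=np.uint8)
    for cid in sorted(mesh.cells):
        poly = mesh.polygon(cid, positions) / pixel_size
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
        lab[rr, cc] = cid
        count[rr, cc] += 1
    lab[count != 1] = 0
    # enforce a ridge wherever 4-neighboring pixels carry different labels
    ridge = np.zeros(shape, dtype=bool)
    h = (lab[:, :-1] != lab[:, 1:]) & (lab[:, :-1] > 0) & (lab[:, 1:] > 0)
    v = (lab[:-1, :] != lab[1:, :]) & (lab[:-1, :] > 0) & (lab[1:, :] > 0)
    ridge[:, :-1] |= h
    ridge[:-1, :] |= v
    lab[ridge] = 0
    return lab


def _edge_arrays(mesh: PolygonMesh):
    pairs = sorted(mesh.edges, key=lambda p: tuple(sorted(p)))
    uu = np.array([mesh.edges[p][0] for p in pairs], dtype=int)
    ww = np.array([mesh.edges[p][1] for p in pairs], dtype=int)
    return pairs, uu, ww


def _theta_image(d: np.ndarray) -> np.ndarray:
    th = np.degrees(np.arctan2(d[..., 0], d[..., 1]))
    return fold_angle(th)


# ----------------------------------------------------------------------- main
def generate_tissue_movie(params: TissueGenParams
                          ) -> tuple[TissueMovie, GroundTruth]:
    """Simulate and rasterize a synthetic tissue movie with known ground truth.

    Returns the rasterized :class:`TissueMovie` (labels, membrane and myosin
    channels share registration) and a :class:`GroundTruth` with per-frame
    true interface lengths/angles/myosin, per-frame true cell areas and
    oscillation phases, all topological events, and the true δ and t0.
    Identical seed and parameters give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.grid
    mesh = PolygonMesh.hex_grid(rows, cols, params.edge_len_um)
    if params.pos_jitter > 0:
        # quenched disorder: real epithelia are not perfect honeycombs, and a
        # continuous spread of interface orientations is what the angle-binned
        # analyses assume
        mesh.positions = mesh.positions + rng.normal(
            0.0, params.pos_jitter * params.edge_len_um, size=mesh.positions.shape)
    center = mesh.positions.mean(axis=0)
    if params.axis_offset_deg:
        mesh.positions = _rotate_about(mesh.positions, center, params.axis_offset_deg)

    margin = 10 * params.pixel_size
    if params.image_shape is None:
        extent = mesh.positions.max(axis=0) + margin
        shape = (int(np.ceil(extent[1] / params.pixel_size)) + 10,
                 int(np.ceil(extent[0] / params.pixel_size)) + 10)
    else:
        shape = tuple(params.image_shape)
    # keep the mesh inside the frame
    mesh.positions = mesh.positions + margin - mesh.positions.min(axis=0)

    boundary = mesh.boundary_cells()
    for sc in params.scripted_t1s:
        if sc.pair not in mesh.edges:
            raise ValueError(f"scripted t1 interface {tuple(sorted(sc.pair))} "
                             "does not exist at t=0")
        if sc.cell_a in boundary or sc.cell_b in boundary:
            raise ValueError(f"scripted t1 interface {tuple(sorted(sc.pair))} "
                             "involves a boundary cell")
    if len({sc.pair for sc in params.scripted_t1s}) != len(params.scripted_t1s):
        raise ValueError("scripted t1 interfaces must be distinct")

    dt_min = params.frame_interval_s / 60.0
    n_frames = int(round(params.duration_min / dt_min)) + 1
    delta = params.axis_offset_deg

    # per-cell oscillation phase offsets (degrees), uniform
    cids = sorted(mesh.cells)
    phase0 = {cid: rng.uniform(0.0, 360.0) for cid in cids}

    # scripted-t1 runtime state
    script_state = [{"sc": sc, "phase": "waiting", "pair": sc.pair,
                     "l_start": None} for sc in params.scripted_t1s]

    truth_if_rows: list[tuple] = []
    truth_cell_rows: list[tuple] = []
    events: list[tuple] = []
    labels = np.zeros((n_frames,) + shape, dtype=np.uint16)
    membrane = np.zeros_like(labels)
    myosin = np.zeros_like(labels)

    def displaced_positions(t_min: float) -> np.ndarray:
        if params.osc_amplitude == 0.0:
            return mesh.positions.copy()
        pos = mesh.positions.copy()
        disp = np.zeros_like(pos)
        for cid in cids:
            phi = np.radians(360.0 * t_min * 60.0 / params.osc_period_s
                             + phase0[cid])
            s = np.sqrt(max(0.0, 1.0 - params.osc_amplitude * np.cos(phi)))
            vids = sorted(mesh.cells[cid])
            ctr = pos[vids].mean(axis=0)
            disp[vids] += (s - 1.0) * (pos[vids] - ctr)
        return pos + disp

    def record_frame(k: int, t_min: float) -> None:
        pos = displaced_positions(t_min)
        pairs, uu, ww = _edge_arrays(mesh)
        d = pos[ww] - pos[uu]
        lengths = np.hypot(d[:, 0], d[:, 1])
        th_img = _theta_image(d)
        th_emb = fold_angle(th_img - delta)
        bleach = 2.0 ** (-t_min / params.bleach_halflife_min)
        m_true = (params.myosin_m0
                  + params.myosin_m1 * np.cos(2 * np.radians(th_emb))) * bleach
        for p, l_um, te, mt, ti in zip(pairs, lengths, th_emb, m_true, th_img):
            a, b = sorted(p)
            truth_if_rows.append((a, b, k, t_min, l_um, te, ti, mt))
        for cid in cids:
            phi = (360.0 * t_min * 60.0 / params.osc_period_s + phase0[cid]) % 360.0
            truth_cell_rows.append((cid, k, t_min, mesh.cell_area(cid, pos), phi))

        lab = _rasterize(mesh, pos, shape, params.pixel_size)
        labels[k] = lab

        interior = ndi.binary_dilation(lab > 0, iterations=3)
        ridge = (lab == 0) & interior
        mem = gaussian(ridge.astype(float), sigma=1.0, preserve_range=True)
        mem = mem * 3000.0 + 100.0
        if params.membrane_noise_sd > 0:
            mem = mem + rng.normal(0.0, params.membrane_noise_sd, size=shape)
        membrane[k] = np.clip(mem, 0, 65535).astype(np.uint16)

        myo = np.zeros(shape, dtype=float)
        px = pos / params.pixel_size
        for p, mt in zip(pairs, m_true):
            u, w = mesh.edges[p]
            r0, c0 = int(round(px[u][1])), int(round(px[u][0]))
            r1, c1 = int(round(px[w][1])), int(round(px[w][0]))
            r0 = np.clip(r0, 0, shape[0] - 1); r1 = np.clip(r1, 0, shape[0] - 1)
            c0 = np.clip(c0, 0, shape[1] - 1); c1 = np.clip(c1, 0, shape[1] - 1)
            rr, cc = draw_line(r0, c0, r1, c1)
            np.maximum.at(myo, (rr, cc), mt)
        myo = ndi.grey_dilation(myo, footprint=ndi.generate_binary_structure(2, 1),
                                mode="constant")
        myo = ndi.grey_dilation(myo, footprint=ndi.generate_binary_structure(2, 1),
                                mode="constant")
        myo = myo * 1000.0 + 100.0
        if params.myosin_noise_sd > 0:
            myo = myo + rng.normal(0.0, params.myosin_noise_sd, size=shape)
        myosin[k] = np.clip(myo, 0, 65535).astype(np.uint16)

    def law_step(t_min: float, frozen: set[int]) -> None:
        if params.v_um_min == 0.0 and params.omega_deg_min == 0.0:
            return
        if t_min < params.t0_min:
            return
        pairs, uu, ww = _edge_arrays(mesh)
        pos = mesh.positions
        d = pos[ww] - pos[uu]
        lengths = np.hypot(d[:, 0], d[:, 1])
        ok = lengths > 1e-9
        th_emb = fold_angle(_theta_image(d) - delta)
        two_th = 2 * np.radians(th_emb)
        dl_dt = -params.v_um_min * np.cos(two_th)            # µm/min
        dth_dt = -np.radians(params.omega_deg_min) * np.sin(two_th)  # rad/min
        u_hat = np.where(ok[:, None], d / np.maximum(lengths, 1e-9)[:, None], 0.0)
        perp = np.stack([-u_hat[:, 1], u_hat[:, 0]], axis=1)
        # endpoint velocities: symmetric extension along the edge plus rotation
        # about the midpoint; θ = atan2(Δx, Δy) decreases under mathematically
        # positive rotation, hence the minus sign on the angular term.
        v_ext_w = 0.5 * dl_dt[:, None] * u_hat
        v_rot_w = (-dth_dt * 0.5 * lengths)[:, None] * perp
        vw = v_ext_w + v_rot_w
        vu = -vw
        # summed (not averaged) contributions: neighboring prescriptions
        # partially cancel geometrically, and summation keeps the realized
        # rates close to the prescribed per-edge laws
        vel = np.zeros_like(pos)
        np.add.at(vel, ww, vw)
        np.add.at(vel, uu, vu)
        if frozen:
            vel[sorted(frozen)] = 0.0
        mesh.positions = pos + vel * dt_min

    flip_len = 1.5 * params.min_edge_um
    refractory: dict[frozenset, int] = {}

    for k in range(n_frames):
        t_min = k * dt_min
        record_frame(k, t_min)
        if k == n_frames - 1:
            break

        # vertices under scripted control are exempt from the background laws
        frozen: set[int] = set()
        active_pairs: set[frozenset] = set()
        for st in script_state:
            if st["phase"] in ("contracting", "resolving") and st["pair"] in mesh.edges:
                frozen.update(mesh.edges[st["pair"]])
                active_pairs.add(st["pair"])
            elif st["phase"] == "waiting":
                active_pairs.add(st["pair"])

        law_step(t_min, frozen)

        t_next = (k + 1) * dt_min
        for st in script_state:
            sc: ScriptedT1 = st["sc"]
            if st["phase"] == "waiting" and t_next >= sc.t_contract_start_min:
                st["phase"] = "contracting"
                _, st["l_start"] = mesh.edge_vector(st["pair"])
            if st["phase"] == "contracting":
                if t_next >= sc.t_vertex_min:
                    if not mesh.can_flip(st["pair"]):
                        raise RuntimeError(
                            f"scripted t1 {tuple(sorted(st['pair']))} cannot flip")
                    a, b = sorted(st["pair"])
                    new_pair, _ = mesh.t1_flip(st["pair"], flip_len * 0.5)
                    c, dcell = sorted(new_pair)
                    events.append(("contraction", a, b, t_next,
                                   sc.t_vertex_min, True))
                    events.append(("appearance", c, dcell, t_next,
                                   sc.t_vertex_min, True))
                    st["pair"] = new_pair
                    st["phase"] = "resolving"
                else:
                    u, w = mesh.edges[st["pair"]]
                    m = 0.5 * (mesh.positions[u] + mesh.positions[w])
                    dvec, length = mesh.edge_vector(st["pair"])
                    frac = (sc.t_vertex_min - t_next) / \
                        (sc.t_vertex_min - sc.t_contract_start_min)
                    target = max(st["l_start"] * frac, 0.02)
                    u_hat = dvec / max(length, 1e-9)
                    mesh.positions[u] = m - 0.5 * target * u_hat
                    mesh.positions[w] = m + 0.5 * target * u_hat
            elif st["phase"] == "resolving":
                if t_next >= sc.t_resolve_min:
                    st["phase"] = "done"
                else:
                    u, w = mesh.edges[st["pair"]]
                    m = 0.5 * (mesh.positions[u] + mesh.positions[w])
                    dvec, length = mesh.edge_vector(st["pair"])
                    frac = (t_next - sc.t_vertex_min) / \
                        (sc.t_resolve_min - sc.t_vertex_min)
                    target = flip_len * 0.5 + \
                        (params.resolved_len_um - flip_len * 0.5) * frac
                    u_hat = dvec / max(length, 1e-9)
                    mesh.positions[u] = m - 0.5 * target * u_hat
                    mesh.positions[w] = m + 0.5 * target * u_hat

        # automatic neighbor exchanges for over-contracted unscripted edges
        active_pairs = {st["pair"] for st in script_state if st["phase"] != "done"}
        for pair in list(mesh.edges):
            if pair in active_pairs or refractory.get(pair, -1) >= k:
                continue
            _, length = mesh.edge_vector(pair)
            if length >= params.min_edge_um:
                continue
            if params.auto_t1 and mesh.can_flip(pair):
                a, b = sorted(pair)
                new_pair, _ = mesh.t1_flip(pair, flip_len)
                c, dcell = sorted(new_pair)
                events.append(("contraction", a, b, t_next, t_next, False))
                events.append(("appearance", c, dcell, t_next, t_next, False))
                refractory[new_pair] = k + int(round(2.0 / dt_min))
            else:
                mesh.clamp_edge(pair, params.min_edge_um)

    truth_if = pd.DataFrame(truth_if_rows, columns=[
        "cell_a", "cell_b", "frame", "t_min", "l_um", "theta_deg",
        "theta_image_deg", "myosin"])
    truth_cells = pd.DataFrame(truth_cell_rows, columns=[
        "cell_id", "frame", "t_min", "area_um2", "phase_deg"])
    ev = pd.DataFrame(events, columns=[
        "kind", "cell_a", "cell_b", "t_min", "t_vertex_min", "scripted"])
    gt = GroundTruth(
        interfaces=truth_if, events=ev, cells=truth_cells,
        delta_deg=params.axis_offset_deg, t0_min=params.t0_min,
        params={
            "grid": list(params.grid), "edge_len_um": params.edge_len_um,
            "pixel_size": params.pixel_size,
            "frame_interval_s": params.frame_interval_s,
            "duration_min": params.duration_min,
            "axis_offset_deg": params.axis_offset_deg,
            "t0_min": params.t0_min, "v_um_min": params.v_um_min,
            "omega_deg_min": params.omega_deg_min,
            "osc_period_s": params.osc_period_s,
            "osc_amplitude": params.osc_amplitude,
            "myosin_m0": params.myosin_m0, "myosin_m1": params.myosin_m1,
            "bleach_halflife_min": params.bleach_halflife_min,
            "seed": params.seed,
        })
    movie = TissueMovie(labels, membrane, myosin,
                        params.pixel_size, params.frame_interval_s)
    return movie, gt
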