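"""Segmentation, cell tracking, vertex and interface extraction.

The measurement substrate is a :class:`LabelMovie`: a T×H×W stack of integer
cell labels with 0 marking watershed ridges / background.  Vertices are the
positions where three or more cells meet; interfaces are the cell-pair
contacts, measured as the Euclidean distance between their two bounding
vertices; interface tracks link the per-frame records of a persistent cell
pair over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .kinematics import interface_angle, unwrap_angles, fold_angle
from .tracks import TrackSet, build_tracks_table


@dataclass
class LabelMovie:
    """Tracked label stack: persistent integer cell ids, 0 = ridge/background."""

    frames: np.ndarray          # (T, H, W) integer
    pixel_size: float           # µm/px
    dt_frame: float             # s
    t0_frame: int | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("label movie must be a T×H×W stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ------------------------------------------------------------------ watershed
def segment_frame(membrane: np.ndarray, smoothing_sigma: float = 1.0,
                  min_seed_area: int = 20) -> np.ndarray:
    """Seeded watershed of a membrane-marker image.

    Seeds are the connected components of the Gaussian-smoothed image below
    its Otsu threshold (cell interiors are dark, membrane ridges bright) with
    area ≥ ``min_seed_area``; the watershed is run on the smoothed image with
    ridge pixels labeled 0 (``watershed_line``).
    """
    img = np.asarray(membrane, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a single 2D intensity image")
    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if smoothed.max() == smoothed.min():
        raise ValueError("membrane image is constant; nothing to segment")
    thr = threshold_otsu(smoothed)
    seeds, n = ndi.label(smoothed < thr)
    if n:
        areas = np.bincount(seeds.ravel())[1:]
        keep = np.flatnonzero(areas >= min_seed_area) + 1
        seeds = np.where(np.isin(seeds, keep), seeds, 0)
        seeds, n = ndi.label(seeds > 0)
    if n == 0:
        raise ValueError(
            f"no watershed seeds found (smoothing sigma={smoothing_sigma}, "
            f"min_seed_area={min_seed_area}); adjust the smoothing parameter")
    return watershed(smoothed, markers=seeds, watershed_line=True).astype(np.int32)


# ------------------------------------------------------------------- tracking
def track_cells(frames: np.ndarray, pixel_size: float, dt_frame: float
                ) -> tuple[LabelMovie, pd.DataFrame]:
    """Propagate persistent cell ids by greedy maximum pixel overlap.

    Frame-0 labels seed the persistent ids.  Each later raw label is assigned
    the persistent id of the previous-frame cell it overlaps most (ties
    resolved toward the lowest candidate id); raw labels claiming an already
    taken id, or overlapping nothing, receive fresh ids.  Returns the
    relabeled movie and the cell table (cell_id, frame, centroid, area).
    """
    frames = np.asarray(frames)
    out = np.zeros_like(frames, dtype=np.int32)
    out[0] = frames[0]
    next_id = int(frames[0].max()) + 1
    for t in range(1, frames.shape[0]):
        prev, cur = out[t - 1], frames[t]
        mask = (prev > 0) & (cur > 0)
        if mask.any():
            combo = prev[mask].astype(np.int64) * (int(cur.max()) + 1) + cur[mask]
            uniq, cnt = np.unique(combo, return_counts=True)
            prev_ids = uniq // (int(cur.max()) + 1)
            cur_ids = uniq % (int(cur.max()) + 1)
            pairs = pd.DataFrame({"prev": prev_ids, "cur": cur_ids, "n": cnt})
        else:
            pairs = pd.DataFrame(columns=["prev", "cur", "n"])
        mapping: dict[int, int] = {}
        taken: set[int] = set()
        # larger overlap first; ties toward lower (prev, cur) ids for determinism
        pairs = pairs.sort_values(["n", "prev", "cur"],
                                  ascending=[False, True, True])
        for row in pairs.itertuples(index=False):
            if row.cur in mapping or row.prev in taken:
                continue
            mapping[int(row.cur)] = int(row.prev)
            taken.add(int(row.prev))
        relab = np.zeros(int(cur.max()) + 1, dtype=np.int32)
        for raw in np.unique(cur):
            if raw == 0:
                continue
            if int(raw) in mapping:
                relab[raw] = mapping[int(raw)]
            else:
                relab[raw] = next_id
                next_id += 1
        out[t] = relab[cur]

    return LabelMovie(out, pixel_size, dt_frame), label_cell_table(out)


def label_cell_table(frames: np.ndarray) -> pd.DataFrame:
    """Cell table (cell_id, frame, centroid x/y, area) of a tracked stack."""
    frames = np.asarray(frames)
    rows = []
    for t in range(frames.shape[0]):
        lab = frames[t]
        ids = np.unique(lab)
        ids = ids[ids > 0]
        if ids.size == 0:
            continue
        areas = np.bincount(lab.ravel())
        coms = ndi.center_of_mass(lab > 0, lab, ids)
        for cid, com in zip(ids, coms):
            rows.append((int(cid), t, com[1], com[0], int(areas[cid])))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "x", "y", "area_px"])


# ------------------------------------------------------------------- vertices
def _distinct_nonzero_stack(stack: np.ndarray) -> np.ndarray:
    """Number of distinct nonzero values along axis 0 of an integer stack."""
    s = np.sort(stack, axis=0)
    first = (s[0] > 0).astype(np.int16)
    diffs = ((s[1:] != s[:-1]) & (s[1:] > 0)).sum(axis=0).astype(np.int16)
    return first + diffs


def _neighborhood_stack(lab: np.ndarray) -> np.ndarray:
    """(9, H, W) stack of the 3×3 neighborhood values (zero-padded)."""
    p = np.pad(lab, 1)
    return np.stack([p[i:i + lab.shape[0], j:j + lab.shape[1]]
                     for i in range(3) for j in range(3)])


def extract_vertices(lab: np.ndarray) -> pd.DataFrame:
    """Vertices: positions where ≥3 cells meet.

    2×2 windows containing ≥3 distinct non-zero labels emit candidates
    directly (label images without ridges); ridge pixels are treated by their
    surrounding labels, emitting a candidate when their 3×3 neighborhood
    touches ≥3 cells.  Candidates within 2 px sharing an incident set are
    merged to their centroid.  Returns columns x, y, cells (frozenset).
    """
    lab = np.asarray(lab)
    cands: list[tuple[float, float, frozenset]] = []

    win = np.stack([lab[:-1, :-1], lab[:-1, 1:], lab[1:, :-1], lab[1:, 1:]])
    nwin = _distinct_nonzero_stack(win)
    for r, c in zip(*np.nonzero(nwin >= 3)):
        cells = frozenset(int(v) for v in win[:, r, c] if v > 0)
        cands.append((c + 0.5, r + 0.5, cells))

    nbh = _neighborhood_stack(lab)
    nn = _distinct_nonzero_stack(nbh)
    ridge_vertex = (lab == 0) & (nn >= 3)
    for r, c in zip(*np.nonzero(ridge_vertex)):
        cells = frozenset(int(v) for v in nbh[:, r, c] if v > 0)
        cands.append((float(c), float(r), cells))

    # merge near-duplicates with identical incident sets
    out: list[tuple[float, float, frozenset]] = []
    bysets: dict[frozenset, list[tuple[float, float]]] = {}
    for x, y, cells in cands:
        bysets.setdefault(cells, []).append((x, y))
    for cells in sorted(bysets, key=lambda s: tuple(sorted(s))):
        pts = np.array(sorted(bysets[cells]))
        used = np.zeros(len(pts), dtype=bool)
        for i in range(len(pts)):
            if used[i]:
                continue
            group = [i]
            used[i] = True
            changed = True
            while changed:
                changed = False
                for j in range(len(pts)):
                    if used[j]:
                        continue
                    if np.min(np.hypot(*(pts[group] - pts[j]).T)) <= 2.0:
                        group.append(j)
                        used[j] = True
                        changed = True
            ctr = pts[group].mean(axis=0)
            out.append((float(ctr[0]), float(ctr[1]), cells))
    return pd.DataFrame(out, columns=["x", "y", "cells"])


# ----------------------------------------------------------------- interfaces
def interface_ridge_pixels(lab: np.ndarray) -> dict[frozenset, np.ndarray]:
    """Map each adjacent cell pair to its ridge pixels (rows of (row, col)).

    A ridge pixel belongs to pair (a, b) when its 3×3 neighborhood contains
    both labels.  Pairs in direct pixel contact (no ridge) map to an empty
    array.
    """
    lab = np.asarray(lab)
    nbh = np.sort(_neighborhood_stack(lab), axis=0)
    nn = _distinct_nonzero_stack(nbh)
    pix: dict[frozenset, list[tuple[int, int]]] = {}
    for r, c in zip(*np.nonzero((lab == 0) & (nn >= 2))):
        vals = nbh[:, r, c]
        cells = sorted({int(v) for v in vals if v > 0})
        for a, b in combinations(cells, 2):
            pix.setdefault(frozenset((a, b)), []).append((r, c))
    out = {p: np.array(v, dtype=int) for p, v in pix.items()}

    # direct label-label contacts (hand-built arrays without ridges)
    for sa, sb in (((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
                   ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
                   ((slice(None, -1), slice(None, -1)), (slice(1, None), slice(1, None))),
                   ((slice(None, -1), slice(1, None)), (slice(1, None), slice(None, -1)))):
        la, lb = lab[sa], lab[sb]
        m = (la > 0) & (lb > 0) & (la != lb)
        if m.any():
            pairs = np.unique(np.stack([np.minimum(la[m], lb[m]),
                                        np.maximum(la[m], lb[m])]), axis=1)
            for a, b in pairs.T:
                out.setdefault(frozenset((int(a), int(b))),
                               np.empty((0, 2), dtype=int))
    return out


def extract_interfaces(lab: np.ndarray, vertices: pd.DataFrame,
                       pixel_size: float) -> pd.DataFrame:
    """Per-frame interface records for every adjacent cell pair.

    Endpoints are the two vertices whose incident sets contain both cells
    (the two with maximal separation if more than two qualify).  Length is
    the Euclidean endpoint distance in µm; pairs with exactly one such vertex
    are higher-order-vertex contacts recorded with length 0; pairs with none
    (clipped by the field edge) are flagged not measurable.
    """
    ridge = interface_ridge_pixels(lab)
    vx = vertices["x"].to_numpy(dtype=float)
    vy = vertices["y"].to_numpy(dtype=float)
    vsets = list(vertices["cells"])
    rows = []
    for pair in sorted(ridge, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        idx = [i for i, s in enumerate(vsets) if a in s and b in s]
        if len(idx) >= 2:
            if len(idx) > 2:
                pts = np.stack([vx[idx], vy[idx]], axis=1)
                dmat = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                                pts[:, None, 1] - pts[None, :, 1])
                i, j = np.unravel_index(np.argmax(dmat), dmat.shape)
                idx = [idx[i], idx[j]]
            (x1, y1), (x2, y2) = (vx[idx[0]], vy[idx[0]]), (vx[idx[1]], vy[idx[1]])
            l_um = float(np.hypot(x2 - x1, y2 - y1)) * pixel_size
            theta = interface_angle((x1, y1), (x2, y2))
            rows.append((a, b, x1, y1, x2, y2, l_um, theta, True))
        elif len(idx) == 1 and len(vsets[idx[0]]) >= 4:
            # pair meeting only at a higher-order vertex: zero-length contact
            rows.append((a, b, vx[idx[0]], vy[idx[0]], vx[idx[0]], vy[idx[0]],
                         0.0, np.nan, True))
        else:
            rows.append((a, b, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         False))
    return pd.DataFrame(rows, columns=[
        "cell_a", "cell_b", "x1", "y1", "x2", "y2", "l_um", "theta_deg",
        "measurable"])


# -------------------------------------------------------------------- linking
def link_interfaces(records: pd.DataFrame, cell_table: pd.DataFrame,
                    n_frames: int, dt_frame: float, pixel_size: float,
                    max_gap: int = 1) -> TrackSet:
    """Link per-frame interface records into :class:`TrackSet` tracks.

    ``records`` must carry a ``frame`` column.  Records of the same cell pair
    over contiguous frames form one track; gaps of ≤ ``max_gap`` frames are
    bridged by linear interpolation (angle interpolated on the unwrapped
    trajectory); longer gaps split the pair into separate tracks.  Causes:
    a track is *contracted* when both cells remain visible after its last
    frame, *left-field* when either cell leaves, *appeared-from-vertex* when
    both cells were visible but non-adjacent before its birth.
    """
    vis = {cid: (int(g["frame"].min()), int(g["frame"].max()))
           for cid, g in cell_table.groupby("cell_id")}
    per_rows = []
    birth_cause: dict[int, str] = {}
    end_cause: dict[int, str] = {}
    tid = 0
    for (a, b), grp in records.groupby(["cell_a", "cell_b"], sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        splits = np.nonzero(np.diff(frames) > max_gap + 1)[0] + 1
        for run in np.split(np.arange(len(frames)), splits):
            sub = grp.iloc[run]
            f = sub["frame"].to_numpy(dtype=int)
            full = np.arange(f[0], f[-1] + 1)
            l = np.interp(full, f, sub["l_um"].to_numpy(dtype=float))
            th_obs = sub["theta_deg"].to_numpy(dtype=float)
            okth = np.isfinite(th_obs)
            if okth.sum() >= 1:
                unw = np.full(len(f), np.nan)
                unw[okth] = unwrap_angles(th_obs[okth])
                theta = fold_angle(np.interp(full, f[okth], unw[okth]))
                if okth.sum() < len(f):
                    # keep NaN where the angle was undefined and not bridgeable
                    pass
            else:
                theta = np.full(len(full), np.nan)
            cols = {}
            for col in ("x1", "y1", "x2", "y2"):
                cols[col] = np.interp(full, f, sub[col].to_numpy(dtype=float))
            for i, fr in enumerate(full):
                per_rows.append((tid, a, b, int(fr), l[i], theta[i],
                                 cols["x1"][i], cols["y1"][i],
                                 cols["x2"][i], cols["y2"][i]))
            a_vis = vis.get(a, (0, -1))
            b_vis = vis.get(b, (0, -1))
            if full[0] == 0:
                birth_cause[tid] = "movie-start"
            elif a_vis[0] < full[0] and b_vis[0] < full[0]:
                birth_cause[tid] = "appeared-from-vertex"
            else:
                birth_cause[tid] = "entered-field"
            if full[-1] >= n_frames - 1:
                end_cause[tid] = "movie-end"
            elif a_vis[1] > full[-1] and b_vis[1] > full[-1]:
                end_cause[tid] = "contracted"
            else:
                end_cause[tid] = "left-field"
            tid += 1
    per_frame = pd.DataFrame(per_rows, columns=[
        "track_id", "cell_a", "cell_b", "frame", "l_um", "theta_deg",
        "x1", "y1", "x2", "y2"])
    tracks = build_tracks_table(per_frame, birth_cause, end_cause)
    return TrackSet(per_frame, tracks, dt_frame=dt_frame, pixel_size=pixel_size)
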