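"""Topological transition (t1) detection and per-cell transition statistics.

A t1 transition is the full contraction of a cell–cell interface to a
higher-order vertex followed by the growth of a new, transverse interface
between the former indirect neighbors.  Contractions and appearances are
read off the track causes, linked across the vertex through the cell
quartet, and summarized per cell by visibility duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import TrackSet


@dataclass
class T1Event:
    """One side of a topological transition, with its partner when linked."""

    kind: str                               # 'contraction' or 'appearance'
    cell_pair: tuple[int, int]
    t_min: float                            # t_last (contraction) / t_first
    partner_pair: tuple[int, int] | None = None
    partner_t_min: float | None = None
    t_vertex_min: float = np.nan            # midpoint when linked, else t_min
    track_id: int = -1
    starting_angle_deg: float = np.nan      # θ at t0 when visible from t0

    @property
    def linked(self) -> bool:
        return self.partner_pair is not None


def _adjacency_at(per_frame: pd.DataFrame, frame: int) -> dict[int, set[int]]:
    """Cell adjacency (neighbor sets) at one frame from the track table."""
    sub = per_frame[per_frame["frame"] == frame]
    adj: dict[int, set[int]] = {}
    for a, b in zip(sub["cell_a"].astype(int), sub["cell_b"].astype(int)):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def detect_t1_events(tracks: TrackSet, link_window_min: float = 3.0
                     ) -> list[T1Event]:
    """Detect contraction and appearance events and link them across vertices.

    Contractions are tracks ending with cause ``contracted`` (both cells
    still visible afterwards); appearances are tracks born with cause
    ``appeared-from-vertex``.  A contraction of pair {a, b} is linked to an
    appearance of pair {c, d} when c and d each neighbored both a and b at
    the contraction's last frame (the transverse pair of the t1 quartet) and
    |t_first − t_last| ≤ ``link_window_min``; with several candidates the
    nearest t_first wins.  For linked events t_vertex is the midpoint of
    (t_last, t_first); unlinked events carry their own bounding time.
    """
    pf = tracks.per_frame
    tt = tracks.tracks
    events: list[T1Event] = []

    contractions = []
    for tid, row in tt.iterrows():
        pair = (int(row["cell_a"]), int(row["cell_b"]))
        if row["end_cause"] == "contracted":
            t_last = float(tracks.time_min(
                np.array([int(row["death_frame"])]))[0])
            ev = T1Event("contraction", pair, t_last,
                         t_vertex_min=t_last, track_id=int(tid))
            events.append(ev)
            contractions.append((ev, int(row["death_frame"])))
        if row["birth_cause"] == "appeared-from-vertex":
            t_first = float(tracks.time_min(
                np.array([int(row["birth_frame"])]))[0])
            events.append(T1Event("appearance", pair, t_first,
                                  t_vertex_min=t_first, track_id=int(tid)))

    appearances = [e for e in events if e.kind == "appearance"]
    used: set[int] = set()
    for con, death_frame in contractions:
        a, b = con.cell_pair
        adj = _adjacency_at(pf, death_frame)
        common = adj.get(a, set()) & adj.get(b, set())
        best = None
        for k, app in enumerate(appearances):
            if k in used:
                continue
            c, d = app.cell_pair
            if not {c, d} <= common:
                continue
            gap = abs(app.t_min - con.t_min)
            if gap > link_window_min:
                continue
            if best is None or gap < best[0]:
                best = (gap, k)
        if best is not None:
            k = best[1]
            used.add(k)
            app = appearances[k]
            t_vertex = 0.5 * (con.t_min + app.t_min)
            con.partner_pair, con.partner_t_min = app.cell_pair, app.t_min
            app.partner_pair, app.partner_t_min = con.cell_pair, con.t_min
            con.t_vertex_min = app.t_vertex_min = t_vertex
    return events


# --------------------------------------------------------------- counting
@dataclass
class TransitionCounts:
    """Per-cell transition counts grouped by continuous visibility duration."""

    table: pd.DataFrame          # cell_id, visibility_min, n_contractions,
    #                              n_appearances, group
    group_edges_min: tuple[float, ...]

    def group_summary(self) -> pd.DataFrame:
        return (self.table.groupby("group", observed=True)
                [["n_contractions", "n_appearances"]]
                .agg(["mean", "sum", "count"]))


def _visibility_spans(cell_table: pd.DataFrame, dt_frame: float
                      ) -> pd.DataFrame:
    """Longest continuous visibility span per cell, in minutes."""
    rows = []
    for cid, grp in cell_table.groupby("cell_id"):
        f = np.sort(grp["frame"].to_numpy(dtype=int))
        splits = np.nonzero(np.diff(f) > 1)[0] + 1
        runs = np.split(f, splits)
        best = max(runs, key=len)
        rows.append((int(cid), (len(best) - 1) * dt_frame / 60.0,
                     int(best[0]), int(best[-1])))
    return pd.DataFrame(rows, columns=["cell_id", "visibility_min",
                                       "first_frame", "last_frame"])


def count_transitions(events: list[T1Event], cell_table: pd.DataFrame,
                      dt_frame: float,
                      group_edges_min: tuple[float, ...] = (5, 10, 15, 20, 25),
                      border_cells: set[int] | None = None
                      ) -> TransitionCounts:
    """Count transitions per cell, grouped by how long the cell was visible.

    Each contraction (appearance) increments ``n_contractions``
    (``n_appearances``) of exactly its two participating cells.  Cells in
    ``border_cells`` (field-border cells whose adjacency changes are
    censoring artifacts) are excluded.  Group labels are half-open
    ``[edge, next)`` intervals with ``<first`` and ``≥last`` end bins.
    """
    spans = _visibility_spans(cell_table, dt_frame)
    if border_cells:
        spans = spans[~spans["cell_id"].isin(border_cells)]
    nc: dict[int, int] = {}
    na: dict[int, int] = {}
    for ev in events:
        tgt = nc if ev.kind == "contraction" else na
        for cid in ev.cell_pair:
            tgt[cid] = tgt.get(cid, 0) + 1
    spans = spans.copy()
    spans["n_contractions"] = spans["cell_id"].map(nc).fillna(0).astype(int)
    spans["n_appearances"] = spans["cell_id"].map(na).fillna(0).astype(int)

    edges = tuple(sorted(group_edges_min))
    labels = [f"<{edges[0]} min"]
    labels += [f"{lo}-{hi} min" for lo, hi in zip(edges[:-1], edges[1:])]
    labels += [f">={edges[-1]} min"]
    bins = np.digitize(spans["visibility_min"].to_numpy(dtype=float),
                       np.asarray(edges, dtype=float))
    spans["group"] = pd.Categorical([labels[i] for i in bins],
                                    categories=labels, ordered=True)
    cols = ["cell_id", "visibility_min", "n_contractions", "n_appearances",
            "group"]
    return TransitionCounts(spans[cols].reset_index(drop=True), edges)


# ------------------------------------------------------- starting angles
def starting_angle_vs_t1_time(events: list[T1Event], tracks: TrackSet,
                              initial_rate_window_min: float = 2.0
                              ) -> pd.DataFrame:
    """Starting angle, t1 time, and initial contraction rate per linked event.

    Restricted to linked contraction events whose track exists at t = 0
    (calibrated onset).  The starting angle is θ at t = 0; the initial rate
    is the mean length-change rate over the first
    ``initial_rate_window_min`` minutes.  Requires calibrated tracks (t0 set)
    with rates computed.
    """
    if tracks.t0_min is None:
        raise ValueError("tracks are not calibrated (t0 undefined)")
    rows = []
    pf = tracks.per_frame
    has_rate = "rl_um_min" in pf.columns
    for ev in events:
        if ev.kind != "contraction" or not ev.linked:
            continue
        grp = pf[pf["track_id"] == ev.track_id]
        t = tracks.time_min(grp["frame"].to_numpy(dtype=int))
        at0 = np.nonzero(np.isclose(t, 0.0, atol=1e-9))[0]
        if len(at0) == 0 or t.min() > 0.0:
            continue  # interface not visible from onset
        theta0 = float(grp["theta_deg"].to_numpy(dtype=float)[at0[0]])
        if has_rate:
            sel = (t >= 0.0) & (t <= initial_rate_window_min)
            r = grp["rl_um_min"].to_numpy(dtype=float)[sel]
            r0 = float(np.nanmean(r)) if np.isfinite(r).any() else np.nan
        else:
            r0 = np.nan
        rows.append((ev.track_id, theta0, ev.t_vertex_min, r0))
    return pd.DataFrame(rows, columns=["track_id", "starting_angle_deg",
                                       "t_vertex_min", "initial_rl_um_min"])


def survival_of_initial_verticals(tracks: TrackSet,
                                  angle_tol_deg: float = 15.0) -> pd.DataFrame:
    """Count of initially vertical interfaces remaining over time.

    The cohort is every track visible at t = 0 with |θ(0)| ≤
    ``angle_tol_deg``; the curve counts how many remain un-contracted and
    in-field at each subsequent frame time.  Empty cohort → empty curve.
    """
    if tracks.t0_min is None:
        raise ValueError("tracks are not calibrated (t0 undefined)")
    pf = tracks.per_frame
    death_times = []
    for tid, grp in tracks.iter_tracks():
        t = tracks.time_min(grp["frame"].to_numpy(dtype=int))
        at0 = np.nonzero(np.isclose(t, 0.0, atol=1e-9))[0]
        if len(at0) == 0 or t.min() > 0.0:
            continue
        theta0 = grp["theta_deg"].to_numpy(dtype=float)[at0[0]]
        if not (np.isfinite(theta0) and abs(theta0) <= angle_tol_deg):
            continue
        death_times.append(float(t.max()))
    if not death_times:
        return pd.DataFrame(columns=["t_min", "n_remaining"])
    death_times = np.asarray(death_times)
    all_t = np.unique(tracks.time_min(pf["frame"].to_numpy(dtype=int)))
    all_t = all_t[all_t >= 0.0]
    remaining = [(t, int((death_times >= t).sum())) for t in all_t]
    return pd.DataFrame(remaining, columns=["t_min", "n_remaining"])
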