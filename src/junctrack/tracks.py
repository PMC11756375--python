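"""Containers for tracked cell-cell interfaces and simulation ground truth.

The central object is :class:`TrackSet`: a tidy per-(interface, frame) table
plus a per-track summary, shared by the generator, the segmentation/tracking
pipeline and every downstream measurement.  Lengths are stored in micrometres
and orientation angles in degrees over the half-open interval (-90, 90], where
0° is vertical (dorsoventral-axis aligned) and ±90° horizontal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

#: per-frame columns every TrackSet carries; endpoint and myosin columns are optional
PER_FRAME_COLUMNS = ["track_id", "cell_a", "cell_b", "frame", "l_um", "theta_deg"]
OPTIONAL_COLUMNS = ["x1", "y1", "x2", "y2", "m"]

#: how a track ended
END_CAUSES = ("contracted", "left-field", "movie-end")
#: how a track began
BIRTH_CAUSES = ("movie-start", "appeared-from-vertex", "entered-field", "unknown")


@dataclass
class TrackSet:
    """A set of interface tracks measured (or generated) on a common clock.

    Parameters
    ----------
    per_frame
        One row per (track, frame): columns ``track_id, cell_a, cell_b, frame,
        l_um, theta_deg`` and optionally ``x1, y1, x2, y2`` (endpoint pixel
        coordinates, x=column / y=row) and ``m`` (normalized myosin).
    tracks
        One row per track, indexed by ``track_id``: ``cell_a, cell_b,
        birth_frame, death_frame, birth_cause, end_cause``.
    dt_frame
        Frame interval in seconds.
    pixel_size
        Micrometres per pixel (NaN for abstract, non-imaged tracks).
    t0_min
        Onset of germband extension in minutes, set by calibration; frame 0
        maps to t = -t0_min ... i.e. ``t_min = frame * dt_frame / 60 - t0_min``
        once calibrated, and simply ``frame * dt_frame / 60`` before.
    delta_deg
        Embryo-axis offset already applied to ``theta_deg``.
    """

    per_frame: pd.DataFrame
    tracks: pd.DataFrame
    dt_frame: float
    pixel_size: float = float("nan")
    t0_min: float | None = None
    delta_deg: float = 0.0

    def __post_init__(self) -> None:
        missing = [c for c in PER_FRAME_COLUMNS if c not in self.per_frame.columns]
        if missing:
            raise ValueError(f"per_frame table lacks required columns {missing}")
        if self.dt_frame <= 0:
            raise ValueError("dt_frame must be positive")
        self.per_frame = self.per_frame.sort_values(["track_id", "frame"], kind="stable")
        self.per_frame = self.per_frame.reset_index(drop=True)

    # ------------------------------------------------------------------ time
    @property
    def dt_frame_min(self) -> float:
        return self.dt_frame / 60.0

    def time_min(self, frames: np.ndarray | pd.Series) -> np.ndarray:
        """Convert frame indices to minutes (relative to onset if calibrated)."""
        t = np.asarray(frames, dtype=float) * self.dt_frame_min
        if self.t0_min is not None:
            t = t - self.t0_min
        return t

    @property
    def t_min(self) -> np.ndarray:
        return self.time_min(self.per_frame["frame"].to_numpy())

    # ----------------------------------------------------------------- access
    @property
    def track_ids(self) -> np.ndarray:
        return self.tracks.index.to_numpy()

    def iter_tracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        """Yield (track_id, per-frame rows sorted by frame)."""
        for tid, grp in self.per_frame.groupby("track_id", sort=True):
            yield tid, grp

    def track(self, track_id: int) -> pd.DataFrame:
        return self.per_frame[self.per_frame["track_id"] == track_id]

    def __len__(self) -> int:
        return len(self.tracks)

    def copy(self) -> "TrackSet":
        return TrackSet(
            self.per_frame.copy(),
            self.tracks.copy(),
            self.dt_frame,
            self.pixel_size,
            self.t0_min,
            self.delta_deg,
        )

    # -------------------------------------------------------------------- io
    def to_csv(self, directory: str | Path, prefix: str = "interfaces") -> None:
        """Write the per-frame and per-track tables as plain CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pf = self.per_frame.copy()
        pf["t_min"] = self.t_min
        pf.to_csv(directory / f"{prefix}_frames.csv", index=False)
        meta = self.tracks.copy()
        meta.to_csv(directory / f"{prefix}_tracks.csv", index_label="track_id")
        with open(directory / f"{prefix}_meta.csv", "w") as fh:
            fh.write("dt_frame_s,pixel_size_um,t0_min,delta_deg\n")
            t0 = "" if self.t0_min is None else repr(self.t0_min)
            fh.write(f"{self.dt_frame!r},{self.pixel_size!r},{t0},{self.delta_deg!r}\n")

    @classmethod
    def from_csv(cls, directory: str | Path, prefix: str = "interfaces") -> "TrackSet":
        directory = Path(directory)
        pf = pd.read_csv(directory / f"{prefix}_frames.csv")
        pf = pf.drop(columns=[c for c in ("t_min",) if c in pf.columns])
        meta = pd.read_csv(directory / f"{prefix}_tracks.csv", index_col="track_id")
        hdr = pd.read_csv(directory / f"{prefix}_meta.csv")
        t0 = hdr["t0_min"].iloc[0]
        return cls(
            pf,
            meta,
            dt_frame=float(hdr["dt_frame_s"].iloc[0]),
            pixel_size=float(hdr["pixel_size_um"].iloc[0]),
            t0_min=None if pd.isna(t0) else float(t0),
            delta_deg=float(hdr["delta_deg"].iloc[0]),
        )


def build_tracks_table(per_frame: pd.DataFrame,
                       birth_cause: dict[int, str] | None = None,
                       end_cause: dict[int, str] | None = None) -> pd.DataFrame:
    """Summarize a per-frame table into the per-track table.

    Unspecified causes default to 'unknown' / 'movie-end'.
    """
    g = per_frame.groupby("track_id", sort=True)
    tab = pd.DataFrame({
        "cell_a": g["cell_a"].first(),
        "cell_b": g["cell_b"].first(),
        "birth_frame": g["frame"].min(),
        "death_frame": g["frame"].max(),
    })
    tab["birth_cause"] = [
        (birth_cause or {}).get(tid, "unknown") for tid in tab.index
    ]
    tab["end_cause"] = [
        (end_cause or {}).get(tid, "movie-end") for tid in tab.index
    ]
    return tab


@dataclass
class GroundTruth:
    """Everything the synthetic generator knows exactly.

    Attributes
    ----------
    interfaces
        Per (interface, frame): true ``l_um``, ``theta_deg`` and, when the
        generator used rate laws, the applied ``rate_l`` (µm/min) and
        ``rate_theta`` (°/min) for the step leaving that frame.
    events
        One row per topological event: ``kind`` in {contraction, appearance},
        ``cell_a, cell_b, t_min`` and for scripted t1s the scripted
        ``t_vertex_min``.
    cells
        Per (cell, frame): true ``area_um2`` and oscillation ``phase_deg``.
    delta_deg, t0_min
        True embryo-axis offset and onset time.
    params
        Echo of the generator parameters (plain dict, YAML-serializable).
    """

    interfaces: pd.DataFrame
    events: pd.DataFrame
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    delta_deg: float = 0.0
    t0_min: float | None = None
    params: dict = field(default_factory=dict)

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.interfaces.to_csv(directory / "truth_interfaces.csv", index=False)
        self.events.to_csv(directory / "truth_events.csv", index=False)
        if len(self.cells):
            self.cells.to_csv(directory / "truth_cells.csv", index=False)
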