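"""End-to-end assembly: label movie → linked interface tracks → calibrated rates."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import segmentation as seg
from .kinematics import (CalibrationResult, apply_calibration, calibrate,
                         compute_rates)
from .tracks import TrackSet


def movie_to_tracks(frames: np.ndarray, pixel_size: float, dt_frame: float,
                    tracked: bool = True, max_gap: int = 1
                    ) -> tuple[TrackSet, pd.DataFrame, seg.LabelMovie]:
    """Measure all interface tracks of a label movie.

    ``tracked=False`` first harmonizes per-frame labels into persistent ids by
    maximum-overlap tracking; ``tracked=True`` trusts the input ids as
    persistent (generator movies and pre-tracked segmentations).  Returns the
    linked tracks, the cell table and the LabelMovie.
    """
    frames = np.asarray(frames)
    if tracked:
        movie = seg.LabelMovie(frames.astype(np.int32), pixel_size, dt_frame)
        cell_table = seg.label_cell_table(movie.frames)
    else:
        movie, cell_table = seg.track_cells(frames, pixel_size, dt_frame)
    recs = []
    for t in range(movie.n_frames):
        lab = movie.frames[t]
        verts = seg.extract_vertices(lab)
        rec = seg.extract_interfaces(lab, verts, pixel_size)
        rec["frame"] = t
        recs.append(rec)
    records = pd.concat(recs, ignore_index=True)
    tracks = seg.link_interfaces(records, cell_table, movie.n_frames,
                                 dt_frame, pixel_size, max_gap=max_gap)
    return tracks, cell_table, movie


def measure_and_calibrate(frames: np.ndarray, pixel_size: float,
                          dt_frame: float, rate_dt_s: float = 30.0,
                          smooth_window: int = 3, tracked: bool = True
                          ) -> tuple[TrackSet, CalibrationResult, pd.DataFrame]:
    """Full kinematic pipeline: track, rate, calibrate, re-express angles.

    Returns the calibrated TrackSet (with rate columns recomputed in the
    embryo frame), the calibration result, and the cell table.
    """
    tracks, cell_table, _ = movie_to_tracks(frames, pixel_size, dt_frame,
                                            tracked=tracked)
    rated = compute_rates(tracks, dt_s=rate_dt_s, smooth_window=smooth_window)
    calib = calibrate(rated)
    out = apply_calibration(rated, calib)
    return out, calib, cell_table
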