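"""Shared fixtures: synthetic movies and track sets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from junctrack.pipeline import measure_and_calibrate, movie_to_tracks
from junctrack.synthetic import (ScriptedT1, TissueGenParams, TrackGenParams,
                                 generate_interface_tracks,
                                 generate_tissue_movie)


@pytest.fixture(scope="session")
def small_tissue():
    """10×10 default-law tissue movie (10 min) plus its ground truth."""
    params = TissueGenParams(grid=(10, 10), duration_min=10, seed=7)
    movie, truth = generate_tissue_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def small_tissue_tracks(small_tissue):
    """Linked (uncalibrated) tracks and cell table of the small tissue."""
    params, movie, _ = small_tissue
    tracks, cell_table, labmovie = movie_to_tracks(
        movie.labels, params.pixel_size, movie.dt_frame)
    return tracks, cell_table, labmovie


@pytest.fixture(scope="session")
def scripted_tissue():
    """Scripted-only movie with three staggered t1s.

    Background laws and automatic flips are off, so by construction the only
    topological events in the movie are the three scripted exchanges.
    """
    scripts = [ScriptedT1(45, 46, 4.0, 6.0, 8.0),
               ScriptedT1(27, 37, 6.0, 8.5, 10.5),
               ScriptedT1(63, 73, 8.0, 10.0, 12.0)]
    params = TissueGenParams(grid=(10, 10), duration_min=14, seed=11,
                             scripted_t1s=scripts, auto_t1=False,
                             v_um_min=0.0, omega_deg_min=0.0)
    movie, truth = generate_tissue_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def scripted_tissue_tracks(scripted_tissue):
    params, movie, _ = scripted_tissue
    tracks, calib, cell_table = measure_and_calibrate(
        movie.labels, params.pixel_size, movie.dt_frame)
    return tracks, calib, cell_table


@pytest.fixture(scope="session")
def default_tracks():
    """300 default-law interface tracks with ground truth (oscillation on)."""
    params = TrackGenParams(n_interfaces=300, duration_min=20, seed=5)
    tracks, truth = generate_interface_tracks(params)
    return params, tracks, truth


@pytest.fixture(scope="session")
def quiet_tracks():
    """Low-noise, oscillation-free tracks under the default laws."""
    params = TrackGenParams(n_interfaces=400, duration_min=20,
                            angle_noise_sd=1.0, length_noise_sd=0.02,
                            oscillation=None, seed=3)
    tracks, truth = generate_interface_tracks(params)
    return params, tracks, truth
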