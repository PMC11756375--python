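"""Interface ROIs, intensity normalization and rotation-aligned myosin."""

import numpy as np
import pandas as pd
import pytest

from junctrack.myosin import (_reference_time, interface_roi,
                              measure_interface_intensity, myosin_heatmap,
                              normalize_frame, rotation_aligned_myosin)
from junctrack.pipeline import movie_to_tracks
from junctrack.synthetic import TissueGenParams, generate_tissue_movie
from junctrack.tracks import TrackSet, build_tracks_table


def _two_cell_frame(h=21, w=21, ridge_col=10):
    lab = np.zeros((h, w), dtype=np.int32)
    lab[:, :ridge_col] = 1
    lab[:, ridge_col + 1:] = 2
    return lab


class TestInterfaceROI:
    def test_single_point_disc_oracle(self):
        # one ridge pixel, max_dist 3.5: the ROI is the 3.5-radius disc,
        # which contains exactly 49 px of a 21×21 frame (twice r=3 disc + ring)
        lab = np.zeros((21, 21), dtype=np.int32)
        ridge = np.array([[10, 10]])
        roi = interface_roi(lab, (1, 2), max_dist=3.5, ridge=ridge)
        rr, cc = np.mgrid[0:21, 0:21]
        expect = np.hypot(rr - 10.0, cc - 10.0) <= 3.5
        assert np.array_equal(roi, expect)
        assert roi.sum() == expect.sum()

    def test_symmetric_in_pair_order(self):
        lab = _two_cell_frame()
        a = interface_roi(lab, (1, 2), max_dist=3.0)
        b = interface_roi(lab, (2, 1), max_dist=3.0)
        assert np.array_equal(a, b)

    def test_monotone_in_max_dist(self):
        lab = _two_cell_frame()
        small = interface_roi(lab, (1, 2), max_dist=2.0)
        big = interface_roi(lab, (1, 2), max_dist=4.0)
        assert np.all(big[small])
        assert big.sum() > small.sum()

    def test_absent_pair_empty(self):
        lab = _two_cell_frame()
        roi = interface_roi(lab, (1, 7), max_dist=3.0)
        assert not roi.any()

    def test_parallel_interfaces_disjoint(self):
        lab = np.zeros((15, 31), dtype=np.int32)
        lab[:, :10] = 1
        lab[:, 11:20] = 2
        lab[:, 21:] = 3
        left = interface_roi(lab, (1, 2), max_dist=3.0)
        right = interface_roi(lab, (2, 3), max_dist=3.0)
        assert left.any() and right.any()
        assert not (left & right).any()

    def test_corridor_excludes_vertex_ends(self):
        lab = _two_cell_frame()
        ep = np.array([[10.0, 0.0], [10.0, 20.0]])  # (x, y) endpoints
        clipped = interface_roi(lab, (1, 2), max_dist=3.0, endpoints=ep,
                                end_margin=4.0)
        free = interface_roi(lab, (1, 2), max_dist=3.0)
        assert clipped.sum() < free.sum()
        assert not clipped[:2, :].any() and not clipped[-2:, :].any()
        assert clipped[10, 10]

    def test_short_interface_empty_under_margin(self):
        lab = _two_cell_frame()
        ep = np.array([[10.0, 8.0], [10.0, 12.0]])  # 4 px long, margin 4
        roi = interface_roi(lab, (1, 2), max_dist=3.0, endpoints=ep,
                            end_margin=4.0)
        assert not roi.any()


class TestNormalization:
    def test_zscore(self):
        rng = np.random.default_rng(0)
        img = rng.normal(50.0, 7.0, (64, 64))
        norm = normalize_frame(img)
        assert norm.mean() == pytest.approx(0.0, abs=1e-12)
        assert norm.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_frame_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            normalize_frame(np.full((8, 8), 3.0))

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.normal(100.0, 20.0, (32, 32))
        a = normalize_frame(img)
        b = normalize_frame(3.0 * img + 250.0)
        assert np.allclose(a, b, atol=1e-10)


def _toy_tracks_with_m(t, theta, m):
    n = len(t)
    pf = pd.DataFrame({
        "track_id": 0, "cell_a": 1, "cell_b": 2, "frame": np.arange(n),
        "l_um": 2.0, "theta_deg": np.asarray(theta, dtype=float),
        "m": np.asarray(m, dtype=float)})
    return TrackSet(pf, build_tracks_table(pf), dt_frame=float((t[1] - t[0]) * 60))


class TestReferenceTime:
    def test_hand_example(self):
        t = np.arange(6, dtype=float)
        ath = np.array([25.0, 22.0, 18.0, 14.0, 9.0, 7.0])
        assert _reference_time(t, ath, 20.0, 10.0) == pytest.approx(2.5)

    def test_no_crossing(self):
        t = np.arange(4, dtype=float)
        assert _reference_time(t, np.array([40.0, 35.0, 30.0, 25.0]),
                               20.0, 10.0) is None

    def test_starts_below_lower(self):
        t = np.arange(4, dtype=float)
        assert _reference_time(t, np.array([5.0, 6.0, 4.0, 3.0]),
                               20.0, 10.0) is None

    def test_bounce_above_upper_resets(self):
        # rises back above `upper` between the bracket points → use the later
        # clean descent
        t = np.arange(7, dtype=float)
        ath = np.array([30.0, 15.0, 25.0, 18.0, 12.0, 8.0, 6.0])
        assert _reference_time(t, ath, 20.0, 10.0) == pytest.approx(3.5)


class TestRotationAligned:
    def test_requires_m_column(self, quiet_tracks):
        _, tracks, _ = quiet_tracks
        with pytest.raises(ValueError, match="myosin column"):
            rotation_aligned_myosin(tracks)

    def test_aligned_profile(self):
        # deterministic descent through the 20°→10° band with rising m
        t = np.arange(0.0, 12.5, 0.5)
        theta = 40.0 - 3.0 * t
        m = 0.1 * t
        ts = _toy_tracks_with_m(t, theta, m)
        res = rotation_aligned_myosin(ts, upper_deg=20.0, lower_deg=10.0,
                                      window_min=2.0, bin_min=0.5)
        assert res.n_tracks == 1
        # reference: midpoint of |θ|=20 (t≈6.67→ last ≥20 at t=6.5) and
        # |θ|≤10 (first at t=10.0) → ref = 8.25 min
        mid = len(res.rel_time_min) // 2
        assert res.mean_theta[mid] == pytest.approx(
            40.0 - 3.0 * 8.25, abs=2.0)
        ok = np.isfinite(res.mean_m)
        assert np.all(np.diff(res.mean_m[ok]) > 0)  # m keeps rising

    def test_no_qualifying_tracks(self):
        t = np.arange(0.0, 5.0, 0.5)
        ts = _toy_tracks_with_m(t, np.full_like(t, 60.0), np.zeros_like(t))
        res = rotation_aligned_myosin(ts, window_min=1.0)
        assert res.n_tracks == 0
        assert not np.isfinite(res.mean_m).any()


@pytest.fixture(scope="module")
def measured_tissue(small_tissue, small_tissue_tracks):
    params, movie, truth = small_tissue
    tracks, _, _ = small_tissue_tracks
    m_tracks = measure_interface_intensity(movie.myosin, tracks, movie.labels)
    return params, movie, truth, m_tracks


class TestMeasureIntensity:
    def test_shape_mismatch_rejected(self, small_tissue, small_tissue_tracks):
        _, movie, _ = small_tissue
        tracks, _, _ = small_tissue_tracks
        with pytest.raises(ValueError, match="shape"):
            measure_interface_intensity(movie.myosin[:, :-1], tracks,
                                        movie.labels)

    def test_m_tracks_polarity(self, measured_tissue):
        # measured m anticorrelates with cos 2θ as painted by the generator
        _, _, _, m_tracks = measured_tissue
        pf = m_tracks.per_frame
        ok = np.isfinite(pf["m"]) & np.isfinite(pf["theta_deg"])
        r = np.corrcoef(pf.loc[ok, "m"],
                        np.cos(2 * np.radians(pf.loc[ok, "theta_deg"])))[0, 1]
        assert r >= 0.9

    def test_bleaching_invariance_of_normalized_m(self, measured_tissue):
        # z-scoring removes the global bleaching decay: the mean m of the
        # brightest (vertical) interfaces does not trend down with time
        _, _, _, m_tracks = measured_tissue
        pf = m_tracks.per_frame
        vertical = np.abs(pf["theta_deg"]) < 20.0
        by_frame = pf[vertical].groupby("frame")["m"].mean().dropna()
        first = by_frame.iloc[:5].mean()
        last = by_frame.iloc[-5:].mean()
        assert abs(last - first) <= 0.3

    def test_heatmap_max_is_vertical(self, measured_tissue):
        _, _, _, m_tracks = measured_tissue
        field = myosin_heatmap(m_tracks, time_bin_min=2.0, angle_bin_deg=10.0)
        centers = field.angle_centers
        for row, nrow in zip(field.mean, field.count):
            occ = (nrow >= 5) & np.isfinite(row)
            if occ.sum() < 3:
                continue
            best = centers[occ][np.argmax(row[occ])]
            assert abs(best) <= 15.0

    def test_affine_transform_invariance(self, measured_tissue):
        # per-frame affine intensity changes leave m untouched
        params, movie, _, m_tracks = measured_tissue
        rng = np.random.default_rng(3)
        warped = movie.myosin.astype(float).copy()
        for k in range(warped.shape[0]):
            warped[k] = warped[k] * rng.uniform(0.5, 3.0) + rng.uniform(0, 500)
        base_tracks = TrackSet(m_tracks.per_frame.drop(columns="m"),
                               m_tracks.tracks, dt_frame=m_tracks.dt_frame,
                               pixel_size=m_tracks.pixel_size)
        redo = measure_interface_intensity(warped, base_tracks, movie.labels)
        a = m_tracks.per_frame["m"].to_numpy()
        b = redo.per_frame["m"].to_numpy()
        ok = np.isfinite(a)
        assert np.array_equal(ok, np.isfinite(b))
        assert np.allclose(a[ok], b[ok], atol=1e-9)
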