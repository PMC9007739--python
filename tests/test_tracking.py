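"""Kalman trackers, association and the SORT-style tracking loop."""

import numpy as np
import pytest
from conftest import brute_force_assignment

from mapose.assembly import Assembly
from mapose.decoding import KeypointDetection
from mapose.tracking import (
    BoxTracker,
    EllipseTracker,
    associate,
    bbox_from_keypoints,
    ellipse_similarity,
    fit_ellipse,
    iou,
    track_video,
)


class TestBBox:
    def test_envelope_of_two_points(self):
        box = bbox_from_keypoints(np.array([[0, 0], [10, 20]]), margin=0)
        np.testing.assert_allclose(box, [0, 0, 10, 20])

    def test_single_point_with_margin(self):
        box = bbox_from_keypoints(np.array([[5, 5]]), margin=5)
        np.testing.assert_allclose(box, [0, 0, 10, 10])

    def test_margin_never_shrinks_area(self):
        rng = np.random.default_rng(0)
        pts = rng.random((6, 2)) * 50
        b0 = bbox_from_keypoints(pts, 0)
        b5 = bbox_from_keypoints(pts, 5)
        area = lambda b: (b[2] - b[0]) * (b[3] - b[1])
        assert area(b5) >= area(b0)


class TestFitEllipse:
    def test_points_on_x_axis_give_horizontal_major_axis(self):
        # symmetric points with sample s.d. 3 along x
        pts = np.array([[-3.0, 0.0], [3.0, 0.0], [-3.0, 0.0], [3.0, 0.0]])
        x, y, h, w, theta = fit_ellipse(pts)
        sd = np.std(pts[:, 0], ddof=1)
        assert theta == pytest.approx(0.0)
        assert h == pytest.approx(2 * sd)  # 2-sigma semi-axis

    def test_isotropic_cloud_reports_zero_angle(self):
        pts = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        *_, h, w, theta = fit_ellipse(pts)
        assert h == pytest.approx(w)
        assert theta == 0.0

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (20, 2)) * [4, 1]
        e0 = fit_ellipse(pts)
        ang = np.deg2rad(45)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        e45 = fit_ellipse(pts @ rot.T)
        assert e45[2] == pytest.approx(e0[2])
        assert e45[3] == pytest.approx(e0[3])
        d = e45[4] - e0[4]
        d = np.mod(d + np.pi / 2, np.pi) - np.pi / 2
        assert d == pytest.approx(ang - np.pi / 2, abs=1e-6) or d == pytest.approx(
            np.deg2rad(45), abs=1e-6
        )

    def test_degenerate_points_fall_back_to_circle(self):
        e = fit_ellipse(np.array([[2.0, 2.0], [2.0, 2.0]]), min_radius=3.0)
        np.testing.assert_allclose(e, [2, 2, 3, 3, 0])


class TestEllipseSimilarity:
    def test_identical_ellipses_score_one(self):
        e = np.array([10.0, 20.0, 5.0, 3.0, 0.4])
        assert ellipse_similarity(e, e) == pytest.approx(1.0)

    def test_distance_one_scores_zero_regardless_of_angle(self):
        e1 = np.array([0.0, 0.0, 5.0, 3.0, 0.0])
        e2 = np.array([5.0, 0.0, 5.0, 3.0, 1.0])  # d = 5/5 = 1
        assert ellipse_similarity(e1, e2) == pytest.approx(0.0)

    def test_coincident_with_90_degree_rotation_scores_08(self):
        e1 = np.array([0.0, 0.0, 5.0, 3.0, 0.0])
        e2 = np.array([0.0, 0.0, 5.0, 3.0, np.pi / 2])
        assert ellipse_similarity(e1, e2) == pytest.approx(0.8)

    def test_clamped_to_unit_interval_for_far_ellipses(self):
        e1 = np.array([0.0, 0.0, 2.0, 1.0, 0.0])
        e2 = np.array([100.0, 0.0, 2.0, 1.0, 0.0])
        assert ellipse_similarity(e1, e2) == 0.0


class TestIoU:
    def test_identical_boxes(self):
        b = np.array([0, 0, 4, 4])
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(np.array([0, 0, 1, 1]), np.array([5, 5, 6, 6])) == 0.0

    def test_half_offset_unit_squares(self):
        got = iou(np.array([0, 0, 1, 1]), np.array([0.5, 0, 1.5, 1]))
        assert got == pytest.approx(1 / 3)


class TestKalman:
    def test_velocities_zero_on_creation(self):
        trk = BoxTracker(0, np.array([10.0, 20.0, 100.0, 1.0]), 0)
        np.testing.assert_allclose(trk.kf.x[4:], 0.0)

    def test_constant_velocity_truth_predicted_exactly(self):
        trk = BoxTracker(0, np.array([0.0, 0.0, 100.0, 1.0]), 0)
        # suppress noise so the linear recursion is exact
        trk.kf.Q[:] = 0.0
        trk.kf.R[:] = 1e-12 * np.eye(4)
        for t in range(1, 6):
            trk.predict()
            trk.update(np.array([2.0 * t, 3.0 * t, 100.0, 1.0]))
        pred = trk.predict()
        assert pred[0] == pytest.approx(12.0, abs=1e-6)
        assert pred[1] == pytest.approx(18.0, abs=1e-6)

    def test_predict_only_advances_with_velocity(self):
        trk = BoxTracker(0, np.array([0.0, 0.0, 100.0, 1.0]), 0)
        trk.kf.x[4:6] = [5.0, -2.0]
        pred = trk.predict()
        np.testing.assert_allclose(pred[:2], [5.0, -2.0])

    def test_non_finite_observation_rejected(self):
        trk = BoxTracker(0, np.array([0.0, 0.0, 100.0, 1.0]), 0)
        before = trk.kf.x.copy()
        trk.update(np.array([np.nan, 0.0, 100.0, 1.0]))
        np.testing.assert_array_equal(trk.kf.x, before)


class TestAssociate:
    def test_single_confident_pair_matched(self):
        m, ur, uc = associate(np.array([[0.9]]), 0.6)
        assert m == [(0, 0)] and ur == [] and uc == []

    def test_below_threshold_dissolved(self):
        m, ur, uc = associate(np.array([[0.5]]), 0.6)
        assert m == [] and ur == [0] and uc == [0]

    @pytest.mark.parametrize("seed", range(20))
    def test_total_similarity_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sim = rng.random((6, 6))
        matches, _, _ = associate(sim, 0.0)
        got = sum(sim[r, c] for r, c in matches)
        assert got == pytest.approx(brute_force_assignment(sim))


def _frames_from_tracks(tracks, n_bodyparts=3, spread=4.0):
    """Build per-frame (assemblies, detections) from centroid trajectories."""
    n_frames = max(len(tr) for tr in tracks.values())
    frames = []
    offsets = np.array(
        [[np.cos(a), np.sin(a)] for a in np.linspace(0, 2 * np.pi, n_bodyparts, endpoint=False)]
    ) * spread
    for t in range(n_frames):
        dets, assemblies = [], []
        for tid, tr in tracks.items():
            if t >= len(tr) or tr[t] is None:
                continue
            asm = Assembly(connection_costs=[1.0])
            for k in range(n_bodyparts):
                idx = len(dets)
                x, y = np.asarray(tr[t]) + offsets[k]
                dets.append(KeypointDetection(k, x, y, 1.0, (0, 0)))
                asm.members[k] = idx
            assemblies.append(asm)
        frames.append((assemblies, dets))
    return frames


class TestTrackVideo:
    def test_two_separated_animals_give_two_full_tracklets(self):
        tracks = {
            0: [(10 + 2 * t, 20.0) for t in range(15)],
            1: [(100 - 2 * t, 80.0) for t in range(15)],
        }
        frames = _frames_from_tracks(tracks)
        tracklets = track_video(frames, method="ellipse")
        assert len(tracklets) == 2
        assert all(len(tr) == 15 for tr in tracklets)

    def test_min_hits_discards_single_frame_spurious_detection(self):
        tracks = {
            0: [(10 + 2 * t, 20.0) for t in range(10)],
            1: [(200.0, 200.0) if t == 4 else None for t in range(10)],
        }
        frames = _frames_from_tracks(tracks)
        tracklets = track_video(frames, method="ellipse", min_hits=2)
        assert len(tracklets) == 1
        assert len(tracklets[0]) == 10

    def test_gap_longer_than_max_age_splits_tracklet(self):
        traj = [
            (10 + 2 * t, 20.0) if not 5 <= t < 7 else None for t in range(15)
        ]
        frames = _frames_from_tracks({0: traj})
        tracklets = track_video(frames, method="ellipse", max_age=1)
        assert len(tracklets) == 2
        assert tracklets[0].end == 4 and tracklets[1].start == 7

    def test_default_parameters_give_contiguous_tracklets(self):
        rng = np.random.default_rng(3)
        traj = [
            None if rng.random() < 0.2 else (50 + t, 50 + 0.5 * t)
            for t in range(40)
        ]
        frames = _frames_from_tracks({0: traj})
        for tr in track_video(frames, method="ellipse", max_age=1, min_hits=1):
            fs = tr.frames
            assert fs == list(range(fs[0], fs[-1] + 1))

    def test_no_two_tracklets_share_a_frame_assembly(self):
        tracks = {
            0: [(30 + t, 40.0) for t in range(20)],
            1: [(90 - t, 40.0) for t in range(20)],
        }
        frames = _frames_from_tracks(tracks)
        tracklets = track_video(frames, method="box", iou_threshold=0.1)
        for t in range(20):
            holders = [tr for tr in tracklets if t in tr.observations]
            centroids = [tuple(tr.observations[t].centroid()) for tr in holders]
            assert len(set(centroids)) == len(centroids)
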