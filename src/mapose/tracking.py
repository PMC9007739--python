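"""Local tracking-by-detection: SORT-style Kalman trackers over assemblies.

Each assembled animal is summarized either as a bounding box (state
[x, y, A, r] with velocities on x, y, A) or as a 2-sigma covariance error
ellipse (state [x, y, h, w, theta] with velocities on all five), propagated
by a constant-velocity Kalman filter. Frame-to-frame association is a
bipartite matching (Hungarian algorithm) over IoU or an ellipse similarity
score, gated by ``iou_threshold``; trackers unseen for more than ``max_age``
frames are terminated and tracks shorter than ``min_hits`` discarded. The
output is a set of tracklets — temporally ordered assembly sequences sharing
one local identity — handed to the global stitcher.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .assembly import Assembly
from .decoding import KeypointDetection


@dataclass
class TrackletObservation:
    """Pose snapshot stored per tracked frame."""

    keypoints: dict[int, np.ndarray]  # bodypart -> (x, y)
    confidences: dict[int, float]
    score: float
    identity_probs: np.ndarray | None = None

    def centroid(self) -> np.ndarray:
        pts = np.array(list(self.keypoints.values()))
        return pts.mean(axis=0)


@dataclass
class Tracklet:
    """A temporally ordered sequence of observations under one local id."""

    id: int
    observations: dict[int, TrackletObservation] = field(default_factory=dict)

    @property
    def frames(self) -> list[int]:
        return sorted(self.observations)

    @property
    def start(self) -> int:
        return min(self.observations)

    @property
    def end(self) -> int:
        return max(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    def centroid_series(self) -> np.ndarray:
        return np.array(
            [self.observations[f].centroid() for f in self.frames]
        )

    def keypoints_at(self, frame: int) -> np.ndarray:
        obs = self.observations[frame]
        return np.array(list(obs.keypoints.values())).reshape(-1, 2)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def bbox_from_keypoints(points: np.ndarray, margin: float = 0.0) -> np.ndarray:
    """Axis-aligned envelope [x1, y1, x2, y2] expanded by ``margin``."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one keypoint")
    x1, y1 = pts.min(axis=0) - margin
    x2, y2 = pts.max(axis=0) + margin
    return np.array([x1, y1, x2, y2])


def iou(box1: np.ndarray, box2: np.ndarray) -> float:
    """Standard intersection-over-union of two [x1, y1, x2, y2] boxes."""
    xx1, yy1 = max(box1[0], box2[0]), max(box1[1], box2[1])
    xx2, yy2 = min(box1[2], box2[2]), min(box1[3], box2[3])
    inter = max(0.0, xx2 - xx1) * max(0.0, yy2 - yy1)
    a1 = (box1[2] - box1[0]) * (box1[3] - box1[1])
    a2 = (box2[2] - box2[0]) * (box2[3] - box2[1])
    union = a1 + a2 - inter
    return float(inter / union) if union > 0 else 0.0


def fit_ellipse(points: np.ndarray, min_radius: float = 1.0) -> np.ndarray:
    """2-sigma covariance error ellipse (x, y, h, w, theta) of a point set.

    Centre is the keypoint mean; semi-axes are 2 * sqrt of the covariance
    eigenvalues (h >= w); theta is the inclination of the major axis in
    (-pi/2, pi/2], 0 for isotropic clouds. Fewer than two distinct points
    fall back to a circle of ``min_radius``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    center = pts.mean(axis=0)
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        return np.array([center[0], center[1], min_radius, min_radius, 0.0])
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)
    h = 2.0 * np.sqrt(evals[1])
    w = 2.0 * np.sqrt(evals[0])
    if np.isclose(evals[0], evals[1]):
        theta = 0.0
    else:
        vx, vy = evecs[:, 1]
        theta = np.arctan2(vy, vx)
        if theta <= -np.pi / 2:
            theta += np.pi
        elif theta > np.pi / 2:
            theta -= np.pi
    h = max(h, min_radius * 1e-3)
    w = max(w, min_radius * 1e-3)
    return np.array([center[0], center[1], h, w, theta])


def ellipse_similarity(e1: np.ndarray, e2: np.ndarray) -> float:
    """Similarity c = 0.8 (1 - d) + 0.2 (1 - d) cos(theta_d - theta_p).

    d is the centroid distance normalized by the longest semi-axis of the
    pair, clamped to [0, 1] so that c stays within [0, 1]. Degenerate
    ellipses (max semi-axis 0): d = 0 if coincident, 1 otherwise.
    """
    dist = float(np.hypot(e1[0] - e2[0], e1[1] - e2[1]))
    longest = max(e1[2], e1[3], e2[2], e2[3])
    if longest <= 0:
        d = 0.0 if dist == 0 else 1.0
    else:
        d = min(dist / longest, 1.0)
    # ellipse orientation is pi-periodic: wrap the difference to (-pi/2, pi/2]
    dtheta = e1[4] - e2[4]
    dtheta = np.mod(dtheta + np.pi / 2, np.pi) - np.pi / 2
    return float(0.8 * (1 - d) + 0.2 * (1 - d) * np.cos(dtheta))


# ---------------------------------------------------------------------------
# Kalman filtering
# ---------------------------------------------------------------------------


class KalmanFilter:
    """Minimal linear Kalman filter (constant-velocity transition)."""

    def __init__(
        self,
        F: np.ndarray,
        H: np.ndarray,
        Q: np.ndarray,
        R: np.ndarray,
        x0: np.ndarray,
        P0: np.ndarray,
    ):
        self.F, self.H, self.Q, self.R = F, H, Q, R
        self.x = x0.astype(float)
        self.P = P0.astype(float)

    def predict(self) -> np.ndarray:
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        return self.x

    def update(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        y = z - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(len(self.x)) - K @ self.H) @ self.P
        return self.x


def _cv_matrices(n_obs: int, n_vel: int) -> tuple[np.ndarray, np.ndarray]:
    """Constant-velocity F and H for n_obs observed dims, first n_vel with
    velocities appended after the observed block."""
    dim = n_obs + n_vel
    F = np.eye(dim)
    for i in range(n_vel):
        F[i, n_obs + i] = 1.0
    H = np.zeros((n_obs, dim))
    H[:n_obs, :n_obs] = np.eye(n_obs)
    return F, H


class _BaseTracker:
    """Shared SORT bookkeeping for box and ellipse trackers.

    Noise covariances follow SORT conventions: large initial uncertainty on
    the unobservable velocities, modest process noise.
    """

    n_obs: int
    n_vel: int

    def __init__(self, tracker_id: int, measurement: np.ndarray, frame: int):
        F, H = _cv_matrices(self.n_obs, self.n_vel)
        dim = self.n_obs + self.n_vel
        P0 = np.eye(dim) * 10.0
        P0[self.n_obs :, self.n_obs :] *= 1000.0  # unobservable velocities
        Q = np.eye(dim) * 1e-2
        Q[self.n_obs :, self.n_obs :] *= 1e-2
        R = np.eye(self.n_obs) * 1.0
        x0 = np.zeros(dim)
        x0[: self.n_obs] = measurement  # velocities start at 0
        self.kf = KalmanFilter(F, H, Q, R, x0, P0)
        self.id = tracker_id
        self.hits = 1
        self.time_since_update = 0
        self.tracklet = Tracklet(tracker_id)

    def predict(self) -> np.ndarray:
        state = self.kf.predict()
        return state[: self.n_obs]

    def update(self, measurement: np.ndarray) -> None:
        if not np.all(np.isfinite(measurement)):
            return  # reject, stay predict-only
        self.kf.update(measurement)
        self.hits += 1
        self.time_since_update = 0


class BoxTracker(_BaseTracker):
    """State s = [x, y, A, r, vx, vy, vA]."""

    n_obs, n_vel = 4, 3

    @staticmethod
    def measure(assembly_points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        box = bbox_from_keypoints(assembly_points, margin)
        w, h = max(box[2] - box[0], 1e-6), max(box[3] - box[1], 1e-6)
        return np.array([(box[0] + box[2]) / 2, (box[1] + box[3]) / 2, w * h, w / h])

    def predicted_box(self) -> np.ndarray:
        x, y, area, ratio = self.kf.x[:4]
        area = max(area, 1e-6)
        ratio = max(ratio, 1e-6)
        w = np.sqrt(area * ratio)
        h = area / w
        return np.array([x - w / 2, y - h / 2, x + w / 2, y + h / 2])


class EllipseTracker(_BaseTracker):
    """State s = [x, y, h, w, theta, vx, vy, vh, vw, vtheta]."""

    n_obs, n_vel = 5, 5

    @staticmethod
    def measure(assembly_points: np.ndarray) -> np.ndarray:
        return fit_ellipse(assembly_points)

    def update(self, measurement: np.ndarray) -> None:
        if not np.all(np.isfinite(measurement)):
            return
        # unwrap theta toward the filter state to avoid +-pi/2 jumps
        meas = measurement.copy()
        theta_pred = self.kf.x[4]
        while meas[4] - theta_pred > np.pi / 2:
            meas[4] -= np.pi
        while meas[4] - theta_pred < -np.pi / 2:
            meas[4] += np.pi
        super().update(meas)

    def predicted_ellipse(self) -> np.ndarray:
        e = self.kf.x[:5].copy()
        e[2] = max(e[2], 1e-6)
        e[3] = max(e[3], 1e-6)
        return e


# ---------------------------------------------------------------------------
# Association and the tracking loop
# ---------------------------------------------------------------------------


def associate(
    similarity: np.ndarray,
    iou_threshold: float = 0.6,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one max-similarity matching with a minimum-similarity gate.

    Returns (matches, unmatched_rows, unmatched_cols); matches whose
    similarity falls below ``iou_threshold`` are dissolved.
    """
    if similarity.size == 0:
        return (
            [],
            list(range(similarity.shape[0])),
            list(range(similarity.shape[1])),
        )
    rows, cols = linear_sum_assignment(similarity, maximize=True)
    matches, mr, mc = [], set(), set()
    for r, c in zip(rows, cols):
        if similarity[r, c] >= iou_threshold:
            matches.append((int(r), int(c)))
            mr.add(int(r))
            mc.add(int(c))
    unmatched_rows = [r for r in range(similarity.shape[0]) if r not in mr]
    unmatched_cols = [c for c in range(similarity.shape[1]) if c not in mc]
    return matches, unmatched_rows, unmatched_cols


def _observation_from_assembly(
    assembly: Assembly,
    detections: Sequence[KeypointDetection],
    identity_probs: np.ndarray | None = None,
) -> TrackletObservation:
    kps = {p: detections[i].position for p, i in assembly.members.items()}
    confs = {p: detections[i].confidence for p, i in assembly.members.items()}
    probs = None
    if identity_probs is not None:
        probs = np.mean(
            [identity_probs[i] for i in assembly.members.values()], axis=0
        )
    return TrackletObservation(kps, confs, assembly.score, probs)


def track_video(
    frames: Sequence[tuple[Sequence[Assembly], Sequence[KeypointDetection]]],
    method: str = "ellipse",
    min_hits: int = 1,
    max_age: int = 1,
    iou_threshold: float = 0.6,
    box_margin: float = 0.0,
    identity_weight: float = 0.0,
    frame_identity_probs: Sequence[np.ndarray | None] | None = None,
) -> list[Tracklet]:
    """SORT-style loop (predict -> associate -> update/create/kill).

    ``frames[t]`` is (assemblies, detections) for frame t. ``method`` picks
    the tracker family ("box" with IoU similarity or "ellipse" with the
    ellipse similarity score). Trackers unmatched for more than ``max_age``
    consecutive frames are terminated; tracklets with fewer than
    ``min_hits`` observed frames are discarded. Output tracklets contain
    observed frames only (no predicted fill-in).

    With ``identity_weight`` > 0 and per-detection identity probabilities,
    the per-assembly soft vote (mean probability vector over bodyparts) is
    blended into the similarity: sim <- (1 - w) * sim + w * agreement,
    where agreement is the dot product of the tracker's running mean vote
    and the assembly's vote.
    """
    if method not in ("box", "ellipse"):
        raise ValueError("method must be 'box' or 'ellipse'")
    trackers: list[_BaseTracker] = []
    finished: list[Tracklet] = []
    next_id = 0

    def _measure(assembly, detections):
        pts = assembly.positions(detections)
        if method == "box":
            return BoxTracker.measure(pts, box_margin)
        return EllipseTracker.measure(pts)

    def _similarity(tracker, measurement) -> float:
        if method == "box":
            x, y, area, ratio = measurement
            w = np.sqrt(max(area, 1e-6) * max(ratio, 1e-6))
            h = max(area, 1e-6) / w
            det_box = np.array([x - w / 2, y - h / 2, x + w / 2, y + h / 2])
            return iou(tracker.predicted_box(), det_box)
        return ellipse_similarity(tracker.predicted_ellipse(), measurement)

    for t, (assemblies, detections) in enumerate(frames):
        probs = (
            frame_identity_probs[t]
            if frame_identity_probs is not None
            else None
        )
        for trk in trackers:
            trk.predict()
        measurements = [_measure(a, detections) for a in assemblies]
        sim = np.zeros((len(trackers), len(assemblies)))
        for i, trk in enumerate(trackers):
            for j, meas in enumerate(measurements):
                s = _similarity(trk, meas)
                if identity_weight > 0 and probs is not None and assemblies[j].members:
                    vote = np.mean(
                        [probs[d] for d in assemblies[j].members.values()], axis=0
                    )
                    trk_votes = [
                        o.identity_probs
                        for o in trk.tracklet.observations.values()
                        if o.identity_probs is not None
                    ]
                    if trk_votes:
                        agreement = float(np.mean(trk_votes, axis=0) @ vote)
                        s = (1 - identity_weight) * s + identity_weight * agreement
                sim[i, j] = s
        matches, unmatched_trk, unmatched_det = associate(sim, iou_threshold)

        for ti, aj in matches:
            trackers[ti].update(measurements[aj])
            trackers[ti].tracklet.observations[t] = _observation_from_assembly(
                assemblies[aj], detections, probs
            )
        for ti in unmatched_trk:
            trackers[ti].time_since_update += 1
        survivors = []
        for trk in trackers:
            if trk.time_since_update > max_age - 1:
                if len(trk.tracklet) >= min_hits:
                    finished.append(trk.tracklet)
            else:
                survivors.append(trk)
        trackers = survivors
        for aj in unmatched_det:
            trk_cls = BoxTracker if method == "box" else EllipseTracker
            trk = trk_cls(next_id, measurements[aj], t)
            next_id += 1
            trk.tracklet.observations[t] = _observation_from_assembly(
                assemblies[aj], detections, probs
            )
            trackers.append(trk)

    for trk in trackers:
        if len(trk.tracklet) >= min_hits:
            finished.append(trk.tracklet)
    finished.sort(key=lambda tr: (tr.start, tr.id))
    for new_id, tr in enumerate(finished):
        tr.id = new_id
    return finished
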