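"""Evaluation metrics: keypoint error, PCK, OKS-mAP, assembly quality,
CLEAR-MOT tracking scores, swap flagging and the Proximity Index.

The CLEAR-MOT accumulator follows the standard convention: ground-truth to
hypothesis correspondence is established per frame by distance-thresholded
optimal assignment, with matches from the previous frame persisting while
they stay within the threshold; MOTA = 1 - (misses + false positives +
switches) / total ground-truth objects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment


# ---------------------------------------------------------------------------
# Keypoint-level detection metrics
# ---------------------------------------------------------------------------


def rmse(pred: np.ndarray, gt: np.ndarray) -> float:
    """Root-mean-square of each ground-truth keypoint's distance to the
    closest predicted keypoint. NaN when there are no predictions."""
    gt = np.asarray(gt, dtype=float).reshape(-1, 2)
    pred = np.asarray(pred, dtype=float).reshape(-1, 2)
    if len(gt) == 0:
        raise ValueError("need at least one ground-truth keypoint")
    if len(pred) == 0:
        return float("nan")
    d = np.linalg.norm(gt[:, None] - pred[None, :], axis=-1).min(axis=1)
    return float(np.sqrt(np.mean(d**2)))


def pck(
    pred: np.ndarray,
    gt: np.ndarray,
    reference_distance: float,
    fraction: float = 1.0 / 3.0,
) -> float:
    """Fraction of predictions within ``fraction * reference_distance`` of
    their ground-truth keypoint (arrays aligned row-wise)."""
    if reference_distance <= 0:
        warnings.warn("zero reference distance; frame skipped")
        return float("nan")
    pred = np.asarray(pred, dtype=float).reshape(-1, 2)
    gt = np.asarray(gt, dtype=float).reshape(-1, 2)
    d = np.linalg.norm(pred - gt, axis=1)
    return float(np.mean(d <= fraction * reference_distance))


# ---------------------------------------------------------------------------
# OKS-mAP
# ---------------------------------------------------------------------------


def object_keypoint_similarity(
    pred: Mapping[int, np.ndarray],
    gt: Mapping[int, np.ndarray],
    area: float,
    kpt_sd: float = 0.1,
    swap_pairs: Sequence[tuple[int, int]] = (),
) -> float:
    """COCO-style OKS between one predicted and one true animal.

    oks = mean over labelled gt keypoints of exp(-d^2 / (2 area (2 sd)^2));
    an unpredicted keypoint contributes 0. Configured symmetric pairs are
    evaluated under the best flip (each pair independently, since a swap
    only affects its own two keypoints).
    """
    if not gt:
        return 0.0
    area = max(float(area), 1.0)
    var = 2.0 * area * (2.0 * kpt_sd) ** 2

    def _term(k: int, source: int) -> float:
        if source not in pred:
            return 0.0
        d2 = float(np.sum((np.asarray(pred[source]) - np.asarray(gt[k])) ** 2))
        return float(np.exp(-d2 / var))

    swapped_of = {}
    for a, b in swap_pairs:
        swapped_of[a], swapped_of[b] = b, a
    total = 0.0
    handled: set[int] = set()
    for k in gt:
        if k in handled:
            continue
        partner = swapped_of.get(k)
        if partner is not None and partner in gt:
            straight = _term(k, k) + _term(partner, partner)
            flipped = _term(k, partner) + _term(partner, k)
            total += max(straight, flipped)
            handled.update((k, partner))
        else:
            total += _term(k, k)
            handled.add(k)
    return total / len(gt)


def oks_map(
    pred_assemblies: Sequence[tuple[Mapping[int, np.ndarray], float]],
    gt_animals: Sequence[Mapping[int, np.ndarray]],
    kpt_sd: float = 0.1,
    thresholds: Sequence[float] | None = None,
    swap_pairs: Sequence[tuple[int, int]] = (),
) -> float:
    """Mean average precision over OKS thresholds 0.50 : 0.05 : 0.95.

    Predictions are (keypoints, score) pairs matched greedily in
    decreasing-score order to the unmatched ground-truth animal of highest
    OKS; AP uses all-point interpolation of the precision-recall curve.
    Ground-truth areas are the animals' bounding-box areas.
    """
    if thresholds is None:
        thresholds = np.arange(0.50, 0.951, 0.05)
    n_gt = len(gt_animals)
    if n_gt == 0:
        return float("nan")
    areas = []
    for gt in gt_animals:
        pts = np.array(list(gt.values())).reshape(-1, 2)
        extent = pts.max(axis=0) - pts.min(axis=0) if len(pts) else np.zeros(2)
        areas.append(float(extent[0] * extent[1]))
    order = sorted(
        range(len(pred_assemblies)), key=lambda i: -pred_assemblies[i][1]
    )
    oks_table = np.zeros((len(pred_assemblies), n_gt))
    for i, (pred, _) in enumerate(pred_assemblies):
        for j, gt in enumerate(gt_animals):
            oks_table[i, j] = object_keypoint_similarity(
                pred, gt, areas[j], kpt_sd, swap_pairs
            )

    aps = []
    for thr in thresholds:
        matched_gt: set[int] = set()
        tp_flags = []
        for i in order:
            cand = [
                (oks_table[i, j], j)
                for j in range(n_gt)
                if j not in matched_gt and oks_table[i, j] >= thr
            ]
            if cand:
                _, j = max(cand)
                matched_gt.add(j)
                tp_flags.append(1)
            else:
                tp_flags.append(0)
        tp = np.cumsum(tp_flags)
        fp = np.cumsum([1 - f for f in tp_flags])
        recall = tp / n_gt
        precision = tp / np.maximum(tp + fp, 1)
        # all-point interpolation
        ap = 0.0
        prev_r = 0.0
        for k in range(len(tp_flags)):
            if tp_flags[k]:
                p = float(np.max(precision[k:]))
                ap += (recall[k] - prev_r) * p
                prev_r = recall[k]
        aps.append(ap)
    return float(np.mean(aps)) if aps else 0.0


# ---------------------------------------------------------------------------
# Assembly quality
# ---------------------------------------------------------------------------


@dataclass
class AssemblyQuality:
    purity: float
    unconnected_fraction: float

    @property
    def connected_fraction(self) -> float:
        return 1.0 - self.unconnected_fraction


def assembly_quality(
    assemblies: Sequence, det_labels: Sequence[int]
) -> AssemblyQuality:
    """Purity and unconnected fraction of one frame's assemblies.

    ``det_labels[i]`` is the hidden ground-truth animal of detection i
    (-1 for clutter). Purity is, per assembly, the fraction of member
    keypoints belonging to its most frequent ground-truth animal, averaged
    over assemblies. The unconnected fraction counts true (non-clutter)
    detections left out of every assembly.
    """
    det_labels = list(det_labels)
    purities = []
    used: set[int] = set()
    for asm in assemblies:
        members = list(asm.members.values())
        used.update(members)
        labels = [det_labels[i] for i in members]
        if not labels:
            continue
        counts: dict[int, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        purities.append(max(counts.values()) / len(labels))
    true_dets = [i for i, lab in enumerate(det_labels) if lab >= 0]
    if true_dets:
        unconnected = sum(1 for i in true_dets if i not in used) / len(true_dets)
    else:
        unconnected = 0.0
    purity = float(np.mean(purities)) if purities else 0.0
    return AssemblyQuality(purity, float(unconnected))


# ---------------------------------------------------------------------------
# CLEAR-MOT
# ---------------------------------------------------------------------------


@dataclass
class MOTReport:
    mota: float
    misses: int
    false_positives: int
    switches: int
    fragments: int
    mostly_tracked: int
    n_objects: int
    n_frames: int

    def rate_per_animal_per_100_frames(self, count: int, n_animals: int) -> float:
        if n_animals == 0 or self.n_frames == 0:
            return float("nan")
        return 100.0 * count / (n_animals * self.n_frames)


def mot_evaluate(
    tracks: Mapping[int, Mapping[int, np.ndarray]],
    gt_tracks: Mapping[int, Mapping[int, np.ndarray]],
    match_threshold: float,
) -> MOTReport:
    """CLEAR-MOT accumulation over a whole sequence.

    ``tracks`` and ``gt_tracks`` map identity -> {frame -> (x, y)}.
    Matching persists across frames while the matched pair stays within
    ``match_threshold``; new correspondences minimize total distance.
    """
    frames = sorted(
        {f for tr in gt_tracks.values() for f in tr}
        | {f for tr in tracks.values() for f in tr}
    )
    last_match: dict[int, int] = {}
    matched_frames: dict[int, list[int]] = {g: [] for g in gt_tracks}
    misses = fps = switches = 0
    total_gt = 0

    for f in frames:
        gt_ids = [g for g in sorted(gt_tracks) if f in gt_tracks[g]]
        hyp_ids = [h for h in sorted(tracks) if f in tracks[h]]
        total_gt += len(gt_ids)
        kept: dict[int, int] = {}
        for g in gt_ids:
            h = last_match.get(g)
            if h is not None and h in hyp_ids and h not in kept.values():
                d = float(np.linalg.norm(gt_tracks[g][f] - tracks[h][f]))
                if d <= match_threshold:
                    kept[g] = h
        free_gt = [g for g in gt_ids if g not in kept]
        free_hyp = [h for h in hyp_ids if h not in kept.values()]
        pairs: dict[int, int] = dict(kept)
        if free_gt and free_hyp:
            dist = np.array(
                [
                    [
                        float(np.linalg.norm(gt_tracks[g][f] - tracks[h][f]))
                        for h in free_hyp
                    ]
                    for g in free_gt
                ]
            )
            cost = np.where(dist <= match_threshold, dist, 1e9)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if dist[r, c] <= match_threshold:
                    g, h = free_gt[r], free_hyp[c]
                    if g in last_match and last_match[g] != h:
                        switches += 1
                    pairs[g] = h
        misses += len(gt_ids) - len(pairs)
        fps += len(hyp_ids) - len(pairs)
        for g, h in pairs.items():
            last_match[g] = h
            matched_frames[g].append(f)

    fragments = 0
    mostly_tracked = 0
    for g, tr in gt_tracks.items():
        present = sorted(tr)
        matched = set(matched_frames.get(g, []))
        tracked_flags = [f in matched for f in present]
        # count tracked -> untracked -> tracked interruptions
        runs = [k for k, _ in itertools.groupby(tracked_flags)]
        fragments += max(0, (sum(1 for r in runs if r) - 1))
        if present and sum(tracked_flags) / len(present) >= 0.8:
            mostly_tracked += 1

    mota = 1.0 - (misses + fps + switches) / total_gt if total_gt else float("nan")
    return MOTReport(
        mota,
        misses,
        fps,
        switches,
        fragments,
        mostly_tracked,
        total_gt,
        len(frames),
    )


def flag_swaps(
    tracks: Mapping[int, Mapping[int, np.ndarray]],
) -> list[tuple[int, tuple[int, int]]]:
    """Flag frames where a pair of tracks' x and y coordinates
    simultaneously intersect between consecutive frames (likely swaps)."""
    flags = []
    ids = sorted(tracks)
    for a, b in itertools.combinations(ids, 2):
        common = sorted(set(tracks[a]) & set(tracks[b]))
        for f0, f1 in zip(common, common[1:]):
            if f1 != f0 + 1:
                continue
            dx0 = tracks[a][f0][0] - tracks[b][f0][0]
            dx1 = tracks[a][f1][0] - tracks[b][f1][0]
            dy0 = tracks[a][f0][1] - tracks[b][f0][1]
            dy1 = tracks[a][f1][1] - tracks[b][f1][1]
            if dx0 * dx1 < 0 and dy0 * dy1 < 0:
                flags.append((f1, (a, b)))
    return flags


# ---------------------------------------------------------------------------
# Dataset characterization
# ---------------------------------------------------------------------------


def proximity_index(frame_animals: Sequence[np.ndarray]) -> list[float]:
    """Per-animal crowding: a disk centred on the animal's centroid with
    radius just covering all its own keypoints; the index is the number of
    other animals' keypoints inside that disk divided by the animal's own
    keypoint count."""
    animals = [np.asarray(a, dtype=float).reshape(-1, 2) for a in frame_animals]
    out = []
    for i, pts in enumerate(animals):
        center = pts.mean(axis=0)
        radius = float(np.linalg.norm(pts - center, axis=1).max())
        count = 0
        for j, other in enumerate(animals):
            if j == i:
                continue
            count += int(
                np.sum(np.linalg.norm(other - center, axis=1) <= radius)
            )
        out.append(count / len(pts))
    return out
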