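"""Decode score maps, location-refinement fields and PAFs into detections.

The detection front-end: smooth each score-map channel, find local maxima by
max-pool non-maximum suppression, refine cell peaks to subpixel image
coordinates with the location-refinement offsets, and score candidate limb
connections by sampling the part-affinity field along the segment joining two
proposals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .synthdata import TargetTensors


@dataclass(frozen=True)
class KeypointDetection:
    """One candidate bodypart location decoded from the maps."""

    bodypart: int
    x: float
    y: float
    confidence: float
    source_cell: tuple[int, int]  # (p, q) = (col, row)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


def smooth_scoremaps(score_maps: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Per-channel Gaussian smoothing; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    maps = np.asarray(score_maps, dtype=float)
    if sigma == 0:
        return maps.copy()
    out = np.empty_like(maps)
    for k in range(maps.shape[-1]):
        ndimage.gaussian_filter(maps[..., k], sigma, output=out[..., k], mode="reflect")
    return out


def find_peaks(
    score_maps: np.ndarray,
    min_confidence: float = 0.01,
    nms_radius: int = 2,
) -> list[tuple[int, int, int, float]]:
    """Local maxima via max-pool NMS: (bodypart, p, q, value) tuples.

    A cell is a peak when it equals the maximum of its
    (2 * nms_radius + 1)^2 window and exceeds ``min_confidence``. On a
    plateau of equal values the cell with the lowest (p, then q) wins, so
    output is deterministic.
    """
    maps = np.asarray(score_maps, dtype=float)
    size = 2 * nms_radius + 1
    peaks: list[tuple[int, int, int, float]] = []
    hg, wg = maps.shape[:2]
    for k in range(maps.shape[-1]):
        chan = maps[..., k]
        pooled = ndimage.maximum_filter(chan, size=size, mode="constant", cval=-np.inf)
        rows, cols = np.nonzero((chan >= pooled) & (chan > min_confidence))
        for q, p in zip(rows.tolist(), cols.tolist()):
            v = chan[q, p]
            # plateau tie-break: reject if an equal-valued cell with smaller
            # (p, q) lies inside the window
            q0, q1 = max(0, q - nms_radius), min(hg, q + nms_radius + 1)
            p0, p1 = max(0, p - nms_radius), min(wg, p + nms_radius + 1)
            window = chan[q0:q1, p0:p1]
            tie_rows, tie_cols = np.nonzero(window == v)
            keep = True
            for tq, tp in zip(tie_rows + q0, tie_cols + p0):
                if (tp, tq) < (p, q):
                    keep = False
                    break
            if keep:
                peaks.append((k, int(p), int(q), float(v)))
    peaks.sort(key=lambda t: (t[0], t[1], t[2]))
    return peaks


def refine_locations(
    peaks: Sequence[tuple[int, int, int, float]],
    locref: np.ndarray,
    stride: int,
) -> list[KeypointDetection]:
    """Map grid peaks to subpixel image coordinates:

    x = p * stride + stride / 2 + Lx(p, q), and likewise for y.
    """
    detections = []
    for k, p, q, value in peaks:
        lx, ly = locref[q, p, k]
        x = p * stride + stride / 2.0 + lx
        y = q * stride + stride / 2.0 + ly
        detections.append(
            KeypointDetection(k, float(x), float(y), float(value), (p, q))
        )
    return detections


def _paf_at(
    pafs: np.ndarray, limb: int, x: float, y: float, stride: int, lookup: str
) -> np.ndarray:
    """Read the 2-vector of limb ``limb`` at full-image point (x, y)."""
    hg, wg = pafs.shape[:2]
    p = (x - stride / 2.0) / stride
    q = (y - stride / 2.0) / stride
    if lookup == "nearest":
        pi = int(np.clip(round(p), 0, wg - 1))
        qi = int(np.clip(round(q), 0, hg - 1))
        return pafs[qi, pi, 2 * limb : 2 * limb + 2]
    # bilinear
    p = float(np.clip(p, 0, wg - 1))
    q = float(np.clip(q, 0, hg - 1))
    p0, q0 = int(p), int(q)
    p1, q1 = min(p0 + 1, wg - 1), min(q0 + 1, hg - 1)
    fp, fq = p - p0, q - q0
    v = (
        pafs[q0, p0, 2 * limb : 2 * limb + 2] * (1 - fp) * (1 - fq)
        + pafs[q0, p1, 2 * limb : 2 * limb + 2] * fp * (1 - fq)
        + pafs[q1, p0, 2 * limb : 2 * limb + 2] * (1 - fp) * fq
        + pafs[q1, p1, 2 * limb : 2 * limb + 2] * fp * fq
    )
    return v


def paf_line_cost(
    pafs: np.ndarray,
    limb: int,
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    stride: int,
    n_samples: int = 10,
    cost: str = "projection",
    lookup: str = "nearest",
) -> float:
    """Length-normalized line integral of the PAF between two proposals.

    Averages the field over ``n_samples`` equally spaced points (endpoints
    included) of the segment from ``pos_i`` to ``pos_j``. With
    ``cost="projection"`` each sample is projected on the segment's unit
    direction (sign-discriminative; reversing the segment flips the sign on
    a constant field); ``cost="norm"`` averages the raw field magnitude.
    A zero-length segment reduces to the value at that single point.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    seg = pos_j - pos_i
    length = float(np.hypot(*seg))
    if length < 1e-12:
        v = _paf_at(pafs, limb, pos_i[0], pos_i[1], stride, lookup)
        return float(np.hypot(*v)) if cost == "norm" else float(v[0])
    u = seg / length
    ts = np.linspace(0.0, 1.0, n_samples)
    total = 0.0
    for t in ts:
        x, y = pos_i + t * seg
        v = _paf_at(pafs, limb, x, y, stride, lookup)
        total += np.hypot(*v) if cost == "norm" else float(v @ u)
    return float(total / n_samples)


def build_affinity_tables(
    detections: Sequence[KeypointDetection],
    pafs: np.ndarray,
    graph: Sequence[tuple[int, int]],
    stride: int,
    n_samples: int = 10,
    cost: str = "projection",
    lookup: str = "nearest",
) -> dict[tuple[int, int], np.ndarray]:
    """Dense per-edge cost tables over all cross pairs of endpoint proposals.

    Returns a map edge -> (n_i, n_j) array of ``paf_line_cost`` values,
    where rows index detections of bodypart i and columns those of
    bodypart j (in the order they appear in ``detections``). An endpoint
    with no proposals yields an empty table.
    """
    by_part: dict[int, list[int]] = {}
    for idx, det in enumerate(detections):
        by_part.setdefault(det.bodypart, []).append(idx)
    tables: dict[tuple[int, int], np.ndarray] = {}
    for limb, (i, j) in enumerate(graph):
        rows = by_part.get(i, [])
        cols = by_part.get(j, [])
        table = np.zeros((len(rows), len(cols)))
        for ri, di in enumerate(rows):
            for cj, dj in enumerate(cols):
                table[ri, cj] = paf_line_cost(
                    pafs,
                    limb,
                    detections[di].position,
                    detections[dj].position,
                    stride,
                    n_samples=n_samples,
                    cost=cost,
                    lookup=lookup,
                )
        tables[(i, j)] = table
    return tables


def decode_frame(
    targets: TargetTensors,
    sigma: float = 1.0,
    min_confidence: float = 0.01,
    nms_radius: int = 2,
) -> list[KeypointDetection]:
    """Full decoding chain: smooth, peak-find, refine."""
    smoothed = smooth_scoremaps(targets.score_maps, sigma)
    peaks = find_peaks(smoothed, min_confidence, nms_radius)
    return refine_locations(peaks, targets.locref, targets.stride)
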