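"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, O(n^2)
comparisons, brute-force recursion): they define ground truth for the
optimized implementations and must stay independent of the code under test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mapose.config import PipelineConfig
from mapose.synthdata import SceneConfig, generate_scene


@pytest.fixture
def pipeline_config():
    return PipelineConfig()

@pytest.fixture
def small_scene_config():
    return SceneConfig(
        n_animals=2,
        n_bodyparts=4,
        n_frames=10,
        image_size=(128, 128),
        body_scale=12,
        occlusion_rate=0.0,
        jitter_sd=0.0,
        dropout=0.0,
        clutter_rate=0.0,
        seed=7,
    )


@pytest.fixture
def small_scene(small_scene_config):
    return generate_scene(small_scene_config)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_assignment(table: np.ndarray) -> float:
    """Max-total one-to-one assignment by enumerating all permutations."""
    n_r, n_c = table.shape
    best = -np.inf
    if n_r <= n_c:
        for perm in itertools.permutations(range(n_c), n_r):
            best = max(best, sum(table[r, c] for r, c in enumerate(perm)))
    else:
        for perm in itertools.permutations(range(n_r), n_c):
            best = max(best, sum(table[r, c] for c, r in enumerate(perm)))
    return float(best)


def brute_force_local_maxima(
    chan: np.ndarray, nms_radius: int, min_confidence: float
) -> set[tuple[int, int]]:
    """Exhaustive scan for window maxima with the lowest-(p, q) tie-break."""
    hg, wg = chan.shape
    out = set()
    for q in range(hg):
        for p in range(wg):
            v = chan[q, p]
            if v <= min_confidence:
                continue
            ok = True
            for dq in range(-nms_radius, nms_radius + 1):
                for dp in range(-nms_radius, nms_radius + 1):
                    qq, pp = q + dq, p + dp
                    if not (0 <= qq < hg and 0 <= pp < wg):
                        continue
                    if (qq, pp) == (q, p):
                        continue
                    other = chan[qq, pp]
                    if other > v or (other == v and (pp, qq) < (p, q)):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                out.add((p, q))
    return out


def pairwise_auroc(pos_samples: np.ndarray, neg_samples: np.ndarray) -> float:
    """O(n^2) Mann-Whitney: P(pos > neg) + 0.5 P(pos == neg)."""
    wins = ties = 0
    for p in pos_samples:
        for n in neg_samples:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_samples) * len(neg_samples))


def brute_force_partition(
    tables: dict[tuple[int, int], np.ndarray],
    counts: dict[int, int],
    graph: list[tuple[int, int]],
    n_slots: int,
) -> tuple[float, dict[int, tuple[int, ...]]]:
    """Exhaustive max-total-affinity partition.

    Every bodypart has ``counts[part]`` detections, each assigned
    injectively to one of ``n_slots`` animal slots; the objective sums,
    per slot and per graph edge, the affinity of the slot's detection
    pair. Returns (best total, best per-part permutation).
    """
    parts = sorted(counts)
    perms_per_part = [
        list(itertools.permutations(range(n_slots), counts[p])) for p in parts
    ]
    part_idx = {p: i for i, p in enumerate(parts)}
    best, best_assign = -np.inf, None
    for combo in itertools.product(*perms_per_part):
        total = 0.0
        for (a, b) in graph:
            pa, pb = combo[part_idx[a]], combo[part_idx[b]]
            table = tables[(a, b)]
            # detection r of part a sits in slot pa[r]
            slot_of_a = {slot: r for r, slot in enumerate(pa)}
            slot_of_b = {slot: c for c, slot in enumerate(pb)}
            for slot in set(slot_of_a) & set(slot_of_b):
                total += table[slot_of_a[slot], slot_of_b[slot]]
        if total > best:
            best, best_assign = total, dict(zip(parts, combo))
    return float(best), best_assign


def brute_force_path_cover(
    spans: list[tuple[int, int]],
    weights: dict[tuple[int, int], int],
    k: int,
    max_gap: int,
) -> float | None:
    """Minimum-cost cover of all tracklets with exactly k node-disjoint
    chains, by recursive assignment in temporal order."""
    order = sorted(range(len(spans)), key=lambda i: spans[i][0])
    best = [None]

    def rec(idx: int, chain_ends: list[int], cost: int) -> None:
        if best[0] is not None and cost >= best[0]:
            return
        if idx == len(order):
            if len(chain_ends) == k:
                best[0] = cost if best[0] is None else min(best[0], cost)
            return
        i = order[idx]
        for ci, end_node in enumerate(chain_ends):
            gap = spans[i][0] - spans[end_node][1]
            if 0 < gap <= max_gap and (end_node, i) in weights:
                chain_ends[ci] = i
                rec(idx + 1, chain_ends, cost + weights[(end_node, i)])
                chain_ends[ci] = end_node
        if len(chain_ends) < k:
            chain_ends.append(i)
            rec(idx + 1, chain_ends, cost)
            chain_ends.pop()

    rec(0, [], 0)
    return best[0]


def make_tracklet(tid, frames, centroids, spread=2.0):
    """Tracklet whose 2 keypoints straddle the given centroids."""
    from mapose.tracking import Tracklet, TrackletObservation

    tr = Tracklet(tid)
    for f, c in zip(frames, centroids):
        c = np.asarray(c, dtype=float)
        kps = {0: c + [spread, 0.0], 1: c - [spread, 0.0]}
        tr.observations[f] = TrackletObservation(kps, {0: 1.0, 1: 1.0}, 1.0)
    return tr


def linear_tracklet(tid, start, length, origin, velocity):
    frames = list(range(start, start + length))
    centroids = [
        np.asarray(origin, float) + np.asarray(velocity, float) * i
        for i in range(length)
    ]
    return make_tracklet(tid, frames, centroids)


def random_stitch_instance(rng, k, max_gap=5):
    """Random feasible stitching instance built from k ground-truth chains."""
    spans = []
    for _ in range(k):
        t = 0
        for _ in range(rng.integers(2, 5)):
            length = int(rng.integers(2, 5))
            spans.append((t, t + length - 1))
            t += length + int(rng.integers(1, 4))
    spans = spans[:10]
    tracklets = [
        linear_tracklet(i, s, e - s + 1, rng.uniform(0, 50, 2), (1, 0))
        for i, (s, e) in enumerate(spans)
    ]
    weights = {}
    for i, (_, e1) in enumerate(spans):
        for j, (s2, _) in enumerate(spans):
            if 0 < s2 - e1 <= max_gap:
                weights[(i, j)] = float(rng.random())
    return tracklets, spans, weights, max_gap


def reference_clear_mot(
    tracks: dict[int, dict[int, np.ndarray]],
    gt_tracks: dict[int, dict[int, np.ndarray]],
    threshold: float,
) -> tuple[int, int, int]:
    """From-scratch CLEAR-MOT counts (misses, false positives, switches).

    Same convention as the package implementation but written
    independently: persistent matches kept while within threshold, new
    correspondences by brute-force minimum-total-distance assignment.
    """
    frames = sorted(
        {f for tr in gt_tracks.values() for f in tr}
        | {f for tr in tracks.values() for f in tr}
    )
    last: dict[int, int] = {}
    misses = fps = switches = 0
    for f in frames:
        gts = [g for g in sorted(gt_tracks) if f in gt_tracks[g]]
        hyps = [h for h in sorted(tracks) if f in tracks[h]]
        kept = {}
        for g in gts:
            h = last.get(g)
            if h is not None and h in hyps and h not in kept.values():
                if np.linalg.norm(gt_tracks[g][f] - tracks[h][f]) <= threshold:
                    kept[g] = h
        free_g = [g for g in gts if g not in kept]
        free_h = [h for h in hyps if h not in kept.values()]
        best_pairs: dict[int, int] = {}
        best_cost = np.inf
        m = min(len(free_g), len(free_h))
        for r in range(m, -1, -1):
            found_at_r = False
            for g_sub in itertools.combinations(free_g, r):
                for h_perm in itertools.permutations(free_h, r):
                    d = [
                        np.linalg.norm(gt_tracks[g][f] - tracks[h][f])
                        for g, h in zip(g_sub, h_perm)
                    ]
                    if all(x <= threshold for x in d):
                        found_at_r = True
                        if sum(d) < best_cost:
                            best_cost = sum(d)
                            best_pairs = dict(zip(g_sub, h_perm))
            if found_at_r:
                break  # maximize the number of matches first
        pairs = dict(kept)
        for g, h in best_pairs.items():
            if g in last and last[g] != h:
                switches += 1
            pairs[g] = h
        misses += len(gts) - len(pairs)
        fps += len(hyps) - len(pairs)
        last.update(pairs)
    return misses, fps, switches
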