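"""Globally optimal tracklet stitching via min-cost network flow.

Tracklets emitted by the local tracker are stitched into k full tracks by
covering a directed acyclic tracklet graph with k node-disjoint source-sink
paths of minimal total cost. Nodes are tracklets (short "residual" tracklets
are excluded and reinserted afterwards); edges connect temporally disjoint
tracklets separated by at most ``max_gap`` frames, weighted by a combination
of affinities:

* motion      — error of constant-velocity extrapolation between the
                tracklets' centroids (forward and backward, averaged), px;
* proximity   — tail-to-head centroid distance (or mean distance over the
                overlap, used only when scoring residual insertion), px;
* shape       — undirected Hausdorff distance between terminal keypoint
                sets, px;
* dynamics    — joint Hankel-matrix rank ratio r_joint / (r1 + r2), small
                when both tracklets obey one low-order linear dynamical
                model;
* appearance  — optional cosine similarity of per-tracklet embedding
                vectors, applied as a multiplicative down-weighting of the
                combined cost.

Each node is split into an input half with unit demand and an output half
with unit supply joined by a weightless edge, so every non-residual tracklet
is visited exactly once; the flow of k units from source to sink is solved
with the capacity-scaling successive-shortest-path algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .tracking import Tracklet

COST_SCALE = 10_000  # flow solvers want integer weights


@dataclass
class Track:
    """A stitched full track: an ordered, non-overlapping tracklet list."""

    id: int
    tracklets: list[Tracklet] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return sorted(f for t in self.tracklets for f in t.frames)

    def occupied(self) -> set[int]:
        return {f for t in self.tracklets for f in t.frames}

    def observation_at(self, frame: int):
        for t in self.tracklets:
            if frame in t.observations:
                return t.observations[frame]
        raise KeyError(frame)


@dataclass
class StitchReport:
    """Diagnostics: which edges were used and their affinity breakdown."""

    edges_used: list[tuple[int, int]]
    affinities: dict[tuple[int, int], dict[str, float]]
    weights: dict[tuple[int, int], float]
    unplaced_residuals: list[int]
    max_gap: int


def split_residuals(
    tracklets: Sequence[Tracklet], min_length: int = 5
) -> tuple[list[Tracklet], list[Tracklet]]:
    """Partition tracklets by length; shorter than ``min_length`` frames are
    residuals and stay out of the stitch graph."""
    graph_t = [t for t in tracklets if len(t) >= min_length]
    residuals = [t for t in tracklets if len(t) < min_length]
    return graph_t, residuals


def compute_max_gap(tracklets: Sequence[Tracklet]) -> int:
    """Automatic temporal search window: ceil(1.5 * tau).

    tau is the smallest gap guaranteeing that every tracklet with a
    temporal successor can reach at least one (the max over tracklets of
    the gap to their nearest following tracklet). A single tracklet yields
    gap 0.
    """
    if len(tracklets) < 2:
        return 0
    tau = 0
    for t1 in tracklets:
        gaps = [t2.start - t1.end for t2 in tracklets if t2.start > t1.end]
        if gaps:
            tau = max(tau, min(gaps))
    return math.ceil(1.5 * tau)


# ---------------------------------------------------------------------------
# Affinity models
# ---------------------------------------------------------------------------


def _terminal_velocity(tracklet: Tracklet, end: str, n_points: int = 3) -> np.ndarray:
    """Average instantaneous centroid velocity over the first/last points."""
    frames = tracklet.frames
    pts = tracklet.centroid_series()
    if len(frames) < 2:
        return np.zeros(2)
    sel = slice(0, n_points) if end == "head" else slice(-n_points, None)
    f = np.asarray(frames[sel], dtype=float)
    p = pts[sel]
    dt = np.diff(f)
    vel = np.diff(p, axis=0) / dt[:, None]
    return vel.mean(axis=0)


def motion_affinity(t1: Tracklet, t2: Tracklet) -> float:
    """Mean of forward and backward rectilinear extrapolation errors (px)."""
    if t1.end >= t2.start:
        raise ValueError("t1 must end before t2 starts")
    gap = t2.start - t1.end
    c1_end = t1.centroid_series()[-1]
    c2_start = t2.centroid_series()[0]
    v_tail = _terminal_velocity(t1, "tail")
    v_head = _terminal_velocity(t2, "head")
    d_f = float(np.linalg.norm(c1_end + v_tail * gap - c2_start))
    d_b = float(np.linalg.norm(c2_start - v_head * gap - c1_end))
    return (d_f + d_b) / 2.0


def spatial_proximity(t1: Tracklet, t2: Tracklet) -> float:
    """Centroid distance: averaged over the temporal overlap if any, else
    between the earlier tracklet's tail and the later one's head."""
    overlap = sorted(set(t1.frames) & set(t2.frames))
    if overlap:
        d = [
            float(
                np.linalg.norm(
                    t1.observations[f].centroid() - t2.observations[f].centroid()
                )
            )
            for f in overlap
        ]
        return float(np.mean(d))
    first, second = (t1, t2) if t1.end < t2.start else (t2, t1)
    tail = first.centroid_series()[-1]
    head = second.centroid_series()[0]
    return float(np.linalg.norm(tail - head))


def shape_similarity(t1: Tracklet, t2: Tracklet) -> float:
    """Undirected Hausdorff distance between t1's tail keypoint set and
    t2's head keypoint set (px); +inf for an empty set."""
    a = t1.keypoints_at(t1.end)
    b = t2.keypoints_at(t2.start)
    if len(a) == 0 or len(b) == 0:
        return float("inf")
    return float(
        max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    )


def hankel_matrix(
    series: np.ndarray,
    depth: int | None = None,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Block Hankel matrix of a (N, 2) centroid series.

    Rows stack ``depth`` delayed copies of the x signal over the same
    number of y rows; columns are time windows. ``depth`` defaults to the
    square-as-possible choice (N + 1) // 2.
    """
    series = np.asarray(series, dtype=float)
    if center is not None:
        # remove a common offset so the effective-rank threshold (relative
        # to the largest singular value) is not swamped by the absolute
        # position of the trajectory
        series = series - np.asarray(center, dtype=float)
    n = len(series)
    if depth is None:
        depth = (n + 1) // 2
    depth = max(2, min(depth, n - 1))
    cols = n - depth + 1
    blocks = []
    for coord in range(2):
        sig = series[:, coord]
        blocks.append(
            np.array([sig[i : i + cols] for i in range(depth)])
        )
    return np.vstack(blocks)


def hankel_rank(matrix: np.ndarray, tol: float = 0.01) -> int:
    """Effective rank: singular values no smaller than ``tol`` times the
    largest (the point past which they drop by less than 1% of the total
    spectrum)."""
    s = np.linalg.svd(matrix, compute_uv=False)
    if s[0] <= 0:
        return 0
    return int(np.sum(s >= tol * s[0]))


def dynamic_similarity(
    t1: Tracklet, t2: Tracklet, min_length: int = 4
) -> float | None:
    """Joint Hankel rank ratio r_joint / (r1 + r2); smaller means the two
    tracklets are consistent with one low-order dynamical model. Returns
    None (affinity unavailable) when either tracklet is too short."""
    if len(t1) < min_length or len(t2) < min_length:
        return None
    s1, s2 = t1.centroid_series(), t2.centroid_series()
    r1 = hankel_rank(hankel_matrix(s1, center=s1.mean(axis=0)))
    r2 = hankel_rank(hankel_matrix(s2, center=s2.mean(axis=0)))
    # joint matrix: delayed measurements of the concatenated trajectory,
    # bridging the temporal gap by linear interpolation — two segments of
    # one low-order dynamical model stay low rank, incompatible dynamics
    # (e.g. a reversal or a jump) raise it
    gap = t2.start - t1.end
    if gap > 1:
        alphas = np.arange(1, gap)[:, None] / gap
        bridge = s1[-1] * (1 - alphas) + s2[0] * alphas
        joint_series = np.vstack([s1, bridge, s2])
    else:
        joint_series = np.vstack([s1, s2])
    joint = hankel_matrix(joint_series, center=joint_series.mean(axis=0))
    r_joint = hankel_rank(joint)
    return float(r_joint) / float(max(r1 + r2, 1))


def tracklet_affinities(
    t1: Tracklet,
    t2: Tracklet,
    dynamics_min_length: int = 4,
) -> dict[str, float]:
    """All available affinity costs for a temporally compatible pair."""
    aff = {
        "motion": motion_affinity(t1, t2),
        "proximity": spatial_proximity(t1, t2),
        "shape": shape_similarity(t1, t2),
    }
    dyn = dynamic_similarity(t1, t2, dynamics_min_length)
    if dyn is not None:
        aff["dynamics"] = dyn
    return aff


def combine_costs(
    edge_affinities: Mapping[tuple[int, int], Mapping[str, float]],
    weights: Mapping[str, float] | None = None,
    appearance: Mapping[tuple[int, int], float] | None = None,
    appearance_strength: float = 0.0,
) -> dict[tuple[int, int], float]:
    """Combine per-edge affinity costs into one weight per edge.

    Each affinity is min-max normalized over the candidate edge set
    (infinite values map to 1, constant affinities to 0), then summed with
    its weight. A supplied appearance cosine similarity rescales the weight
    multiplicatively: w <- w * (1 - s * cos_sim).
    """
    weights = dict(weights or {})
    names = sorted({k for aff in edge_affinities.values() for k in aff})
    norm: dict[tuple[int, int], dict[str, float]] = {
        e: {} for e in edge_affinities
    }
    for name in names:
        vals = [
            aff[name]
            for aff in edge_affinities.values()
            if name in aff and math.isfinite(aff[name])
        ]
        lo = min(vals) if vals else 0.0
        hi = max(vals) if vals else 0.0
        span = hi - lo
        for e, aff in edge_affinities.items():
            if name not in aff:
                continue
            v = aff[name]
            if not math.isfinite(v):
                norm[e][name] = 1.0
            elif span <= 0:
                norm[e][name] = 0.0
            else:
                norm[e][name] = (v - lo) / span
    combined = {}
    for e, comps in norm.items():
        if not comps:
            continue
        w = sum(weights.get(name, 1.0) * val for name, val in comps.items())
        if appearance is not None and e in appearance:
            w *= 1.0 - appearance_strength * appearance[e]
        combined[e] = max(w, 0.0)
    return combined


# ---------------------------------------------------------------------------
# The flow problem
# ---------------------------------------------------------------------------


def build_stitch_graph(
    tracklets: Sequence[Tracklet],
    k: int,
    weights: Mapping[tuple[int, int], float],
    max_gap: int,
) -> nx.DiGraph:
    """Node-split flow network over temporally compatible tracklet pairs.

    Tracklet i becomes nodes ("in", i) with demand 1 and ("out", i) with
    supply 1; the source supplies and the sink demands k units. All
    inter-node edges have unit capacity.
    """
    g = nx.DiGraph()
    g.add_node("source", demand=-k)
    g.add_node("sink", demand=k)
    for i, _ in enumerate(tracklets):
        g.add_node(("in", i), demand=1)
        g.add_node(("out", i), demand=-1)
        g.add_edge("source", ("in", i), capacity=1, weight=0)
        g.add_edge(("out", i), "sink", capacity=1, weight=0)
    for (i, j), w in weights.items():
        gap = tracklets[j].start - tracklets[i].end
        if 0 < gap <= max_gap:
            g.add_edge(
                ("out", i),
                ("in", j),
                capacity=1,
                weight=int(round(w * COST_SCALE)),
            )
    return g


def solve_flow(
    graph: nx.DiGraph, tracklets: Sequence[Tracklet], k: int
) -> list[list[int]]:
    """Minimum-cost cover of all tracklets with k node-disjoint paths.

    Returns k lists of tracklet indices in temporal order. Raises if no
    feasible cover exists, naming the offending frame range.
    """
    try:
        _, flow = nx.capacity_scaling(graph)
    except nx.NetworkXUnfeasible as err:
        frames = [f for t in tracklets for f in (t.start, t.end)]
        lo, hi = (min(frames), max(frames)) if frames else (0, 0)
        raise ValueError(
            f"no feasible {k}-track cover of {len(tracklets)} tracklets "
            f"(frames {lo}-{hi}); too many concurrent tracklets or k too small"
        ) from err
    successor: dict[int, int] = {}
    starts: list[int] = []
    for i in range(len(tracklets)):
        for target, amount in flow.get(("out", i), {}).items():
            if amount > 0 and isinstance(target, tuple):
                successor[i] = target[1]
    for target, amount in flow.get("source", {}).items():
        if amount > 0 and isinstance(target, tuple):
            starts.append(target[1])
    paths = []
    for s in sorted(starts, key=lambda i: tracklets[i].start):
        path = [s]
        while path[-1] in successor:
            path.append(successor[path[-1]])
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Residual reinsertion
# ---------------------------------------------------------------------------


def _merge_tracklets(parts: Sequence[Tracklet], new_id: int) -> Tracklet:
    merged = Tracklet(new_id)
    for t in parts:
        merged.observations.update(t.observations)
    return merged


def _grow_residuals(
    residuals: list[Tracklet], max_gap: int
) -> list[list[Tracklet]]:
    """Forward screening pass: group temporally close residuals along
    weighted longest paths of small association DAGs, growing longer and
    more confident residuals before insertion. Returns groups of residual
    tracklets meant to be inserted together."""
    if len(residuals) < 2:
        return [[r] for r in residuals]
    g = nx.DiGraph()
    g.add_nodes_from(range(len(residuals)))
    for i, a in enumerate(residuals):
        for j, b in enumerate(residuals):
            gap = b.start - a.end
            if 0 < gap <= max(max_gap, 1):
                tail = a.centroid_series()[-1]
                head = b.centroid_series()[0]
                overlap = 1.0 / (1.0 + float(np.linalg.norm(tail - head)))
                g.add_edge(i, j, weight=overlap)
    groups: list[list[Tracklet]] = []
    remaining = set(range(len(residuals)))
    while remaining:
        sub = g.subgraph(remaining)
        if sub.number_of_edges() == 0:
            groups.extend([residuals[i]] for i in sorted(remaining))
            break
        path = nx.dag_longest_path(sub, weight="weight")
        groups.append([residuals[i] for i in path])
        remaining -= set(path)
    return groups


def reinsert_residuals(
    tracks: list[Track], residuals: Sequence[Tracklet], max_gap: int = 5
) -> list[int]:
    """Greedily place residual tracklets into temporal gaps of the tracks.

    Residual groups (grown by the screening pass) are processed longest
    first; a residual may go only where none of its frames is already
    occupied, and among candidate tracks the one minimizing the distance
    to the neighbouring tracklets wins. A grown group that fits nowhere as
    a whole falls back to individual placement of its members. Returns ids
    of unplaceable residuals.
    """

    def _try_place(res: Tracklet) -> bool:
        best_track, best_score = None, float("inf")
        for track in tracks:
            if track.occupied() & set(res.frames):
                continue
            score = 0.0
            before = [t for t in track.tracklets if t.end < res.start]
            after = [t for t in track.tracklets if t.start > res.end]
            if not before and not after:
                continue
            if before:
                prev = max(before, key=lambda t: t.end)
                score += float(
                    np.linalg.norm(
                        prev.centroid_series()[-1] - res.centroid_series()[0]
                    )
                )
            if after:
                nxt = min(after, key=lambda t: t.start)
                score += float(
                    np.linalg.norm(
                        res.centroid_series()[-1] - nxt.centroid_series()[0]
                    )
                )
            if score < best_score:
                best_track, best_score = track, score
        if best_track is None:
            return False
        best_track.tracklets.append(res)
        best_track.tracklets.sort(key=lambda t: t.start)
        return True

    unplaced: list[int] = []
    groups = _grow_residuals(list(residuals), max_gap)
    for group in sorted(groups, key=lambda g: sum(len(t) for t in g), reverse=True):
        if len(group) > 1 and _try_place(_merge_tracklets(group, group[0].id)):
            continue
        for res in group:
            if not _try_place(res):
                unplaced.append(res.id)
    return unplaced


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def stitch_tracklets(
    tracklets: Sequence[Tracklet],
    k: int,
    min_length: int = 5,
    max_gap: int | None = None,
    affinity_weights: Mapping[str, float] | None = None,
    embeddings: Mapping[int, np.ndarray] | None = None,
    appearance_strength: float = 0.0,
    dynamics_min_length: int = 4,
) -> tuple[list[Track], StitchReport]:
    """Full stitching pass: residual split, affinity graph, min-cost flow,
    residual reinsertion."""
    graph_t, residuals = split_residuals(tracklets, min_length)
    if not graph_t:
        # residual-only reconstruction: greedily chain residuals into k tracks
        tracks = [Track(i) for i in range(k)]
        unplaced = []
        for res in sorted(residuals, key=lambda t: (t.start, t.id)):
            placed = False
            for track in tracks:
                if not track.occupied() & set(res.frames):
                    track.tracklets.append(res)
                    track.tracklets.sort(key=lambda t: t.start)
                    placed = True
                    break
            if not placed:
                unplaced.append(res.id)
        return tracks, StitchReport([], {}, {}, unplaced, 0)

    gap = compute_max_gap(graph_t) if max_gap is None else max_gap
    gap_relaxations = 2  # on an infeasible cover, widen the search window
    paths = None
    while True:
        affinities: dict[tuple[int, int], dict[str, float]] = {}
        for i, t1 in enumerate(graph_t):
            for j, t2 in enumerate(graph_t):
                if 0 < t2.start - t1.end <= gap:
                    affinities[(i, j)] = tracklet_affinities(
                        t1, t2, dynamics_min_length
                    )
        appearance = None
        if embeddings is not None:
            from .identity import tracklet_cosine

            appearance = {}
            for (i, j) in affinities:
                ei = embeddings.get(graph_t[i].id)
                ej = embeddings.get(graph_t[j].id)
                if ei is not None and ej is not None:
                    appearance[(i, j)] = tracklet_cosine(ei, ej)
        weights = combine_costs(
            affinities, affinity_weights, appearance, appearance_strength
        )
        flow_graph = build_stitch_graph(graph_t, k, weights, gap)
        try:
            paths = solve_flow(flow_graph, graph_t, k)
            break
        except ValueError:
            # No k node-disjoint cover exists. First widen the temporal
            # search window (the automatic gap can be too tight when an
            # early tracklet has no successor within 1.5 tau); if that is
            # not enough, more than k tracklets overlap in time (e.g. a
            # spuriously split animal): demote the shortest
            # most-overlapping tracklet to a residual and retry; it gets
            # greedily reinserted afterwards.
            if gap_relaxations > 0:
                gap_relaxations -= 1
                gap = max(2 * gap, 1)
                continue
            if len(graph_t) <= k:
                raise
            overlaps = []
            for i, t in enumerate(graph_t):
                frames = set(t.frames)
                n_over = sum(
                    1
                    for j, o in enumerate(graph_t)
                    if j != i and frames & set(o.frames)
                )
                overlaps.append((n_over, -len(t), i))
            _, _, worst = max(overlaps)
            residuals.append(graph_t.pop(worst))
    tracks = [
        Track(tid, [graph_t[i] for i in path]) for tid, path in enumerate(paths)
    ]
    unplaced = reinsert_residuals(tracks, residuals, max_gap=max(gap, 1))
    edges_used = [
        (path[i], path[i + 1]) for path in paths for i in range(len(path) - 1)
    ]
    report = StitchReport(
        edges_used,
        {e: affinities[e] for e in edges_used if e in affinities},
        {e: weights[e] for e in edges_used if e in weights},
        unplaced,
        gap,
    )
    return tracks, report
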