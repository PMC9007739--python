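"""Group per-frame keypoint detections into individual animals.

The frame-level assembly problem (a k-dimensional matching, NP hard in
general) is broken into per-edge bipartite matchings: strong connections are
picked per skeleton edge by optimal assignment over affinity costs, their
connected components seed unambiguous individuals, and the remaining
connections are sorted by decreasing affinity and greedily linked subject to
a no-duplicate-bodypart rule. Optionally, a multivariate-normal pose prior
over all pairwise inter-keypoint distances gates ambiguous growth steps
(Mahalanobis calibration), and in video mode a temporal-coherence kernel
up-weights connections consistent with recent frames.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .decoding import KeypointDetection


@dataclass
class Assembly:
    """One putative animal: bodypart -> detection index, with a score."""

    members: dict[int, int] = field(default_factory=dict)
    connection_costs: list[float] = field(default_factory=list)
    identity: int | str | None = None

    @property
    def score(self) -> float:
        """Mean affinity of internal connections (0 for singletons)."""
        return float(np.mean(self.connection_costs)) if self.connection_costs else 0.0

    def positions(self, detections: Sequence[KeypointDetection]) -> np.ndarray:
        return np.array(
            [detections[i].position for i in self.members.values()]
        ).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PosePrior:
    """Gaussian prior over the vector of all pairwise keypoint distances."""

    n_bodyparts: int
    mean: np.ndarray  # (D,), D = K(K-1)/2
    cov: np.ndarray  # (D, D)
    pair_index: dict[tuple[int, int], int]

    def distance_percentile(self, q: float) -> float:
        sd = np.sqrt(np.diag(self.cov))
        from scipy.stats import norm

        return float(np.max(self.mean + norm.ppf(q / 100.0) * sd))


def pick_optimal_pairs(
    table: np.ndarray, paf_threshold: float = 0.1
) -> list[tuple[int, int, float]]:
    """Per-edge one-to-one matching maximizing total affinity.

    Returns (row, col, cost) triples for the optimal bipartite assignment
    restricted to entries with cost >= ``paf_threshold``.
    """
    if table.size == 0:
        return []
    # forbid below-threshold pairs by masking, keep the LP feasible
    masked = np.where(table >= paf_threshold, table, -1e9)
    rows, cols = linear_sum_assignment(masked, maximize=True)
    return [
        (int(r), int(c), float(table[r, c]))
        for r, c in zip(rows, cols)
        if table[r, c] >= paf_threshold
    ]


def connected_components(pairs: Sequence[tuple[int, int]]) -> list[set[int]]:
    """Maximal groups of detections mutually reachable through pairs (BFS)."""
    adj: dict[int, set[int]] = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[int] = set()
    groups = []
    for start in adj:
        if start in seen:
            continue
        queue, comp = [start], set()
        seen.add(start)
        while queue:
            node = queue.pop()
            comp.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        groups.append(comp)
    return groups


def _pairwise_distance_vector(
    positions: Mapping[int, np.ndarray], pair_index: Mapping[tuple[int, int], int]
) -> tuple[np.ndarray, np.ndarray]:
    """(indices, values) of the observed coordinates of the distance vector."""
    idx, vals = [], []
    parts = sorted(positions)
    for a, b in itertools.combinations(parts, 2):
        key = (a, b) if (a, b) in pair_index else (b, a)
        if key in pair_index:
            idx.append(pair_index[key])
            vals.append(float(np.linalg.norm(positions[a] - positions[b])))
    return np.array(idx, dtype=int), np.array(vals)


def fit_pose_prior(labelled_poses: Sequence[np.ndarray]) -> PosePrior:
    """Fit the Gaussian pose prior from labelled poses.

    Each pose is a (K, 2) array. The prior is the Gaussian matching the
    kernel density estimate of the pairwise-distance vectors with bandwidth
    chosen by Scott's rule: mean = sample mean, covariance = sample
    covariance inflated by (1 + n^(-2/(d+4))). A singular covariance is
    regularized by adding eps * I with eps = 1e-8 * trace / dim.
    """
    poses = [np.asarray(p, dtype=float) for p in labelled_poses]
    if len(poses) < 2:
        raise ValueError("need at least 2 labelled poses")
    k = poses[0].shape[0]
    if k < 2:
        raise ValueError("need at least 2 bodyparts")
    pairs = list(itertools.combinations(range(k), 2))
    pair_index = {pair: i for i, pair in enumerate(pairs)}
    vecs = np.array(
        [
            [np.linalg.norm(p[a] - p[b]) for a, b in pairs]
            for p in poses
        ]
    )
    n, d = vecs.shape
    mean = vecs.mean(axis=0)
    cov = np.cov(vecs, rowvar=False).reshape(d, d)
    scott = n ** (-2.0 / (d + 4))
    cov = cov * (1.0 + scott)
    if np.linalg.matrix_rank(cov) < d or np.trace(cov) == 0:
        eps = 1e-8 * (np.trace(cov) / d if np.trace(cov) > 0 else 1.0)
        cov = cov + eps * np.eye(d)
    return PosePrior(k, mean, cov, pair_index)


def _mahalanobis(
    positions: Mapping[int, np.ndarray], prior: PosePrior
) -> float | None:
    idx, vals = _pairwise_distance_vector(positions, prior.pair_index)
    if len(idx) == 0:
        return None
    mu = prior.mean[idx]
    sub = prior.cov[np.ix_(idx, idx)]
    delta = vals - mu
    try:
        sol = np.linalg.solve(sub, delta)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(sub, delta, rcond=None)[0]
    return float(np.sqrt(max(delta @ sol, 0.0)))


def mahalanobis_gate(
    group_positions: Mapping[int, np.ndarray],
    new_part: int,
    new_position: np.ndarray,
    prior: PosePrior,
) -> bool:
    """Accept a growth step iff it does not increase the Mahalanobis
    distance of the (partial) configuration to the pose prior, restricted to
    the observed distance coordinates. Inapplicable gates (no shared
    coordinates before the step) accept.
    """
    before = _mahalanobis(group_positions, prior)
    extended = dict(group_positions)
    extended[new_part] = np.asarray(new_position, dtype=float)
    after = _mahalanobis(extended, prior)
    if before is None or after is None:
        return True
    return after <= before + 1e-12


def temporal_coherence_weight(
    connection_midpoint: np.ndarray,
    past_connections: Sequence[tuple[int, np.ndarray]],
    gamma: float = 0.01,
) -> float:
    """Average exponential kernel over the closest connections of past frames.

    weight = (1/j) * sum_n exp(-gamma * dt_n * ||c - c_n||^2) over the j
    supplied past frames, where c_n is the closest matching connection of
    the n-th past frame and dt_n its frame gap. Returns 0 with no history.
    """
    if not past_connections:
        return 0.0
    c = np.asarray(connection_midpoint, dtype=float)
    total = 0.0
    for dt, c_n in past_connections:
        d2 = float(np.sum((c - np.asarray(c_n, dtype=float)) ** 2))
        total += np.exp(-gamma * dt * d2)
    return float(total / len(past_connections))


def greedy_link(
    connections: Sequence[tuple[tuple[int, int], int, int, float]],
    groups: list[dict[int, int]],
    group_costs: list[list[float]],
    detections: Sequence[KeypointDetection] | None = None,
    prior: PosePrior | None = None,
) -> None:
    """Greedily apply connections in descending affinity order (in place).

    Each connection ((part_i, part_j), det_i, det_j, cost) may merge two
    groups, extend one group, or create a new one — unless it would give a
    group two detections of one bodypart or re-assign an already grouped
    detection to a second group. With a prior, ambiguous growth steps are
    Mahalanobis-gated.
    """
    owner: dict[int, int] = {}  # detection -> group index
    for gi, grp in enumerate(groups):
        for det in grp.values():
            owner[det] = gi

    for (pi, pj), di, dj, cost in sorted(connections, key=lambda c: -c[3]):
        gi, gj = owner.get(di), owner.get(dj)
        if gi is not None and gj is not None:
            if gi == gj:
                group_costs[gi].append(cost)  # redundant internal connection
                continue
            merged_parts = set(groups[gi]) & set(groups[gj])
            if merged_parts:
                continue  # duplicate bodypart after merge
            groups[gi].update(groups[gj])
            group_costs[gi].extend(group_costs[gj] + [cost])
            for det in groups[gj].values():
                owner[det] = gi
            groups[gj] = {}
            group_costs[gj] = []
        elif gi is not None or gj is not None:
            g = gi if gi is not None else gj
            new_part, new_det = ((pj, dj) if gi is not None else (pi, di))
            if new_part in groups[g]:
                continue
            if prior is not None and detections is not None and len(groups[g]) >= 2:
                pos = {p: detections[d].position for p, d in groups[g].items()}
                if not mahalanobis_gate(
                    pos, new_part, detections[new_det].position, prior
                ):
                    continue
            groups[g][new_part] = new_det
            group_costs[g].append(cost)
            owner[new_det] = g
        else:
            groups.append({pi: di, pj: dj})
            group_costs.append([cost])
            owner[di] = owner[dj] = len(groups) - 1

    # drop emptied groups from merges
    keep = [i for i, g in enumerate(groups) if g]
    groups[:] = [groups[i] for i in keep]
    group_costs[:] = [group_costs[i] for i in keep]


def assemble_frame(
    detections: Sequence[KeypointDetection],
    affinity_tables: Mapping[tuple[int, int], np.ndarray],
    graph: Sequence[tuple[int, int]],
    paf_threshold: float = 0.1,
    prior: PosePrior | None = None,
    identity_probs: np.ndarray | None = None,
    identity_mode: bool = False,
    past_connections: Mapping[tuple[int, int], Sequence[tuple[int, np.ndarray]]]
    | None = None,
    gamma: float = 0.01,
    temporal_mode: str = "multiplicative",
) -> tuple[list[Assembly], list[int]]:
    """Assemble one frame's detections into animals.

    Returns (assemblies, unconnected detection indices). With
    ``identity_mode`` and per-detection identity probabilities, grouping
    bypasses PAFs entirely and groups by argmax identity.
    """
    if not detections:
        return [], []

    if identity_mode:
        if identity_probs is None:
            raise ValueError("identity_mode requires identity_probs")
        by_id: dict[int, Assembly] = {}
        for idx, det in enumerate(detections):
            label = int(np.argmax(identity_probs[idx]))
            asm = by_id.setdefault(label, Assembly(identity=label))
            if det.bodypart in asm.members:
                # keep the more confident detection
                prev = asm.members[det.bodypart]
                if det.confidence > detections[prev].confidence:
                    asm.members[det.bodypart] = idx
            else:
                asm.members[det.bodypart] = idx
        assemblies = [by_id[k] for k in sorted(by_id)]
        used = {i for a in assemblies for i in a.members.values()}
        return assemblies, [i for i in range(len(detections)) if i not in used]

    by_part: dict[int, list[int]] = {}
    for idx, det in enumerate(detections):
        by_part.setdefault(det.bodypart, []).append(idx)

    def _weighted(edge, di, dj, cost):
        if past_connections is None:
            return cost
        hist = past_connections.get(tuple(edge), [])
        mid = (detections[di].position + detections[dj].position) / 2.0
        w = temporal_coherence_weight(mid, hist, gamma)
        return w if temporal_mode == "replace" else cost * (1.0 + w)

    strong: list[tuple[tuple[int, int], int, int, float]] = []
    remaining: list[tuple[tuple[int, int], int, int, float]] = []
    for edge in graph:
        edge = tuple(edge)
        table = affinity_tables.get(edge)
        if table is None or table.size == 0:
            continue
        rows = by_part.get(edge[0], [])
        cols = by_part.get(edge[1], [])
        picked = pick_optimal_pairs(table, paf_threshold)
        picked_set = {(r, c) for r, c, _ in picked}
        for r, c, cost in picked:
            strong.append(
                (edge, rows[r], cols[c], _weighted(edge, rows[r], cols[c], cost))
            )
        for r, c in itertools.product(range(len(rows)), range(len(cols))):
            if (r, c) in picked_set:
                continue
            cost = float(table[r, c])
            if cost >= paf_threshold:
                remaining.append(
                    (edge, rows[r], cols[c], _weighted(edge, rows[r], cols[c], cost))
                )

    # seed groups from strong pairs (descending cost; conflict-free by the
    # same rules, which reduces to plain connected components when the
    # per-edge matchings do not collide across edges)
    groups: list[dict[int, int]] = []
    costs: list[list[float]] = []
    greedy_link(strong, groups, costs, detections, prior=None)
    # weaker connections, gated
    greedy_link(remaining, groups, costs, detections, prior=prior)

    assemblies = [
        Assembly(members=g, connection_costs=c) for g, c in zip(groups, costs)
    ]
    used = {i for a in assemblies for i in a.members.values()}
    unconnected = [i for i in range(len(detections)) if i not in used]
    return assemblies, unconnected
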