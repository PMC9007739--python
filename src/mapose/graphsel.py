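"""Data-driven part-affinity graph (skeleton) selection.

Given labelled frames where every detection's true animal is known, the
affinity cost of each candidate edge is histogrammed separately for
within-animal and between-animal pairs (bin width 0.01). Edges are ranked by
their discriminability — the area under the ROC curve separating the two
distributions — and the smallest skeleton is taken as the maximum spanning
tree over auROC weights. Increasingly redundant candidate graphs extend the
tree with the next most discriminative edges; the graph jointly maximizing
assembly purity and the fraction of connected keypoints is retained.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np

BIN_WIDTH = 0.01


@dataclass
class PartAffinityGraph:
    """An ordered edge list over bodypart indices with per-edge auROC."""

    edges: list[tuple[int, int]]
    discriminability: dict[tuple[int, int], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    def is_connected(self, n_bodyparts: int) -> bool:
        g = nx.Graph(self.edges)
        g.add_nodes_from(range(n_bodyparts))
        return nx.is_connected(g)


@dataclass
class EdgeCostDistributions:
    """Within-/between-animal affinity histograms per edge (bin width 0.01)."""

    bins: np.ndarray  # shared bin edges
    within: dict[tuple[int, int], np.ndarray]
    between: dict[tuple[int, int], np.ndarray]
    flagged: list[tuple[int, int]]  # edges with no same-animal examples


def _bin_edges(lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    n = int(round((hi - lo) / BIN_WIDTH))
    return lo + BIN_WIDTH * np.arange(n + 1)


def edge_cost_distributions(
    labelled_frames: Sequence[tuple[Sequence, dict[tuple[int, int], np.ndarray]]],
    full_graph: Sequence[tuple[int, int]],
) -> EdgeCostDistributions:
    """Accumulate within-/between-animal cost histograms over labelled frames.

    ``labelled_frames`` is a sequence of (detections, affinity_tables)
    pairs where each detection carries a ``gt_animal`` attribute (or the
    detections item is a list of (bodypart, gt_animal) tuples aligned with
    the affinity table ordering). Edges that never see a same-animal pair
    are flagged and excluded from ranking.
    """
    bins = _bin_edges()
    within = {tuple(e): np.zeros(len(bins) - 1) for e in full_graph}
    between = {tuple(e): np.zeros(len(bins) - 1) for e in full_graph}

    for detections, tables in labelled_frames:
        labels = [getattr(d, "gt_animal", d[1] if isinstance(d, tuple) else None) for d in detections]
        parts = [getattr(d, "bodypart", d[0] if isinstance(d, tuple) else None) for d in detections]
        by_part: dict[int, list[int]] = {}
        for idx, part in enumerate(parts):
            by_part.setdefault(part, []).append(idx)
        for edge in full_graph:
            edge = tuple(edge)
            table = tables.get(edge)
            if table is None or table.size == 0:
                continue
            rows = by_part.get(edge[0], [])
            cols = by_part.get(edge[1], [])
            for ri, di in enumerate(rows):
                for cj, dj in enumerate(cols):
                    cost = np.clip(table[ri, cj], -1.0, 1.0 - 1e-12)
                    hist = (
                        within
                        if labels[di] == labels[dj] and labels[di] is not None and labels[di] >= 0
                        else between
                    )
                    bin_idx = int((cost - bins[0]) / BIN_WIDTH)
                    hist[edge][bin_idx] += 1

    flagged = [e for e, h in within.items() if h.sum() == 0]
    return EdgeCostDistributions(bins, within, between, flagged)


def auroc_from_histograms(pos: np.ndarray, neg: np.ndarray) -> float:
    """auROC of 'positive scores exceed negative scores' from shared bins.

    Computed as the Mann-Whitney statistic P(pos > neg) + 0.5 P(tie), with
    ties counted within a bin, which equals the trapezoidal area under the
    binned ROC curve.
    """
    n_pos, n_neg = pos.sum(), neg.sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both histograms must be nonempty")
    neg_below = np.concatenate([[0.0], np.cumsum(neg)[:-1]])
    wins = float(np.sum(pos * neg_below))
    ties = float(np.sum(pos * neg))
    return (wins + 0.5 * ties) / (n_pos * n_neg)


def rank_edges_auroc(
    dists: EdgeCostDistributions,
) -> list[tuple[tuple[int, int], float]]:
    """Edges sorted by decreasing discriminability (stable sort)."""
    scored = []
    for edge in dists.within:
        if edge in dists.flagged or dists.between[edge].sum() == 0:
            continue
        scored.append((edge, auroc_from_histograms(dists.within[edge], dists.between[edge])))
    scored.sort(key=lambda t: -t[1])
    return scored


def maximum_spanning_tree(
    ranked_edges: Sequence[tuple[tuple[int, int], float]],
    n_bodyparts: int,
) -> PartAffinityGraph:
    """Spanning tree over all bodyparts maximizing total auROC weight."""
    g = nx.Graph()
    g.add_nodes_from(range(n_bodyparts))
    for (i, j), w in ranked_edges:
        g.add_edge(i, j, weight=w)
    if not nx.is_connected(g):
        missing = sorted(
            set(range(n_bodyparts)) - set(nx.node_connected_component(g, 0))
        )
        raise ValueError(f"ranked edges do not span all bodyparts; unreachable: {missing}")
    tree = nx.maximum_spanning_tree(g, weight="weight")
    order = {tuple(sorted(e)): k for k, (e, _) in enumerate(ranked_edges)}
    edges = sorted(
        (tuple(sorted(e)) for e in tree.edges),
        key=lambda e: order.get(e, math.inf),
    )
    disc = {e: g.edges[e]["weight"] for e in edges}
    return PartAffinityGraph(list(edges), disc)


def candidate_graphs(
    mst: PartAffinityGraph,
    ranked_edges: Sequence[tuple[tuple[int, int], float]],
    n_candidates: int = 9,
    baseline_skeleton: Sequence[tuple[int, int]] | None = None,
) -> list[PartAffinityGraph]:
    """Increasingly redundant graphs from the MST up to the full edge set.

    graph_0 is the MST; subsequent graphs add the next best-ranked
    non-tree edges in (approximately) equal increments until every ranked
    edge is included, giving at most ``n_candidates`` nested graphs. When a
    ``baseline_skeleton`` is supplied, a parallel family grows it with
    edges added from least to most discriminative (the naive baseline).
    """
    in_tree = set(map(tuple, mst.edges))
    extras = [(tuple(sorted(e)), w) for e, w in ranked_edges if tuple(sorted(e)) not in in_tree]
    disc = dict((tuple(sorted(e)), w) for e, w in ranked_edges)
    disc.update(mst.discriminability)

    sizes = np.unique(
        np.round(np.linspace(len(mst), len(mst) + len(extras), n_candidates)).astype(int)
    )
    graphs = []
    for size in sizes:
        take = size - len(mst)
        edges = list(mst.edges) + [e for e, _ in extras[:take]]
        graphs.append(PartAffinityGraph(edges, {e: disc.get(e, np.nan) for e in edges}))

    if baseline_skeleton is not None:
        base = [tuple(sorted(e)) for e in baseline_skeleton]
        pool = [e for e, _ in reversed(extras) if e not in set(base)]
        for size in sizes:
            take = max(0, size - len(base))
            edges = base + pool[:take]
            graphs.append(
                PartAffinityGraph(edges, {e: disc.get(e, np.nan) for e in edges})
            )
    return graphs


def select_graph(
    candidates: Sequence[PartAffinityGraph],
    evaluate: Callable[[PartAffinityGraph], tuple[float, float]],
) -> PartAffinityGraph:
    """Retain the candidate jointly maximizing purity and connected fraction.

    ``evaluate`` maps a candidate graph to (purity, connected_fraction) on
    held-out labelled frames; the scalarization is their unweighted mean,
    ties broken toward the smaller graph, then candidate order.
    """
    if not candidates:
        raise ValueError("no candidate graphs")
    best, best_key = None, None
    for rank, cand in enumerate(candidates):
        purity, connected = evaluate(cand)
        key = (-(purity + connected) / 2.0, len(cand), rank)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best


def prune_random_subgraph(
    full_graph: Sequence[tuple[int, int]],
    fraction: float,
    n_bodyparts: int,
    seed: int = 0,
) -> PartAffinityGraph:
    """Uniform random edge subset of the stated size, forced connected.

    If the sampled subset leaves bodyparts unreachable, edges of a spanning
    tree of the full graph are swapped in for the lowest-index sampled
    non-bridging edges.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    edges = [tuple(sorted(e)) for e in full_graph]
    n_keep = max(n_bodyparts - 1, int(round(fraction * len(edges))))
    rng = np.random.default_rng(seed)
    chosen = [edges[i] for i in rng.choice(len(edges), size=n_keep, replace=False)]

    g_full = nx.Graph(edges)
    tree_edges = [tuple(sorted(e)) for e in nx.minimum_spanning_tree(g_full).edges]
    g = nx.Graph(chosen)
    g.add_nodes_from(range(n_bodyparts))
    for te in tree_edges:
        if nx.is_connected(g):
            break
        if te in set(map(tuple, g.edges)) or te in chosen:
            continue
        # swap: drop a sampled edge that is not a bridge, add the tree edge
        for ce in list(chosen):
            g2 = g.copy()
            g2.remove_edge(*ce)
            g2.add_edge(*te)
            if nx.number_connected_components(g2) <= nx.number_connected_components(g):
                chosen.remove(ce)
                chosen.append(te)
                g = g2
                break
    if not nx.is_connected(g):
        raise ValueError("could not produce a connected subgraph")
    return PartAffinityGraph(sorted(chosen))


def complete_graph(n_bodyparts: int) -> list[tuple[int, int]]:
    """All bodypart pairs, e.g. 66 edges for 12 bodyparts."""
    return list(itertools.combinations(range(n_bodyparts), 2))
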