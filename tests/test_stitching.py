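"""Tracklet affinities, min-cost-flow stitching and residual handling."""

import numpy as np
import pytest
from conftest import brute_force_path_cover, linear_tracklet, make_tracklet, random_stitch_instance

from mapose.stitching import (
    COST_SCALE,
    Track,
    build_stitch_graph,
    combine_costs,
    compute_max_gap,
    dynamic_similarity,
    hankel_matrix,
    hankel_rank,
    motion_affinity,
    reinsert_residuals,
    shape_similarity,
    solve_flow,
    spatial_proximity,
    split_residuals,
    stitch_tracklets,
)
from mapose.tracking import Tracklet, TrackletObservation


class TestSplitResiduals:
    def test_threshold_boundary_five_is_kept(self):
        ts = [linear_tracklet(i, 0, n, (0, 0), (1, 0)) for i, n in enumerate([3, 5, 7])]
        graph_t, residuals = split_residuals(ts, 5)
        assert [len(t) for t in graph_t] == [5, 7]
        assert [len(t) for t in residuals] == [3]

    def test_min_length_one_leaves_no_residuals(self):
        ts = [linear_tracklet(0, 0, 2, (0, 0), (1, 0))]
        assert split_residuals(ts, 1)[1] == []


class TestComputeMaxGap:
    def test_stated_rule_on_gaps_two_and_four(self):
        t1 = linear_tracklet(0, 0, 5, (0, 0), (1, 0))  # ends 4
        t2 = linear_tracklet(1, 6, 5, (10, 0), (1, 0))  # gap 2, ends 10
        t3 = linear_tracklet(2, 14, 5, (20, 0), (1, 0))  # gap 4
        assert compute_max_gap([t1, t2, t3]) == 6  # ceil(1.5 * 4)

    def test_contiguous_tracklets(self):
        t1 = linear_tracklet(0, 0, 5, (0, 0), (1, 0))
        t2 = linear_tracklet(1, 5, 5, (5, 0), (1, 0))  # gap 1
        assert compute_max_gap([t1, t2]) == 2  # ceil(1.5)

    def test_single_tracklet_gives_zero(self):
        assert compute_max_gap([linear_tracklet(0, 0, 5, (0, 0), (1, 0))]) == 0


class TestMotionAffinity:
    def test_shared_rectilinear_trajectory_scores_zero(self):
        t1 = linear_tracklet(0, 0, 6, (0, 0), (2, 1))
        t2 = linear_tracklet(1, 10, 6, (20, 10), (2, 1))
        assert motion_affinity(t1, t2) == pytest.approx(0.0, abs=1e-9)

    def test_consistent_displacement_gives_its_magnitude(self):
        t1 = linear_tracklet(0, 0, 6, (0, 0), (2, 1))
        # displaced by (3, 4) from the extrapolated continuation
        t2 = linear_tracklet(1, 10, 6, (23, 14), (2, 1))
        assert motion_affinity(t1, t2) == pytest.approx(5.0)

    def test_stationary_tracklets_score_their_distance(self):
        t1 = linear_tracklet(0, 0, 5, (0, 0), (0, 0))
        t2 = linear_tracklet(1, 8, 5, (6, 8), (0, 0))
        assert motion_affinity(t1, t2) == pytest.approx(10.0)


class TestSpatialProximity:
    def test_identical_overlapping_tracklets_score_zero(self):
        t = linear_tracklet(0, 0, 6, (5, 5), (1, 1))
        assert spatial_proximity(t, t) == 0.0

    def test_disjoint_tail_to_head_distance(self):
        t1 = linear_tracklet(0, 0, 4, (0, 0), (0, 0))
        t2 = linear_tracklet(1, 10, 4, (6, 8), (0, 0))
        assert spatial_proximity(t1, t2) == pytest.approx(10.0)

    def test_overlapping_constant_offset(self):
        t1 = make_tracklet(0, range(5), [(i, 0) for i in range(5)])
        t2 = make_tracklet(1, range(5), [(i, 2) for i in range(5)])
        assert spatial_proximity(t1, t2) == pytest.approx(2.0)


class TestShapeSimilarity:
    def test_identical_terminal_point_sets_score_zero(self):
        t = linear_tracklet(0, 0, 4, (5, 5), (0, 0))  # stationary
        assert shape_similarity(t, t) == 0.0

    def test_single_points(self):
        t1 = make_tracklet(0, [0], [(0, 0)], spread=0.0)
        t2 = make_tracklet(1, [5], [(3, 4)], spread=0.0)
        assert shape_similarity(t1, t2) == pytest.approx(5.0)

    def test_undirectedness_forces_the_max(self):
        t1 = Tracklet(0)
        t1.observations[0] = TrackletObservation(
            {0: np.array([0.0, 0.0]), 1: np.array([10.0, 0.0])}, {0: 1.0, 1: 1.0}, 1.0
        )
        t2 = Tracklet(1)
        t2.observations[5] = TrackletObservation(
            {0: np.array([0.0, 0.0])}, {0: 1.0}, 1.0
        )
        assert shape_similarity(t1, t2) == pytest.approx(10.0)


class TestDynamics:
    def test_rectilinear_hankel_rank_is_exactly_two(self):
        series = np.array([[2.0 * t + 1, 3.0 * t - 2] for t in range(10)])
        assert hankel_rank(hankel_matrix(series)) == 2

    def test_segments_of_one_trajectory_give_ratio_half(self):
        t1 = linear_tracklet(0, 0, 8, (0, 0), (2, 1))
        t2 = linear_tracklet(1, 12, 8, (24, 12), (2, 1))
        assert dynamic_similarity(t1, t2) == pytest.approx(0.5)

    def test_time_reversed_displaced_trajectory_raises_ratio(self):
        t1 = linear_tracklet(0, 0, 8, (0, 0), (2, 1))
        t2 = linear_tracklet(1, 12, 8, (90, 40), (-2, -1))
        assert dynamic_similarity(t1, t2) > 0.5

    def test_short_tracklets_marked_unavailable(self):
        t1 = linear_tracklet(0, 0, 3, (0, 0), (1, 0))
        t2 = linear_tracklet(1, 5, 8, (10, 0), (1, 0))
        assert dynamic_similarity(t1, t2) is None


class TestCombineCosts:
    def test_single_affinity_equals_normalized_value(self):
        aff = {(0, 1): {"motion": 2.0}, (0, 2): {"motion": 6.0}}
        w = combine_costs(aff, {"motion": 1.0})
        assert w[(0, 1)] == pytest.approx(0.0)
        assert w[(0, 2)] == pytest.approx(1.0)

    def test_perfect_appearance_similarity_zeroes_the_cost(self):
        aff = {(0, 1): {"motion": 2.0}, (0, 2): {"motion": 6.0}}
        w = combine_costs(
            aff, {"motion": 1.0}, appearance={(0, 2): 1.0}, appearance_strength=1.0
        )
        assert w[(0, 2)] == pytest.approx(0.0)

    def test_identical_affinities_give_identical_weights(self):
        aff = {(0, 1): {"motion": 3.0, "shape": 1.0}, (2, 3): {"motion": 3.0, "shape": 1.0}}
        w = combine_costs(aff)
        assert w[(0, 1)] == w[(2, 3)]

    def test_infinite_shape_maps_to_worst_normalized_cost(self):
        aff = {(0, 1): {"shape": float("inf")}, (0, 2): {"shape": 1.0}, (1, 2): {"shape": 3.0}}
        w = combine_costs(aff)
        assert w[(0, 1)] == pytest.approx(1.0)


class TestSolveFlow:
    def test_forced_single_chain(self):
        ts = [linear_tracklet(i, 6 * i, 5, (6.0 * i, 0), (1, 0)) for i in range(3)]
        weights = {(0, 1): 0.3, (1, 2): 0.2}
        g = build_stitch_graph(ts, 1, weights, max_gap=3)
        assert solve_flow(g, ts, 1) == [[0, 1, 2]]

    def test_two_parallel_chains(self):
        a1 = linear_tracklet(0, 0, 5, (0, 0), (1, 0))
        a2 = linear_tracklet(1, 6, 5, (6, 0), (1, 0))
        b1 = linear_tracklet(2, 0, 5, (0, 50), (1, 0))
        b2 = linear_tracklet(3, 6, 5, (6, 50), (1, 0))
        ts = [a1, a2, b1, b2]
        weights = {(0, 1): 0.1, (2, 3): 0.1, (0, 3): 0.9, (2, 1): 0.9}
        g = build_stitch_graph(ts, 2, weights, max_gap=3)
        paths = solve_flow(g, ts, 2)
        assert sorted(paths) == [[0, 1], [2, 3]]

    def test_infeasible_names_frame_range(self):
        # two overlapping tracklets cannot be covered by one path
        t1 = linear_tracklet(0, 0, 5, (0, 0), (1, 0))
        t2 = linear_tracklet(1, 2, 5, (30, 0), (1, 0))
        g = build_stitch_graph([t1, t2], 1, {}, max_gap=3)
        with pytest.raises(ValueError, match="frames 0-6"):
            solve_flow(g, [t1, t2], 1)

    @pytest.mark.parametrize("seed", range(25))
    def test_optimal_cost_matches_brute_force_cover(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 4))
        tracklets, spans, weights, max_gap = random_stitch_instance(rng, k)
        g = build_stitch_graph(tracklets, k, weights, max_gap)
        try:
            paths = solve_flow(g, tracklets, k)
        except ValueError:
            assert brute_force_path_cover(
                spans, {e: int(round(w * COST_SCALE)) for e, w in weights.items()}, k, max_gap
            ) is None
            return
        got = sum(
            int(round(weights[(p[i], p[i + 1])] * COST_SCALE))
            for p in paths
            for i in range(len(p) - 1)
        )
        want = brute_force_path_cover(
            spans, {e: int(round(w * COST_SCALE)) for e, w in weights.items()}, k, max_gap
        )
        assert want is not None
        assert got == want


class TestReinsertResiduals:
    def test_bridging_residual_inserted(self):
        t1 = linear_tracklet(0, 0, 5, (0, 0), (1, 0))
        t2 = linear_tracklet(1, 8, 5, (8, 0), (1, 0))
        res = linear_tracklet(5, 5, 3, (5, 0), (1, 0))
        track = Track(0, [t1, t2])
        unplaced = reinsert_residuals([track], [res], max_gap=5)
        assert unplaced == []
        assert set(track.frames) == set(range(13))

    def test_residual_conflicting_everywhere_left_unplaced(self):
        t1 = linear_tracklet(0, 0, 10, (0, 0), (1, 0))
        res = linear_tracklet(9, 4, 3, (100, 100), (0, 0))
        track = Track(0, [t1])
        unplaced = reinsert_residuals([track], [res], max_gap=5)
        assert unplaced == [9]

    def test_closest_track_wins_among_candidates(self):
        a1 = linear_tracklet(0, 0, 5, (0, 0), (1, 0))
        a2 = linear_tracklet(1, 10, 5, (10, 0), (1, 0))
        b1 = linear_tracklet(2, 0, 5, (0, 50), (1, 0))
        b2 = linear_tracklet(3, 10, 5, (10, 50), (1, 0))
        res = linear_tracklet(7, 6, 3, (6, 1), (1, 0))  # near track a
        ta, tb = Track(0, [a1, a2]), Track(1, [b1, b2])
        unplaced = reinsert_residuals([ta, tb], [res], max_gap=5)
        assert unplaced == []
        assert 7 in {t.id for t in ta.tracklets}


class TestStitchTracklets:
    def test_outputs_are_temporally_consistent(self):
        rng = np.random.default_rng(12)
        ts = []
        tid = 0
        for lane in range(2):
            t = 0
            while t < 40:
                length = int(rng.integers(5, 9))
                ts.append(
                    linear_tracklet(tid, t, length, (t * 2.0, 40.0 * lane), (2, 0))
                )
                tid += 1
                t += length + int(rng.integers(1, 3))
        tracks, report = stitch_tracklets(ts, 2, min_length=5)
        assert len(tracks) == 2
        for tr in tracks:
            frames = tr.frames
            assert len(frames) == len(set(frames))
            assert frames == sorted(frames)

    def test_residual_only_input_builds_tracks_greedily(self):
        ts = [linear_tracklet(i, 3 * i, 2, (i * 3.0, 0), (1, 0)) for i in range(4)]
        tracks, report = stitch_tracklets(ts, 1, min_length=5)
        assert len(tracks) == 1
        assert report.edges_used == []
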