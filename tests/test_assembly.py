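"""Frame assembly: pairing, components, greedy linking, prior gating."""

import numpy as np
import pytest
from conftest import brute_force_assignment

from mapose.assembly import (
    Assembly,
    assemble_frame,
    connected_components,
    fit_pose_prior,
    greedy_link,
    mahalanobis_gate,
    pick_optimal_pairs,
    temporal_coherence_weight,
)
from mapose.decoding import KeypointDetection, build_affinity_tables, decode_frame
from mapose.synthdata import SceneConfig, generate_scene, render_targets


class TestPickOptimalPairs:
    def test_dominant_diagonal(self):
        table = np.array([[0.9, 0.1], [0.2, 0.8]])
        pairs = pick_optimal_pairs(table, 0.05)
        assert {(r, c) for r, c, _ in pairs} == {(0, 0), (1, 1)}

    def test_all_below_threshold_yields_no_pairs(self):
        assert pick_optimal_pairs(np.full((3, 3), 0.05), 0.1) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matching_total_equals_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.random((5, 5))
        pairs = pick_optimal_pairs(table, paf_threshold=0.0)
        got = sum(c for _, _, c in pairs)
        assert got == pytest.approx(brute_force_assignment(table))


class TestConnectedComponents:
    def test_chain_forms_one_group(self):
        assert connected_components([(1, 2), (2, 3)]) == [{1, 2, 3}]

    def test_disjoint_pairs_form_two_groups(self):
        groups = connected_components([(1, 2), (3, 4)])
        assert sorted(map(sorted, groups)) == [[1, 2], [3, 4]]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [tuple(rng.integers(0, 12, 2)) for _ in range(15)]
        pairs = [(a, b) for a, b in pairs if a != b]
        got = sorted(map(sorted, connected_components(pairs)))
        # union-find oracle
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in pairs:
            parent[find(a)] = find(b)
        comps = {}
        for node in parent:
            comps.setdefault(find(node), set()).add(node)
        want = sorted(map(sorted, comps.values()))
        assert got == want


class TestGreedyLink:
    def test_singletons_merge_on_valid_connection(self):
        groups = [{0: 10}, {1: 11}]
        costs = [[], []]
        greedy_link([((0, 1), 10, 11, 0.9)], groups, costs)
        assert groups == [{0: 10, 1: 11}]

    def test_duplicate_bodypart_connection_skipped(self):
        groups = [{0: 10, 1: 11}]
        costs = [[0.9]]
        greedy_link([((0, 1), 10, 12, 0.8)], groups, costs)
        assert groups == [{0: 10, 1: 11}]  # 12 would duplicate bodypart 1

    def test_merge_blocked_by_shared_bodypart(self):
        groups = [{0: 10, 1: 11}, {1: 12, 2: 13}]
        costs = [[0.9], [0.8]]
        greedy_link([((0, 2), 10, 13, 0.7)], groups, costs)
        assert len([g for g in groups if g]) == 2


class TestPosePrior:
    def test_identical_poses_give_zero_variance_mean(self):
        pose = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 0.0]])
        prior = fit_pose_prior([pose] * 5)
        expected = [5.0, 6.0, 5.0]  # pairwise distances 01, 02, 12
        np.testing.assert_allclose(prior.mean, expected)
        assert np.all(np.diag(prior.cov) >= 0)

    def test_two_bodyparts_give_single_distance_coordinate(self):
        poses = [np.array([[0.0, 0.0], [d, 0.0]]) for d in (3.0, 4.0, 5.0)]
        prior = fit_pose_prior(poses)
        assert prior.mean.shape == (1,)

    def test_parameter_recovery_from_gaussian_distances(self):
        rng = np.random.default_rng(8)
        true_mean = np.array([10.0, 14.0, 10.0])
        n = 500
        poses = []
        for _ in range(n):
            d01 = rng.normal(true_mean[0], 1.0)
            poses.append(
                np.array([[0.0, 0.0], [d01, 0.0], [d01 / 2, rng.normal(9.0, 1.0)]])
            )
        prior = fit_pose_prior(poses)
        se = np.sqrt(np.diag(prior.cov) / n)
        assert abs(prior.mean[0] - true_mean[0]) < 3 * se[0] + 0.2


class TestMahalanobisGate:
    def _prior(self):
        rng = np.random.default_rng(1)
        poses = [
            np.array([[0, 0], [10, 0], [10, 10]]) + rng.normal(0, 0.5, (3, 2))
            for _ in range(100)
        ]
        return fit_pose_prior(poses)

    def test_connection_at_prior_mean_accepted(self):
        prior = self._prior()
        m01, m02, m12 = prior.mean
        # place the new keypoint exactly at the prior's mean distances
        group = {0: np.array([0.0, 0.0]), 1: np.array([m01, 0.0])}
        x = (m01**2 + m02**2 - m12**2) / (2 * m01)
        y = np.sqrt(m02**2 - x**2)
        assert mahalanobis_gate(group, 2, np.array([x, y]), prior)

    def test_connection_far_from_prior_rejected(self):
        prior = self._prior()
        group = {0: np.array([0.0, 0.0]), 1: np.array([10.0, 0.0])}
        assert not mahalanobis_gate(group, 2, np.array([100.0, 100.0]), prior)

    def test_gate_inapplicable_without_shared_coordinates(self):
        prior = self._prior()
        assert mahalanobis_gate({}, 0, np.array([5.0, 5.0]), prior)


class TestTemporalCoherence:
    def test_zero_distance_history_gives_weight_one(self):
        w = temporal_coherence_weight(np.zeros(2), [(1, np.zeros(2))] * 3)
        assert w == pytest.approx(1.0)

    def test_distant_history_gives_vanishing_weight(self):
        w = temporal_coherence_weight(
            np.zeros(2), [(1, np.array([1e4, 1e4]))], gamma=0.01
        )
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_stated_formula_direct_evaluation(self):
        # j=2, gamma=0.01, dt=1, distances 0 and 10
        w = temporal_coherence_weight(
            np.zeros(2),
            [(1, np.zeros(2)), (1, np.array([10.0, 0.0]))],
            gamma=0.01,
        )
        assert w == pytest.approx((1.0 + np.exp(-1.0)) / 2.0)

    def test_no_history_gives_zero(self):
        assert temporal_coherence_weight(np.zeros(2), []) == 0.0


def _frame_from_scene(cfg, frame=0):
    scene = generate_scene(cfg)
    targets = render_targets(scene.coords[frame], cfg, scene.visible[frame])
    dets = decode_frame(targets)
    tables = build_affinity_tables(dets, targets.pafs, cfg.skeleton, cfg.stride)
    labels = []
    for d in dets:
        dists = np.linalg.norm(scene.coords[frame][:, d.bodypart] - d.position, axis=1)
        labels.append(int(np.argmin(dists)))
    return dets, tables, labels


class TestAssembleFrame:
    def test_single_clean_animal_forms_one_full_assembly(self):
        cfg = SceneConfig(
            n_animals=1, n_bodyparts=4, n_frames=1, image_size=(128, 128),
            body_scale=14, jitter_sd=0, dropout=0, clutter_rate=0,
            occlusion_rate=0, seed=21,
        )
        dets, tables, _ = _frame_from_scene(cfg)
        assemblies, unconnected = assemble_frame(dets, tables, cfg.skeleton)
        assert len(assemblies) == 1
        assert len(assemblies[0]) == 4
        assert unconnected == []

    def test_two_separated_animals_form_pure_assemblies(self):
        cfg = SceneConfig(
            n_animals=2, n_bodyparts=4, n_frames=1, image_size=(256, 256),
            body_scale=14, jitter_sd=0, dropout=0, clutter_rate=0,
            occlusion_rate=0, seed=22,
        )
        dets, tables, labels = _frame_from_scene(cfg)
        assemblies, _ = assemble_frame(dets, tables, cfg.skeleton)
        assert len(assemblies) == 2
        for asm in assemblies:
            member_labels = {labels[i] for i in asm.members.values()}
            assert len(member_labels) == 1  # purity 1.0

    def test_identity_mode_follows_argmax_probabilities(self):
        dets = [
            KeypointDetection(k, 10.0 * k, 5.0 * a, 1.0, (0, 0))
            for a in range(2)
            for k in range(3)
        ]
        probs = np.zeros((6, 2))
        for i in range(3):
            probs[i, 0] = 1.0
        for i in range(3, 6):
            probs[i, 1] = 1.0
        assemblies, unconnected = assemble_frame(
            dets, {}, [(0, 1), (1, 2)], identity_probs=probs, identity_mode=True
        )
        assert len(assemblies) == 2
        assert sorted(assemblies[0].members.values()) == [0, 1, 2]
        assert sorted(assemblies[1].members.values()) == [3, 4, 5]
        assert unconnected == []

    def test_empty_frame_gives_empty_output(self):
        assert assemble_frame([], {}, [(0, 1)]) == ([], [])

    def test_no_detection_in_two_assemblies(self):
        cfg = SceneConfig(
            n_animals=3, n_bodyparts=5, n_frames=1, image_size=(256, 256),
            body_scale=16, jitter_sd=1.0, dropout=0.0, clutter_rate=0,
            occlusion_rate=0, seed=23,
        )
        dets, tables, _ = _frame_from_scene(cfg)
        assemblies, _ = assemble_frame(dets, tables, cfg.skeleton)
        seen = set()
        for asm in assemblies:
            for part, det in asm.members.items():
                assert det not in seen
                seen.add(det)
            assert len(set(asm.members)) == len(asm.members)
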