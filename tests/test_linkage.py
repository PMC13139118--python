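"""Linkage algorithms: closed forms, hand-traced examples, exhaustive
oracles, merge/split behaviour, termination statuses."""

import numpy as np
import pytest

from neutrack.linkage import (ENDED_LAST_FRAME, ENDED_NO_AVAILABLE_CELL,
                              ENDED_ZERO_SCORES, TRUNCATED_DISAPPEARED,
                              LinkageParams, discount_threshold, link,
                              link_greedy_delta, link_hungarian,
                              link_viterbi_basic, link_viterbi_extended)
from neutrack.scoring import matrices_from_arrays
from neutrack.simulate import scenario_score_matrices


def enumerate_best_path(arrays, seed_col, floor=0.0):
    """Independent exhaustive-path oracle.

    Among all maximal paths from the frame-0 seed (steps must score above
    0 and ``floor``), returns (nodes, product) preferring the longest
    path, then the highest product.
    """
    n_frames = len(arrays) + 1
    best = ([(0, seed_col)], 1.0)

    def extend(nodes, prod):
        nonlocal best
        t, lab = nodes[-1]
        moved = False
        if t < n_frames - 1:
            a = arrays[t]
            for j in range(a.shape[1]):
                s = a[lab - 1, j]
                if s > 0.0 and s >= floor:
                    moved = True
                    extend(nodes + [(t + 1, j + 1)], prod * s)
        if not moved and (len(nodes), prod) > (len(best[0]), best[1]):
            best = (nodes, prod)

    extend(best[0], 1.0)
    return best


def random_chain(rng, max_frames=5, max_cells=4, sparsity=0.2):
    n_frames = int(rng.integers(2, max_frames + 1))
    sizes = [int(rng.integers(1, max_cells + 1)) for _ in range(n_frames)]
    arrays = []
    for t in range(n_frames - 1):
        a = rng.uniform(size=(sizes[t], sizes[t + 1]))
        a[rng.uniform(size=a.shape) < sparsity] = 0.0
        arrays.append(a)
    return arrays


class TestDiscountThreshold:
    def test_closed_form_small_values(self):
        assert discount_threshold(0.875, 1) == 1.0
        assert discount_threshold(0.875, 2) == 0.875
        assert discount_threshold(0.875, 3) == pytest.approx(0.765625,
                                                             abs=1e-15)

    def test_strictly_decreasing(self):
        vals = [discount_threshold(0.875, n) for n in range(1, 50)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_frame_number_below_one_rejected(self):
        with pytest.raises(ValueError):
            discount_threshold(0.875, 0)


class TestGreedy:
    def test_identity_matrices_full_tracks(self):
        mats = matrices_from_arrays([np.eye(3)] * 4)
        res = link_greedy_delta(mats)
        assert len(res.trajectories) == 3
        for tr in res.trajectories:
            assert len(tr) == 5
            assert tr.status == ENDED_LAST_FRAME

    def test_zero_row_ends_track(self):
        mats = matrices_from_arrays([np.eye(2),
                                     np.array([[0.0, 0.0], [0.0, 1.0]])])
        res = link_greedy_delta(mats)
        tr1 = next(t for t in res.trajectories if t.nodes[0] == (0, 1))
        assert tr1.nodes == [(0, 1), (1, 1)]
        assert tr1.status == ENDED_ZERO_SCORES

    def test_contended_best_goes_to_first_row(self):
        """Both rows prefer column 1; the first row takes it, the second
        ends and the orphaned cell seeds a new trajectory."""
        a = np.array([[0.9, 0.1], [0.9, 0.2]])
        mats = matrices_from_arrays([a, np.eye(2)])
        res = link_greedy_delta(mats)
        tr1 = next(t for t in res.trajectories if t.nodes[0] == (0, 1))
        tr2 = next(t for t in res.trajectories if t.nodes[0] == (0, 2))
        assert tr1.nodes[1] == (1, 1)
        assert tr2.status == ENDED_NO_AVAILABLE_CELL
        assert any(t.nodes[0] == (1, 2) for t in res.trajectories)


class TestHungarian:
    def test_identity_matrices_full_tracks(self):
        mats = matrices_from_arrays([np.eye(3)] * 3)
        res = link_hungarian(mats)
        full = [t for t in res.trajectories if len(t) == 4]
        assert len(full) == 3

    def test_swap_instance_beats_greedy(self):
        """On [[0.6, 0.5], [0.5, 0.1]] the optimal assignment is the swap
        (total 1.0), whereas greedy locks 1->1 and strands the second row
        (total 0.7)."""
        a = np.array([[0.6, 0.5], [0.5, 0.1]])
        mats = matrices_from_arrays([a])
        hung = link_hungarian(mats)
        swaps = {tuple(t.nodes) for t in hung.trajectories}
        assert ((0, 1), (1, 2)) in swaps and ((0, 2), (1, 1)) in swaps
        hung_total = sum(s for t in hung.trajectories for s in t.step_scores)
        greedy = link_greedy_delta(mats)
        greedy_total = sum(s for t in greedy.trajectories
                           for s in t.step_scores)
        assert hung_total == pytest.approx(1.0)
        assert hung_total > greedy_total

    def test_all_below_end_threshold_ends_tracks(self):
        a = np.full((2, 2), 0.1)
        mats = matrices_from_arrays([a, np.eye(2)])
        res = link_hungarian(mats, LinkageParams(end_threshold=0.5))
        enders = [t for t in res.trajectories if t.nodes[0][0] == 0]
        assert all(t.status == TRUNCATED_DISAPPEARED and len(t) == 1
                   for t in enders)


class TestBasicViterbi:
    def test_single_cell_perfect_scores(self):
        mats = matrices_from_arrays([np.array([[1.0]])] * 5)
        res = link_viterbi_basic(mats)
        (tr,) = res.trajectories
        assert tr.accumulated_score == 1.0
        assert len(tr) == 6

    def test_global_beats_greedy_first_hop(self):
        """Greedy's best first hop (0.9 then 0.1) loses to the globally
        optimal 0.8 * 0.9 path."""
        a0 = np.array([[0.9, 0.8]])
        a1 = np.array([[0.1, 0.0], [0.0, 0.9]])
        res = link_viterbi_basic(matrices_from_arrays([a0, a1]))
        tr = res.trajectories[0]
        assert tr.nodes == [(0, 1), (1, 2), (2, 2)]
        assert tr.accumulated_score == pytest.approx(0.72)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(50):
            arrays = random_chain(rng)
            res = link_viterbi_basic(matrices_from_arrays(arrays),
                                     truncate=False)
            for seed in range(1, arrays[0].shape[0] + 1):
                nodes, prod = enumerate_best_path(arrays, seed)
                tr = next(t for t in res.trajectories
                          if t.nodes[0] == (0, seed))
                assert tr.nodes == nodes
                assert tr.accumulated_score == pytest.approx(prod,
                                                             abs=1e-12)

    def test_accumulation_is_monotone_nonincreasing(self, rng):
        arrays = random_chain(rng, max_frames=5)
        res = link_viterbi_basic(matrices_from_arrays(arrays))
        for tr in res.trajectories:
            accs = [tr.acc_upto(k) for k in range(1, len(tr) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(accs, accs[1:]))


class TestExtendedViterbi:
    def test_clean_matrices_match_basic(self):
        mats = scenario_score_matrices("clean_separated")
        basic = link_viterbi_basic(mats, truncate=False)
        ext = link_viterbi_extended(mats)
        assert ({tuple(t.nodes) for t in basic.trajectories}
                == {tuple(t.nodes) for t in ext.trajectories})
        occ = ext.occupancy()
        assert all(len(ids) == 1 for ids in occ.values())

    def test_merge_split_fixture_preserves_both_identities(self,
                                                           merge_fixture):
        """Both trajectories traverse the shared detection and exit on
        their ground-truth sides."""
        mats = scenario_score_matrices("two_cells_cross_merge_split",
                                       merge_fixture)
        res = link_viterbi_extended(mats)
        assert len(res.trajectories) == 2
        expected = {
            tr.track_id: list(zip(tr.frames, tr.labels))
            for tr in merge_fixture.gt_tracks
        }
        got = {tuple(t.nodes) for t in res.trajectories}
        assert got == {tuple(v) for v in expected.values()}
        occ = res.occupancy()
        shared = [n for n, ids in occ.items() if len(ids) == 2]
        assert sorted(shared) == [(3, 1), (4, 1)]

    def test_merge_fixture_defeats_greedy_and_basic(self, merge_fixture):
        """The baselines lose one identity on the fixture: greedy strands
        the second track before the merge; basic Viterbi collapses both
        tracks onto the same exit."""
        mats = scenario_score_matrices("two_cells_cross_merge_split",
                                       merge_fixture)
        gt_nodes = {tuple(zip(tr.frames, tr.labels))
                    for tr in merge_fixture.gt_tracks}
        greedy = link_greedy_delta(mats)
        assert {tuple(t.nodes) for t in greedy.trajectories} != gt_nodes
        tr2 = next(t for t in greedy.trajectories if t.nodes[0] == (0, 2))
        assert tr2.status == ENDED_NO_AVAILABLE_CELL
        assert tr2.nodes[-1][0] < 3  # never reaches the shared detection
        basic = link_viterbi_basic(mats, truncate=False)
        seeds = [t for t in basic.trajectories if t.nodes[0][0] == 0]
        exits = {t.nodes[5] for t in seeds if len(t) > 5}
        assert len(exits) == 1  # both collapse onto one exit side

    def test_merge_conditions_logged_for_shared_nodes(self, merge_fixture):
        mats = scenario_score_matrices("two_cells_cross_merge_split",
                                       merge_fixture)
        res = link_viterbi_extended(mats)
        shared = {n for n, ids in res.occupancy().items() if len(ids) >= 2}
        logged = {rec["node"] for rec in res.merge_log}
        assert shared <= logged
        assert all(rec["condition"] in ("cond1", "cond2")
                   for rec in res.merge_log)

    def test_sub_threshold_scores_truncate_as_disappeared(self):
        arrays = [np.array([[0.9]]), np.array([[5e-4]]),
                  np.array([[0.9]])]
        res = link_viterbi_extended(matrices_from_arrays(arrays))
        tr = res.trajectories[0]
        assert tr.status == TRUNCATED_DISAPPEARED
        assert tr.nodes[-1][0] == 1
        # the detections after the truncation are re-seeded
        assert any(t.nodes[0] == (2, 1) for t in res.trajectories)

    def test_zero_rows_give_distinct_status(self):
        arrays = [np.array([[0.9]]), np.array([[0.0]]),
                  np.array([[0.9]])]
        res = link_viterbi_extended(matrices_from_arrays(arrays))
        tr = res.trajectories[0]
        assert tr.status == ENDED_ZERO_SCORES

    def test_appearing_detection_seeds_new_trajectory(self):
        # two cells at frame 1 but only one at frame 0
        arrays = [np.array([[1.0, 0.0]]), np.eye(2)]
        res = link_viterbi_extended(matrices_from_arrays(arrays))
        starts = {t.nodes[0] for t in res.trajectories}
        assert (1, 2) in starts

    def test_every_detection_is_covered(self, rng):
        """Conservation: after the appearance pass no detection is
        orphaned."""
        for _ in range(20):
            arrays = random_chain(rng)
            mats = matrices_from_arrays(arrays)
            res = link_viterbi_extended(mats)
            occ = res.occupancy()
            for f, size in enumerate([arrays[0].shape[0]]
                                     + [a.shape[1] for a in arrays]):
                for lab in range(1, size + 1):
                    assert (f, lab) in occ

    def test_matches_oracle_when_optima_are_disjoint(self, rng):
        params = LinkageParams(T_truncated=0.0)
        checked = 0
        while checked < 20:
            arrays = random_chain(rng)
            oracle = {seed: enumerate_best_path(arrays, seed)
                      for seed in range(1, arrays[0].shape[0] + 1)}
            node_sets = [set(nodes) for nodes, _ in oracle.values()]
            disjoint = all(not (node_sets[i] & node_sets[j])
                           for i in range(len(node_sets))
                           for j in range(i + 1, len(node_sets)))
            if not disjoint:
                continue
            checked += 1
            res = link_viterbi_extended(matrices_from_arrays(arrays), params)
            for seed, (nodes, prod) in oracle.items():
                tr = next(t for t in res.trajectories
                          if t.nodes[0] == (0, seed))
                assert tr.nodes == nodes

    def test_all_zero_chain_gives_length_one_tracks(self):
        arrays = [np.zeros((3, 3)), np.zeros((3, 3))]
        res = link_viterbi_extended(matrices_from_arrays(arrays))
        assert all(len(t) == 1 for t in res.trajectories)
        assert len(res.trajectories) == 9  # every detection seeds one


def test_link_dispatch_and_unknown_method():
    mats = matrices_from_arrays([np.eye(2)])
    assert link(mats, "greedy").method == "greedy"
    with pytest.raises(ValueError):
        link(mats, "bogus")


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        LinkageParams(T_merge=1.5)
    with pytest.raises(ValueError):
        LinkageParams(reroute_factor=0.5)
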