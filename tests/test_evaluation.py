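"""Tracking metrics (TP/OP/FIT/FIO), corruption monotonicity, and the
Kruskal–Wallis + Dunn + Benjamini–Hochberg comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neutrack.evaluation import (compute_metrics, evaluate_tracking,
                                 kruskal_dunn, match_identities,
                                 split_counts)


def _tracks(records):
    return pd.DataFrame(records, columns=["track_id", "frame", "x", "y"])


def _grid_gt(n_tracks=4, n_frames=10, spacing=50.0):
    rows = []
    for tid in range(1, n_tracks + 1):
        for f in range(n_frames):
            rows.append((tid, f, spacing * tid, 10.0 + 2.0 * f))
    return _tracks(rows)


class TestMatchIdentities:
    def test_exact_prediction_identifies_everywhere(self):
        gt = _grid_gt()
        pred = gt.copy()
        pred["track_id"] += 100
        out = match_identities(pred, gt, radius=10.0)
        assert (out["identified_gt"] >= 0).all()
        assert (out["matched_gt"] == out["track_id"] - 100).all()

    def test_far_track_is_unmatched(self):
        gt = _grid_gt(n_tracks=1)
        pred = gt.copy()
        pred["x"] += 500.0
        out = match_identities(pred, gt, radius=10.0)
        assert (out["identified_gt"] == -1).all()
        assert (out["matched_gt"] == -1).all()

    def test_majority_vote_picks_dominant_object(self):
        """A track following object 1 for 6 frames then object 2 for 4 is
        matched to object 1."""
        gt = _grid_gt(n_tracks=2)
        rows = [(7, f, 50.0 if f < 6 else 100.0, 10.0 + 2.0 * f)
                for f in range(10)]
        out = match_identities(_tracks(rows), gt, radius=5.0)
        assert (out["matched_gt"] == 1).all()


class TestComputeMetrics:
    def test_perfect_tracking_scores_perfectly(self):
        gt = _grid_gt()
        pred = gt.copy()
        pred["track_id"] += 100
        rep = evaluate_tracking(pred, gt, radius=5.0)
        assert rep.tp == 1.0 and rep.op == 1.0
        assert rep.fit == 0.0 and rep.fio == 0.0
        assert rep.avg_track_length == 10.0

    def test_half_correct_track_purity(self):
        """A 10-frame track correct in 5 frames contributes purity 0.5."""
        gt = _grid_gt(n_tracks=2)
        rows = [(7, f, 50.0 if f < 5 else 100.0, 10.0 + 2.0 * f)
                for f in range(10)]
        rep = evaluate_tracking(_tracks(rows), gt, radius=5.0)
        assert rep.per_track["purity"].iloc[0] == 0.5

    def test_avg_track_length_is_mean_node_count(self):
        gt = _grid_gt(n_tracks=1)
        rows = ([(1, f, 50.0, 10.0 + 2.0 * f) for f in range(3)]
                + [(2, f, 50.0, 10.0 + 2.0 * f) for f in range(5)])
        rep = evaluate_tracking(_tracks(rows), gt, radius=5.0)
        assert rep.avg_track_length == 4.0

    def test_empty_prediction_warns_and_reports_zero(self):
        gt = _grid_gt()
        with pytest.warns(UserWarning):
            rep = compute_metrics(
                match_identities(_tracks([]), gt), gt)
        assert rep.tp == 0.0

    def test_purities_invariant_to_relabeling(self, rng):
        gt = _grid_gt()
        pred = gt.copy()
        pred["track_id"] += 100
        rep_a = evaluate_tracking(pred, gt, radius=5.0)
        relabeled = pred.copy()
        mapping = {101: 9, 102: 500, 103: 7, 104: 42}
        relabeled["track_id"] = relabeled["track_id"].map(mapping)
        rep_b = evaluate_tracking(relabeled, gt, radius=5.0)
        assert rep_a.tp == rep_b.tp and rep_a.op == rep_b.op

    def test_corruption_monotonicity(self, rng):
        """Reassigning k% of node identities never increases the
        purities and never decreases the error rates."""
        gt = _grid_gt(n_tracks=6, n_frames=20)
        perfect = gt.copy()
        perfect["track_id"] += 100
        base = evaluate_tracking(perfect, gt, radius=5.0)
        order = rng.permutation(len(perfect))
        reports = []
        for k in (0.1, 0.3, 0.5):
            corrupted = perfect.copy()
            chosen = order[:int(k * len(perfect))]  # nested corruption sets
            ids = corrupted["track_id"].to_numpy().copy()
            ids[chosen] = 100 + ((ids[chosen] - 100 + 2) % 6) + 1
            corrupted["track_id"] = ids
            reports.append(evaluate_tracking(corrupted, gt, radius=5.0))
        for rep in reports:
            assert rep.tp <= base.tp and rep.op <= base.op
            assert rep.fit >= base.fit and rep.fio >= base.fio
        for a, b in zip(reports, reports[1:]):
            assert b.tp <= a.tp + 1e-12
            assert b.op <= a.op + 1e-12


class TestSplitCounts:
    @pytest.mark.parametrize("total,expected", [
        (240, (192, 48)),
        (192, (153, 39)),
        (110, (88, 22)),
    ])
    def test_eight_two_splits(self, total, expected):
        assert split_counts(total, 0.8) == expected

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_counts(100, 1.0)


class TestKruskalDunn:
    def test_identical_samples_omnibus_one(self):
        res = kruskal_dunn({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert res["p"] == 1.0 and res["posthoc"] is None

    def test_h_matches_hand_computed_rank_statistic(self):
        """H for {1,2,3} vs {101,102,103} vs {1,2,3} from rank sums with
        tie correction."""
        groups = {"a": [1, 2, 3], "b": [101, 102, 103], "c": [1, 2, 3]}
        res = kruskal_dunn(groups)
        # pooled ranks: 1->1.5, 2->3.5, 3->5.5 (tied pairs), 101..103->7,8,9
        r = {"a": 1.5 + 3.5 + 5.5, "b": 7 + 8 + 9, "c": 1.5 + 3.5 + 5.5}
        n, N = 3, 9
        h = 12.0 / (N * (N + 1)) * sum(v ** 2 / n for v in r.values()) \
            - 3 * (N + 1)
        ties = 3 * (2 ** 3 - 2)
        h /= 1.0 - ties / (N ** 3 - N)
        assert res["h"] == pytest.approx(h, abs=1e-12)

    def test_posthoc_flags_the_outlying_group(self):
        groups = {"a": [1, 2, 3, 4], "b": [101, 102, 103, 104],
                  "c": [1.1, 2.1, 2.9, 4.2]}
        res = kruskal_dunn(groups)
        post = res["posthoc"]
        assert post is not None
        ab = post[(post.group_a == "a") & (post.group_b == "b")]
        ac = post[(post.group_a == "a") & (post.group_b == "c")]
        assert abs(ab["z"].iloc[0]) > abs(ac["z"].iloc[0])

    def test_bh_adjustment_matches_step_up_formula(self):
        """BH on {0.01, 0.02, 0.03} with m=3 adjusts all three to 0.03."""
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_dunn_z_sanity_against_normal_two_group(self):
        """With two groups and no ties, Dunn's |z| relates to the
        Kruskal H as z^2 ~= H."""
        groups = {"a": [1.0, 2.0, 3.0, 4.0], "b": [10.0, 11.0, 12.0, 13.0]}
        h = sps.kruskal(groups["a"], groups["b"]).statistic
        res = kruskal_dunn(groups, alpha=1.0)
        z = res["posthoc"]["z"].iloc[0]
        assert z ** 2 == pytest.approx(h, rel=1e-9)

    def test_too_few_groups_or_samples_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            kruskal_dunn({"a": [1], "b": [1, 2]})
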