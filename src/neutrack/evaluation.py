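"""Tracking-quality metrics and cross-method statistical comparison.

Predicted trajectories and ground-truth tracks are both given as tables
of (track_id, frame, x, y).  Each predicted node *identifies* the nearest
ground-truth object within a matching radius; a predicted track is
matched to the ground-truth object it identifies in the majority of its
frames.  From these identifications:

* track purity (TP) — fraction of a track's frames in which it identifies
  its matched object, averaged over tracks;
* object purity (OP) — fraction of an object's frames in which it is
  identified by a track matched to it, averaged over objects;
* FIT — (frame, object) identifications by a wrongly-matched track;
* FIO — (frame, track) events where a track identifies an object other
  than its match.  FIT and FIO are normalised per frame per cell
  (divided by n_frames x mean ground-truth cells per frame).

The cross-method comparison is a Kruskal–Wallis omnibus test followed by
Dunn's pairwise post-hoc z-tests with Benjamini–Hochberg correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "match_identities",
    "compute_metrics",
    "evaluate_tracking",
    "MetricsReport",
    "kruskal_dunn",
    "compare_methods",
    "split_counts",
]


def split_counts(n_total: int, train_fraction: float = 0.8
                 ) -> tuple[int, int]:
    """Deterministic dataset split sizes: (floor(n*frac), remainder).

    With an 8:2 ratio, 240 images split 192/48 and 192 images 153/39.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    train = int(n_total * train_fraction)
    return train, n_total - train


def match_identities(pred: pd.DataFrame, gt: pd.DataFrame,
                     radius: float = 10.0) -> pd.DataFrame:
    """Frame-level identification table plus per-track majority matching.

    Both inputs need columns (track_id, frame, x, y).  Returns a copy of
    ``pred`` with two added columns: ``identified_gt`` (the nearest
    ground-truth id within ``radius`` at that frame, or -1) and
    ``matched_gt`` (the track's majority identification, or -1).
    """
    pred = pred.copy()
    identified = np.full(len(pred), -1, dtype=np.int64)
    gt_by_frame = {f: g for f, g in gt.groupby("frame")}
    for f, idx in pred.groupby("frame").groups.items():
        g = gt_by_frame.get(f)
        if g is None or not len(g):
            continue
        gx = g["x"].to_numpy()
        gy = g["y"].to_numpy()
        gids = g["track_id"].to_numpy()
        px = pred.loc[idx, "x"].to_numpy()
        py = pred.loc[idx, "y"].to_numpy()
        d = np.hypot(px[:, None] - gx[None, :], py[:, None] - gy[None, :])
        nearest = np.argmin(d, axis=1)
        ok = d[np.arange(len(idx)), nearest] <= radius
        identified[pred.index.get_indexer(idx)] = np.where(
            ok, gids[nearest], -1)
    pred["identified_gt"] = identified
    matched = {}
    for tid, sub in pred.groupby("track_id"):
        ids = sub["identified_gt"]
        ids = ids[ids >= 0]
        if len(ids):
            counts = ids.value_counts()
            top = counts.max()
            matched[tid] = int(min(c for c, n in counts.items() if n == top))
        else:
            matched[tid] = -1
    pred["matched_gt"] = pred["track_id"].map(matched)
    return pred


@dataclass
class MetricsReport:
    fit: float
    fio: float
    tp: float
    op: float
    avg_track_length: float
    n_tracks: int
    n_gt: int
    per_track: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {"fit": self.fit, "fio": self.fio, "tp": self.tp,
                "op": self.op, "avg_track_length": self.avg_track_length,
                "n_tracks": self.n_tracks, "n_gt": self.n_gt}


def compute_metrics(assigned: pd.DataFrame, gt: pd.DataFrame,
                    n_frames: int | None = None) -> MetricsReport:
    """Purity and error metrics from an identification table.

    ``assigned`` is the output of :func:`match_identities`; ``gt`` the
    ground-truth table.  ``n_frames`` defaults to the ground truth's
    frame span.
    """
    if n_frames is None:
        n_frames = int(gt["frame"].max()) + 1 if len(gt) else 0
    mean_cells = len(gt) / n_frames if n_frames else 0.0
    norm = n_frames * mean_cells if n_frames and mean_cells else 1.0

    if not len(assigned):
        warnings.warn("empty prediction set: purity metrics undefined, "
                      "reported as 0", stacklevel=2)
        return MetricsReport(0.0, 0.0, 0.0, 0.0, 0.0, 0, gt["track_id"].nunique(),
                             pd.DataFrame())

    rows = []
    for tid, sub in assigned.groupby("track_id"):
        m = sub["matched_gt"].iloc[0]
        correct = int((sub["identified_gt"] == m).sum()) if m >= 0 else 0
        rows.append({"track_id": tid, "matched_gt": m, "length": len(sub),
                     "purity": correct / len(sub)})
    per_track = pd.DataFrame(rows)
    tp = float(per_track["purity"].mean())
    avg_len = float(per_track["length"].mean())

    op_vals = []
    for gid, gsub in gt.groupby("track_id"):
        gframes = set(gsub["frame"])
        hits = assigned[(assigned["matched_gt"] == gid)
                        & (assigned["identified_gt"] == gid)]
        covered = len(set(hits["frame"]) & gframes)
        op_vals.append(covered / len(gframes))
    op = float(np.mean(op_vals)) if op_vals else 0.0

    wrong = assigned[(assigned["identified_gt"] >= 0)
                     & (assigned["identified_gt"] != assigned["matched_gt"])]
    fit = len(wrong.groupby(["frame", "identified_gt"])) / norm
    fio = len(wrong.groupby(["frame", "track_id"])) / norm
    return MetricsReport(fit=float(fit), fio=float(fio), tp=tp, op=op,
                         avg_track_length=avg_len,
                         n_tracks=assigned["track_id"].nunique(),
                         n_gt=gt["track_id"].nunique(),
                         per_track=per_track)


def evaluate_tracking(pred: pd.DataFrame, gt: pd.DataFrame,
                      radius: float = 10.0,
                      n_frames: int | None = None) -> MetricsReport:
    """Convenience: identity matching followed by metric computation."""
    return compute_metrics(match_identities(pred, gt, radius), gt,
                           n_frames=n_frames)


# ---------------------------------------------------------------------------
# statistical comparison across methods
# ---------------------------------------------------------------------------

def _dunn_z(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc pairwise z statistics with tie correction."""
    names = list(groups)
    values = np.concatenate([np.asarray(groups[n], dtype=float)
                             for n in names])
    sizes = {n: len(groups[n]) for n in names}
    ranks = stats.rankdata(values)
    mean_rank = {}
    i = 0
    for n in names:
        mean_rank[n] = float(ranks[i:i + sizes[n]].mean())
        i += sizes[n]
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (N - 1))) if N > 1 else 0.0
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            na, nb = names[a], names[b]
            se = math.sqrt((N * (N + 1) / 12.0 - tie_term)
                          * (1.0 / sizes[na] + 1.0 / sizes[nb]))
            z = (mean_rank[na] - mean_rank[nb]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": na, "group_b": nb, "z": z, "p": p})
    return pd.DataFrame(rows)


def kruskal_dunn(groups: dict[str, np.ndarray], alpha: float = 0.05
                 ) -> dict:
    """Kruskal–Wallis omnibus test; Dunn + BH post hoc if significant.

    Returns {"h", "p", "posthoc"} where ``posthoc`` is a DataFrame with
    pairwise z, raw p and BH-adjusted p (None when the omnibus test is
    not significant or identical samples make it degenerate).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 samples per group")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return {"h": 0.0, "p": 1.0, "posthoc": None}
    h, p = stats.kruskal(*arrays)
    result = {"h": float(h), "p": float(p), "posthoc": None}
    if p < alpha:
        post = _dunn_z(groups)
        post["p_adj"] = multipletests(post["p"], method="fdr_bh")[1]
        result["posthoc"] = post
    return result


def compare_methods(samples: dict[str, pd.DataFrame],
                    metrics: tuple[str, ...] = ("fit", "fio", "tp", "op"),
                    alpha: float = 0.05) -> dict[str, dict]:
    """Per-metric Kruskal–Wallis + Dunn/BH over per-method sample tables.

    ``samples`` maps method name to a DataFrame with one row per sequence
    and one column per metric.
    """
    out = {}
    for m in metrics:
        out[m] = kruskal_dunn(
            {name: df[m].to_numpy() for name, df in samples.items()},
            alpha=alpha)
    return out
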