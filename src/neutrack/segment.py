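"""Reference segmentation and segmentation-quality metrics.

The reference segmenter is a deterministic classical pipeline — normalise
to [0, 1], threshold at ``t``, label 8-connected components, drop specks —
that stands in for a trained instance-segmentation network wherever the
downstream tracking stages need per-frame labelled masks.

Evaluation follows the standard tracking-oriented convention: a semantic
Jaccard index on the union foreground, object-level F1 from
mutually-maximal-overlap matching, plus under-/over-segmentation counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "SegParams",
    "CellDetection",
    "SegMetrics",
    "segment_reference",
    "segment_sequence",
    "extract_detections",
    "evaluate_segmentation",
    "object_iou_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegParams:
    """t: foreground threshold on normalised intensity; min_area in px."""

    t: float = 0.1
    min_area: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")


@dataclass
class CellDetection:
    """One segmented cell instance in one frame."""

    frame_index: int
    label: int
    centroid: tuple[float, float]  # (x, y) pixels
    area: int
    pixel_set: np.ndarray = field(repr=False)  # (n, 2) array of (row, col)


def segment_reference(frame: np.ndarray, params: SegParams = SegParams()
                      ) -> np.ndarray:
    """Threshold-and-label segmentation of a single intensity frame.

    The frame is min-max normalised to [0, 1]; pixels strictly above
    ``params.t`` are foreground; 8-connected components smaller than
    ``min_area`` are discarded.  An all-background result is valid.
    """
    frame = np.asarray(frame, dtype=np.float64)
    lo, hi = float(frame.min()), float(frame.max())
    if hi > lo:
        norm = (frame - lo) / (hi - lo)
    else:
        norm = np.zeros_like(frame)
    fg = norm > params.t
    labels = cc_label(fg, connectivity=2).astype(np.int32)
    if params.min_area > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < params.min_area)
        if small.size:
            labels[np.isin(labels, small)] = 0
        labels = cc_label(labels > 0, connectivity=2).astype(np.int32)
    if labels.max() == 0:
        log.info("segment_reference: empty mask (no foreground above t=%g)",
                 params.t)
    return labels


def segment_sequence(frames, params: SegParams = SegParams()
                     ) -> list[np.ndarray]:
    return [segment_reference(f, params) for f in frames]


def extract_detections(mask: np.ndarray, frame_index: int = 0
                       ) -> list[CellDetection]:
    """One :class:`CellDetection` per positive label, centroid = mean."""
    out = []
    for rp in regionprops(np.asarray(mask)):
        cy, cx = rp.centroid
        out.append(CellDetection(
            frame_index=frame_index,
            label=int(rp.label),
            centroid=(float(cx), float(cy)),
            area=int(rp.area),
            pixel_set=rp.coords.copy(),
        ))
    out.sort(key=lambda d: d.label)
    return out


@dataclass
class SegMetrics:
    iou: float
    f1: float
    true_pos: int
    fp: int
    fn: int
    n_under: int  # predicted objects spanning >= 2 truth objects (merges)
    n_over: int   # truth objects covered by >= 2 predicted objects (splits)


def _overlap_table(truth: np.ndarray, pred: np.ndarray) -> dict:
    """Pixel-overlap counts for every (truth label, pred label) pair."""
    both = (truth > 0) & (pred > 0)
    pairs, counts = np.unique(
        np.stack([truth[both], pred[both]]), axis=1, return_counts=True)
    return {(int(t), int(p)): int(c)
            for (t, p), c in zip(pairs.T, counts)}


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Compare a predicted labelled mask against the ground truth.

    IoU is computed on binary foregrounds.  Objects are matched by
    mutually maximal pixel overlap: a (truth, pred) pair whose overlap is
    the largest both row-wise and column-wise counts as a true positive;
    unmatched predictions are FP, unmatched truth objects FN.  A predicted
    object overlapping >= 2 truth objects counts one under-segmentation; a
    truth object overlapped by >= 2 predictions counts one
    over-segmentation.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("mask shape mismatch")
    pf, tf = pred > 0, truth > 0
    union = int(np.logical_or(pf, tf).sum())
    inter = int(np.logical_and(pf, tf).sum())
    iou = inter / union if union else 1.0

    table = _overlap_table(truth, pred)
    t_labels = {int(v) for v in np.unique(truth) if v > 0}
    p_labels = {int(v) for v in np.unique(pred) if v > 0}
    best_for_t: dict[int, tuple[int, int]] = {}
    best_for_p: dict[int, tuple[int, int]] = {}
    t_partners: dict[int, int] = {}
    p_partners: dict[int, int] = {}
    for (t, p), c in sorted(table.items()):
        if t not in best_for_t or c > best_for_t[t][1]:
            best_for_t[t] = (p, c)
        if p not in best_for_p or c > best_for_p[p][1]:
            best_for_p[p] = (t, c)
        t_partners[t] = t_partners.get(t, 0) + 1
        p_partners[p] = p_partners.get(p, 0) + 1
    true_pos = sum(1 for t, (p, _) in best_for_t.items()
                   if best_for_p.get(p, (None,))[0] == t)
    matched_p = {best_for_t[t][0] for t in best_for_t
                 if best_for_p.get(best_for_t[t][0], (None,))[0] == t}
    matched_t = {t for t in best_for_t
                 if best_for_p.get(best_for_t[t][0], (None,))[0] == t}
    fp = len(p_labels - matched_p)
    fn = len(t_labels - matched_t)
    n_under = sum(1 for p, n in p_partners.items() if n >= 2)
    n_over = sum(1 for t, n in t_partners.items() if n >= 2)
    denom = 2 * true_pos + fp + fn
    f1 = 2 * true_pos / denom if denom else 1.0
    return SegMetrics(iou=iou, f1=f1, true_pos=true_pos, fp=fp, fn=fn,
                      n_under=n_under, n_over=n_over)


def object_iou_table(pred: np.ndarray, truth: np.ndarray
                     ) -> dict[tuple[int, int], float]:
    """Per-(truth, pred) object IoU, for diagnostics."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    table = _overlap_table(truth, pred)
    t_area = {int(v): int(c) for v, c in
              zip(*np.unique(truth[truth > 0], return_counts=True))}
    p_area = {int(v): int(c) for v, c in
              zip(*np.unique(pred[pred > 0], return_counts=True))}
    return {(t, p): c / (t_area[t] + p_area[p] - c)
            for (t, p), c in table.items()}
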