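"""Score-matrix construction for adjacent frame pairs.

For every cell detected at frame t a candidate region for frame t+1 is
predicted; the predicted pixels are intersected with the frame-t+1
segmentation and the overlap areas are normalised into linkage scores in
[0, 1].  Rows are cells at frame t, columns cells at frame t+1, so a
120-frame sequence yields 119 adjacent score matrices.

The built-in predictor is a dilation-based spatial-proximity prior; an
adapter accepts externally supplied per-cell prediction masks (e.g. from a
learned motion model) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .segment import CellDetection, extract_detections

__all__ = [
    "CellPrediction",
    "ScoreMatrix",
    "proxy_predict",
    "overlap_score_matrix",
    "score_sequence",
    "select_best_roi",
    "matrices_from_arrays",
]

NORMALIZATIONS = ("pred", "target", "union")


@dataclass
class CellPrediction:
    """Predicted frame-t+1 support for one frame-t cell.

    ``pixels`` is an (n, 2) array of (row, col) coordinates; it may be
    empty (a disappearance prediction).
    """

    source_frame: int
    source_label: int
    pixels: np.ndarray
    shape: tuple[int, int]

    @property
    def area(self) -> int:
        return int(len(self.pixels))

    def as_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        if len(self.pixels):
            m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class ScoreMatrix:
    """Linkage scores between cells of frames ``frame_pair``.

    ``scores[i, j]`` in [0, 1] links ``row_labels[i]`` (frame t) to
    ``col_labels[j]`` (frame t+1).
    """

    frame_pair: tuple[int, int]
    scores: np.ndarray
    row_labels: list[int]
    col_labels: list[int]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("score matrix shape does not match label counts")
        if self.scores.size and (self.scores.min() < 0
                                 or self.scores.max() > 1 + 1e-12):
            raise ValueError("scores must lie in [0, 1]")


def proxy_predict(det: CellDetection, mask_t: np.ndarray,
                  search_radius: int = 10) -> CellPrediction:
    """Dilate the detection's pixel set by ``search_radius``.

    A purely spatial-proximity prior standing in for a learned motion
    predictor; with radius 0 the prediction is the detection itself.
    """
    shape = tuple(mask_t.shape)
    if search_radius < 0:
        raise ValueError("search_radius must be >= 0")
    if det.area == 0:
        return CellPrediction(det.frame_index, det.label,
                              np.empty((0, 2), dtype=int), shape)
    if search_radius == 0:
        return CellPrediction(det.frame_index, det.label,
                              det.pixel_set.copy(), shape)
    rows, cols = det.pixel_set[:, 0], det.pixel_set[:, 1]
    r0 = max(0, rows.min() - search_radius)
    r1 = min(shape[0], rows.max() + search_radius + 1)
    c0 = max(0, cols.min() - search_radius)
    c1 = min(shape[1], cols.max() + search_radius + 1)
    window = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    window[rows - r0, cols - c0] = True
    dil = ndimage.binary_dilation(window, structure=disk(search_radius))
    rr, cc = np.nonzero(dil)
    pixels = np.stack([rr + r0, cc + c0], axis=1)
    return CellPrediction(det.frame_index, det.label, pixels, shape)


def overlap_score_matrix(preds: list[CellPrediction], mask_t1: np.ndarray,
                         normalize: str = "pred",
                         frame_pair: tuple[int, int] | None = None
                         ) -> ScoreMatrix:
    """Overlap areas between predictions and frame-t+1 regions.

    raw(i, j) = |prediction_i ∩ region_j|; normalisation divides by the
    prediction area (default), the target region area, or their union,
    giving entries interpretable as linkage probabilities.
    """
    if normalize not in NORMALIZATIONS:
        raise ValueError(f"normalize must be one of {NORMALIZATIONS}")
    mask_t1 = np.asarray(mask_t1)
    col_labels = sorted(int(v) for v in np.unique(mask_t1) if v > 0)
    cidx = {lab: j for j, lab in enumerate(col_labels)}
    col_areas = {lab: int((mask_t1 == lab).sum()) for lab in col_labels}
    row_labels = [p.source_label for p in preds]
    raw = np.zeros((len(preds), len(col_labels)), dtype=np.float64)
    for i, p in enumerate(preds):
        if p.area == 0:
            continue
        hit = mask_t1[p.pixels[:, 0], p.pixels[:, 1]]
        labs, counts = np.unique(hit[hit > 0], return_counts=True)
        for lab, c in zip(labs, counts):
            raw[i, cidx[int(lab)]] = float(c)
    scores = np.zeros_like(raw)
    for i, p in enumerate(preds):
        for j, lab in enumerate(col_labels):
            c = raw[i, j]
            if c == 0:
                continue
            if normalize == "pred":
                scores[i, j] = c / max(1, p.area)
            elif normalize == "target":
                scores[i, j] = c / max(1, col_areas[lab])
            else:
                scores[i, j] = c / (p.area + col_areas[lab] - c)
    if frame_pair is None:
        src = preds[0].source_frame if preds else 0
        frame_pair = (src, src + 1)
    return ScoreMatrix(frame_pair, scores, row_labels, col_labels)


def score_sequence(masks: list[np.ndarray], search_radius: int = 10,
                   normalize: str = "pred",
                   predictor=None) -> list[ScoreMatrix]:
    """Score matrices for every adjacent frame pair of a mask sequence.

    Exactly ``len(masks) - 1`` matrices are returned, in temporal order.
    ``predictor(det, mask_t)`` may replace the built-in proximity prior.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 frames")
    if predictor is None:
        def predictor(det, mask_t):
            return proxy_predict(det, mask_t, search_radius)
    out = []
    for t in range(len(masks) - 1):
        dets = extract_detections(masks[t], frame_index=t)
        preds = [predictor(d, masks[t]) for d in dets]
        out.append(overlap_score_matrix(preds, masks[t + 1],
                                        normalize=normalize,
                                        frame_pair=(t, t + 1)))
    return out


def select_best_roi(pred_mask: np.ndarray, intensity_frame: np.ndarray
                    ) -> np.ndarray:
    """Keep only the connected component with highest mean intensity.

    Applied to externally supplied predictions that may contain several
    blobs; a prediction with one ROI (or none) is returned unchanged.
    """
    pred_mask = np.asarray(pred_mask, dtype=bool)
    labels = cc_label(pred_mask, connectivity=2)
    n = labels.max()
    if n <= 1:
        return pred_mask
    frame = np.asarray(intensity_frame, dtype=np.float64)
    means = ndimage.mean(frame, labels=labels, index=np.arange(1, n + 1))
    best = int(np.argmax(means)) + 1
    return labels == best


def matrices_from_arrays(arrays) -> list[ScoreMatrix]:
    """Wrap plain 2-D arrays into a consistent ScoreMatrix chain.

    Cells are labelled 1..n per frame; shapes must chain (cols of matrix
    t == rows of matrix t+1).  Convenience for tests and hand-built
    examples.
    """
    mats = []
    for t, a in enumerate(arrays):
        a = np.asarray(a, dtype=np.float64)
        if t > 0 and a.shape[0] != mats[-1].scores.shape[1]:
            raise ValueError("matrix chain is inconsistent")
        mats.append(ScoreMatrix((t, t + 1), a,
                                list(range(1, a.shape[0] + 1)),
                                list(range(1, a.shape[1] + 1))))
    return mats
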