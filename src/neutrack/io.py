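"""File formats: multi-page TIFF stacks, tracks CSV, score-matrix CSVs.

The tracks CSV schema (track_id, frame, cell_label, x, y, step_score,
accumulated_score, status) is the single interchange format for both
predicted and ground-truth trajectories; ground-truth rows leave the
score columns empty.  Frame indices are 0-based, x = column, y = row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .linkage import TrackingResult
from .segment import extract_detections
from .simulate import GroundTruthTrack, SimOutput

__all__ = [
    "TRACK_COLUMNS",
    "write_stack",
    "read_stack",
    "write_tracks_csv",
    "read_tracks_csv",
    "tracking_result_to_frame",
    "gt_tracks_to_frame",
    "write_score_matrices",
    "read_score_matrices",
    "write_sim_output",
]

TRACK_COLUMNS = ["track_id", "frame", "cell_label", "x", "y",
                 "step_score", "accumulated_score", "status"]


def write_stack(path, frames, dtype=None) -> None:
    """Write a sequence of 2-D arrays as a multi-page TIFF."""
    arr = np.stack([np.asarray(f) for f in frames])
    if dtype is not None:
        arr = arr.astype(dtype)
    # explicit photometric: a 3-page stack must not be guessed as RGB
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_stack(path) -> list[np.ndarray]:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return [arr[i] for i in range(arr.shape[0])]


def tracking_result_to_frame(result: TrackingResult,
                             masks: list[np.ndarray] | None = None
                             ) -> pd.DataFrame:
    """Flatten a TrackingResult into the tracks CSV schema.

    When ``masks`` are given, x/y are the centroids of the referenced
    detections; otherwise they are left as NaN.
    """
    centroids: dict[tuple[int, int], tuple[float, float]] = {}
    if masks is not None:
        for f, mask in enumerate(masks):
            for det in extract_detections(mask, frame_index=f):
                centroids[(f, det.label)] = det.centroid
    rows = []
    for tr in result.trajectories:
        acc = 1.0
        for k, (f, lab) in enumerate(tr.nodes):
            step = tr.step_scores[k - 1] if k > 0 else np.nan
            if k > 0:
                acc *= tr.step_scores[k - 1]
            x, y = centroids.get((f, lab), (np.nan, np.nan))
            rows.append({
                "track_id": tr.track_id, "frame": f, "cell_label": lab,
                "x": x, "y": y, "step_score": step,
                "accumulated_score": acc, "status": tr.status,
            })
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def gt_tracks_to_frame(gt_tracks: list[GroundTruthTrack]) -> pd.DataFrame:
    """Ground-truth tracks in the shared schema (score columns empty)."""
    rows = []
    for tr in gt_tracks:
        for f, x, y, lab in zip(tr.frames, tr.xs, tr.ys, tr.labels):
            rows.append({
                "track_id": tr.track_id, "frame": f, "cell_label": lab,
                "x": x, "y": y, "step_score": np.nan,
                "accumulated_score": np.nan, "status": "",
            })
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks_csv(path, tracks: pd.DataFrame) -> None:
    tracks.to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"tracks CSV missing columns {sorted(missing)}")
    if "status" in df.columns:
        df["status"] = df["status"].fillna("")
    return df


def write_score_matrices(directory, matrices) -> None:
    """One CSV per frame pair (labelled rows/cols) plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for m in matrices:
        name = f"scores_{m.frame_pair[0]:04d}_{m.frame_pair[1]:04d}.csv"
        df = pd.DataFrame(m.scores, index=m.row_labels, columns=m.col_labels)
        df.to_csv(directory / name)
        manifest.append({"frame_pair": list(m.frame_pair), "file": name})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_score_matrices(directory):
    from .scoring import ScoreMatrix

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = []
    for entry in manifest:
        df = pd.read_csv(directory / entry["file"], index_col=0)
        out.append(ScoreMatrix(tuple(entry["frame_pair"]),
                               df.to_numpy(dtype=float),
                               [int(v) for v in df.index],
                               [int(v) for v in df.columns]))
    return out


def write_sim_output(directory, sim: SimOutput) -> None:
    """Persist a simulation: frames + masks as TIFF, tracks + events as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_stack(directory / "frames.tif", sim.frames, dtype=np.float32)
    write_stack(directory / "gt_masks.tif", sim.gt_masks, dtype=np.int32)
    write_tracks_csv(directory / "gt_tracks.csv",
                     gt_tracks_to_frame(sim.gt_tracks))
    events = pd.DataFrame(
        [{"kind": e.kind, "frame": e.frame,
          "track_ids": ";".join(map(str, e.track_ids))}
         for e in sim.event_log])
    events.to_csv(directory / "events.csv", index=False)
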