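"""Cell-migration statistics from trajectories.

Net displacement is the Euclidean distance between a cell's first and
last positions; the meandering index is net displacement divided by total
path length (1 = perfectly straight); mean speed is total path length
divided by travel time.  A cell is classified *distant* when its average
per-step displacement exceeds a threshold (default 2.4 µm, stable within
2.2–2.5 µm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MigrationStats", "migration_stats", "stats_for_tracks",
           "group_compare"]

DISTANT_MODES = ("step", "per_frame")


@dataclass
class MigrationStats:
    track_id: int
    net_displacement: float  # µm
    total_distance: float  # µm
    meandering_index: float  # unitless in [0, 1]
    mean_speed: float  # µm / min
    avg_step_displacement: float  # µm / frame
    is_distant: bool
    degenerate: bool = False  # total distance was zero

    def as_dict(self) -> dict:
        return {
            "track_id": self.track_id,
            "net_displacement": self.net_displacement,
            "total_distance": self.total_distance,
            "meandering_index": self.meandering_index,
            "mean_speed": self.mean_speed,
            "avg_step_displacement": self.avg_step_displacement,
            "is_distant": self.is_distant,
        }


def migration_stats(positions, pixel_size: float = 1.0,
                    frame_interval: float = 1.0,
                    distant_threshold: float = 2.4,
                    distant_mode: str = "step",
                    track_id: int = 0) -> MigrationStats:
    """Migration statistics for one track.

    ``positions`` is a sequence of (x, y) in pixels, one per frame, in
    temporal order; at least two are required.  ``distant_mode`` selects
    how "average net displacement between frames" is operationalised:
    ``"step"`` (default) uses the mean per-step path length; ``"per_frame"``
    divides the net displacement by the number of steps.
    """
    if distant_mode not in DISTANT_MODES:
        raise ValueError(f"distant_mode must be one of {DISTANT_MODES}")
    pos = np.asarray(positions, dtype=float) * pixel_size
    if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] != 2:
        raise ValueError("need at least two (x, y) positions")
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    total = float(steps.sum())
    net = float(math.hypot(*(pos[-1] - pos[0])))
    n_steps = len(steps)
    degenerate = total == 0.0
    if degenerate:
        warnings.warn("zero total distance: meandering index reported as 0",
                      stacklevel=2)
    mi = net / total if total > 0 else 0.0
    speed = total / (n_steps * frame_interval)
    avg_step = total / n_steps
    per_frame_net = net / n_steps
    basis = avg_step if distant_mode == "step" else per_frame_net
    return MigrationStats(
        track_id=track_id,
        net_displacement=net,
        total_distance=total,
        meandering_index=mi,
        mean_speed=speed,
        avg_step_displacement=avg_step,
        is_distant=bool(basis > distant_threshold),
        degenerate=degenerate,
    )


def stats_for_tracks(tracks: pd.DataFrame, pixel_size: float = 1.0,
                     frame_interval: float = 1.0,
                     distant_threshold: float = 2.4,
                     distant_mode: str = "step",
                     min_length: int = 2) -> pd.DataFrame:
    """Per-track migration statistics from a (track_id, frame, x, y) table."""
    rows = []
    for tid, sub in tracks.sort_values("frame").groupby("track_id"):
        if len(sub) < min_length:
            continue
        ms = migration_stats(sub[["x", "y"]].to_numpy(),
                             pixel_size=pixel_size,
                             frame_interval=frame_interval,
                             distant_threshold=distant_threshold,
                             distant_mode=distant_mode,
                             track_id=int(tid))
        rows.append(ms.as_dict())
    return pd.DataFrame(rows)


def group_compare(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
                  properties: tuple[str, ...] = (
                      "net_displacement", "meandering_index", "mean_speed"),
                  labels: tuple[str, str] = ("group_a", "group_b")
                  ) -> pd.DataFrame:
    """Independent-samples t-test per migration property.

    Returns one row per property with group means ± SD, the t statistic
    and two-sided p value.  Groups of fewer than two samples are
    rejected; a comparison where both groups have zero variance is
    reported with NaN p and flagged.
    """
    rows = []
    for prop in properties:
        a = np.asarray(stats_a[prop], dtype=float)
        b = np.asarray(stats_b[prop], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 samples per group")
        degenerate = a.std() == 0 and b.std() == 0
        if degenerate and np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        elif degenerate:
            t, p = float("nan"), float("nan")
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append({
            "property": prop,
            f"mean_{labels[0]}": float(a.mean()),
            f"sd_{labels[0]}": float(a.std(ddof=1)),
            f"mean_{labels[1]}": float(b.mean()),
            f"sd_{labels[1]}": float(b.std(ddof=1)),
            "t": float(t), "p": float(p),
            "degenerate": bool(degenerate),
        })
    return pd.DataFrame(rows)
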