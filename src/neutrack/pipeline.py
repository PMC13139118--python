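"""End-to-end pipeline: simulate/load -> preprocess -> segment -> score ->
link -> evaluate -> measure, with YAML configuration and a JSON
provenance record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import evaluate_tracking
from .io import (gt_tracks_to_frame, read_stack, tracking_result_to_frame,
                 write_score_matrices, write_stack, write_tracks_csv)
from .linkage import LinkageParams, link
from .migration import stats_for_tracks
from .preprocess import preprocess_sequence
from .scoring import score_sequence
from .segment import SegParams, segment_sequence
from .simulate import SimConfig, simulate_sequence

__all__ = ["RunConfig", "run_pipeline", "render_overlay"]


@dataclass
class RunConfig:
    """Serialisable configuration of a full pipeline run."""

    out_dir: str = "run"
    frames_path: str | None = None  # if None, simulate
    sim: SimConfig = field(default_factory=SimConfig)
    # preprocessing
    contrast: tuple[float, float] = (1.0, 99.8)
    median_radius: int = 1
    gaussian_sigma: float = 1.0
    preprocess: bool = False  # synthetic frames are already clean
    # segmentation
    seg: SegParams = field(default_factory=SegParams)
    # scoring
    search_radius: int = 10
    normalization: str = "pred"
    # linkage
    method: str = "viterbi-ext"
    linkage: LinkageParams = field(default_factory=LinkageParams)
    # evaluation
    match_radius: float = 10.0
    # migration
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    distant_threshold: float = 2.4
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            for key in ("image_size", "cell_radius_range"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            if "scripted_events" in sim:
                from .simulate import Event
                sim["scripted_events"] = tuple(
                    Event(e["kind"], e["frame"], tuple(e["track_ids"]))
                    for e in sim["scripted_events"])
            d["sim"] = SimConfig(**sim)
        if "seg" in d and isinstance(d["seg"], dict):
            d["seg"] = SegParams(**d["seg"])
        if "linkage" in d and isinstance(d["linkage"], dict):
            d["linkage"] = LinkageParams(**d["linkage"])
        if "contrast" in d and d["contrast"] is not None:
            d["contrast"] = tuple(d["contrast"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline, writing all artifacts under ``out_dir``.

    Returns the provenance record (also written as provenance.json).
    Stage failures are re-raised with the stage name; artifacts of
    completed stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"config_hash": _config_hash(config),
                        "version": __version__, "stages": {}}
    config.to_yaml(out / "config.yaml")

    stage = "input"
    try:
        gt_frame = None
        if config.frames_path:
            frames = read_stack(config.frames_path)
        else:
            sim = simulate_sequence(config.sim)
            frames = sim.frames
            gt_frame = gt_tracks_to_frame(sim.gt_tracks)
            write_stack(out / "frames.tif", frames, dtype=np.float32)
            write_stack(out / "gt_masks.tif", sim.gt_masks, dtype=np.int32)
            write_tracks_csv(out / "gt_tracks.csv", gt_frame)
        provenance["stages"]["input"] = {"n_frames": len(frames)}

        stage = "preprocess"
        if config.preprocess:
            frames = preprocess_sequence(
                frames, low_pct=config.contrast[0],
                high_pct=config.contrast[1],
                median_radius=config.median_radius,
                gaussian_sigma=config.gaussian_sigma)
            write_stack(out / "preprocessed.tif", frames, dtype=np.float32)
        provenance["stages"]["preprocess"] = {"applied": config.preprocess}

        stage = "segment"
        masks = segment_sequence(frames, config.seg)
        write_stack(out / "masks.tif", masks, dtype=np.int32)
        provenance["stages"]["segment"] = {
            "n_cells_per_frame": [int(m.max()) for m in masks]}

        stage = "score"
        matrices = score_sequence(masks, search_radius=config.search_radius,
                                  normalize=config.normalization)
        write_score_matrices(out / "scores", matrices)
        provenance["stages"]["score"] = {"n_matrices": len(matrices)}

        stage = "link"
        result = link(matrices, method=config.method, params=config.linkage)
        tracks = tracking_result_to_frame(result, masks)
        write_tracks_csv(out / "tracks.csv", tracks)
        provenance["stages"]["link"] = {
            "method": config.method,
            "n_trajectories": len(result.trajectories)}

        stage = "evaluate"
        if gt_frame is not None:
            report = evaluate_tracking(tracks, gt_frame,
                                       radius=config.match_radius,
                                       n_frames=len(frames))
            metrics = report.as_dict()
            pd.DataFrame([metrics]).to_csv(out / "metrics.csv", index=False)
            provenance["stages"]["evaluate"] = metrics

        stage = "measure"
        mstats = stats_for_tracks(tracks.dropna(subset=["x", "y"]),
                                  pixel_size=config.pixel_size,
                                  frame_interval=config.frame_interval,
                                  distant_threshold=config.distant_threshold)
        mstats.to_csv(out / "migration.csv", index=False)
        provenance["stages"]["measure"] = {"n_tracks": len(mstats)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return provenance


# ---------------------------------------------------------------------------
# visualisation
# ---------------------------------------------------------------------------

_PALETTE = np.array([
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207),
], dtype=np.uint8)


def _track_color(track_id: int) -> np.ndarray:
    return _PALETTE[int(track_id) % len(_PALETTE)]


def render_overlay(frames, tracks: pd.DataFrame, out_dir=None
                   ) -> list[np.ndarray]:
    """Per-frame RGB images with coloured polyline trails per track.

    Colours are keyed deterministically by track id.  When ``out_dir`` is
    given the images are also written as PNGs.
    """
    from skimage.draw import line as draw_line

    images = []
    tracks = tracks.dropna(subset=["x", "y"])
    by_track = {tid: sub.sort_values("frame")
                for tid, sub in tracks.groupby("track_id")}
    for f, frame in enumerate(frames):
        frame = np.asarray(frame, dtype=float)
        lo, hi = frame.min(), frame.max()
        gray = ((frame - lo) / (hi - lo) * 255.0 if hi > lo
                else np.zeros_like(frame)).astype(np.uint8)
        rgb = np.stack([gray] * 3, axis=-1)
        h, w = gray.shape
        for tid, sub in by_track.items():
            past = sub[sub["frame"] <= f]
            if len(past) < 2:
                continue
            color = _track_color(tid)
            xs = past["x"].to_numpy()
            ys = past["y"].to_numpy()
            for k in range(1, len(past)):
                rr, cc = draw_line(int(round(ys[k - 1])),
                                   int(round(xs[k - 1])),
                                   int(round(ys[k])), int(round(xs[k])))
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                rgb[rr[keep], cc[keep]] = color
        images.append(rgb)
    if out_dir is not None:
        import imageio.v3 as iio
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for f, img in enumerate(images):
            iio.imwrite(out_dir / f"overlay_{f:04d}.png", img)
    return images
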