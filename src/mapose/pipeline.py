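"""End-to-end pipeline: decode -> assemble -> track -> stitch -> evaluate.

Glues the stages together for synthetic scenes (the built-in generator) or
for externally supplied detection tables. Every stage's output can be
persisted; a run is fully determined by (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .assembly import Assembly, PosePrior, assemble_frame
from .config import PipelineConfig
from .decoding import KeypointDetection, build_affinity_tables, decode_frame
from .metrics import MOTReport, mot_evaluate
from .stitching import Track, StitchReport, stitch_tracklets
from .synthdata import (
    GroundTruthScene,
    SceneConfig,
    corrupt_detections,
    generate_scene,
    render_targets,
)
from .tracking import Tracklet, track_video

logger = logging.getLogger("mapose")


@dataclass
class PipelineResult:
    scene: GroundTruthScene | None
    frames: list[tuple[list[Assembly], list[KeypointDetection]]]
    tracklets: list[Tracklet]
    tracks: list[Track]
    stitch_report: StitchReport
    mot: MOTReport | None
    frame_labels: list[list[int]] = field(default_factory=list)


def detections_from_table(
    df: pd.DataFrame, frame: int
) -> tuple[list[KeypointDetection], list[int], np.ndarray | None]:
    """Detections, hidden gt labels and identity probabilities for a frame."""
    sub = df[df["frame"] == frame]
    id_cols = mio.identity_columns(df)
    dets, labels = [], []
    probs = [] if id_cols else None
    for _, row in sub.iterrows():
        part = row["bodypart"]
        part = int(part) if str(part).lstrip("-").isdigit() else part
        dets.append(
            KeypointDetection(
                part, float(row["x"]), float(row["y"]), float(row["confidence"]), (-1, -1)
            )
        )
        labels.append(int(row["gt_animal"]) if "gt_animal" in row else -1)
        if probs is not None:
            probs.append(row[id_cols].to_numpy(dtype=float))
    return dets, labels, (np.array(probs) if probs else None)


def simulate_detection_stream(
    scene: GroundTruthScene,
    config: PipelineConfig,
    detections_df: pd.DataFrame | None = None,
):
    """Yield (frame, detections, labels, affinity_tables) for a scene.

    Detections come from the noisy detection tables; affinity costs are read
    from part-affinity fields rendered at the ground-truth limb positions,
    so clutter gains little PAF support while jittered true detections keep
    theirs.
    """
    scfg = scene.config
    if detections_df is None:
        detections_df = corrupt_detections(scene)
    for t in range(scene.n_frames):
        dets, labels, _ = detections_from_table(detections_df, t)
        targets = render_targets(
            scene.coords[t], scfg, visible=scene.visible[t]
        )
        tables = build_affinity_tables(
            dets,
            targets.pafs,
            scfg.skeleton,
            scfg.stride,
            n_samples=config.n_samples,
            cost=config.paf_cost,
            lookup=config.paf_lookup,
        )
        yield t, dets, labels, tables


def assemble_video(
    stream,
    graph: Sequence[tuple[int, int]],
    config: PipelineConfig,
    prior: PosePrior | None = None,
) -> tuple[list[tuple[list[Assembly], list[KeypointDetection]]], list[list[int]]]:
    """Run frame assembly over a detection stream."""
    frames, frame_labels = [], []
    for _, dets, labels, tables in stream:
        assemblies, _ = assemble_frame(
            dets,
            tables,
            graph,
            paf_threshold=config.paf_threshold,
            prior=prior,
        )
        frames.append((assemblies, dets))
        frame_labels.append(labels)
    return frames, frame_labels


def gt_centroid_tracks(scene: GroundTruthScene) -> dict[int, dict[int, np.ndarray]]:
    """Ground-truth tracks (visible frames only) for CLEAR-MOT."""
    out: dict[int, dict[int, np.ndarray]] = {a: {} for a in range(scene.n_animals)}
    for t in range(scene.n_frames):
        for a in range(scene.n_animals):
            vis = scene.visible[t, a]
            if vis.any():
                out[a][t] = scene.coords[t, a][vis].mean(axis=0)
    return {a: tr for a, tr in out.items() if tr}


def hypothesis_tracks(
    items: Sequence[Track] | Sequence[Tracklet],
) -> dict[int, dict[int, np.ndarray]]:
    out: dict[int, dict[int, np.ndarray]] = {}
    for item in items:
        if isinstance(item, Track):
            obs = {f: item.observation_at(f) for f in item.frames}
        else:
            obs = item.observations
        out[item.id] = {f: o.centroid() for f, o in obs.items()}
    return {i: tr for i, tr in out.items() if tr}


def default_match_threshold(scene: GroundTruthScene) -> float:
    """Half the mean animal bounding-box diagonal of the scene."""
    diags = []
    for t in range(scene.n_frames):
        for a in range(scene.n_animals):
            vis = scene.visible[t, a]
            if vis.sum() >= 2:
                pts = scene.coords[t, a][vis]
                extent = pts.max(axis=0) - pts.min(axis=0)
                diags.append(float(np.hypot(*extent)))
    return 0.5 * float(np.mean(diags)) if diags else 20.0


def run_pipeline(
    config: PipelineConfig,
    scene_config: SceneConfig,
    method: str = "ellipse",
    tracking_max_gap: int | None = None,
    embeddings: Mapping[int, np.ndarray] | None = None,
    outdir: str | Path | None = None,
    evaluate: bool = True,
) -> PipelineResult:
    """Full synthetic run: simulate, assemble, track, stitch, evaluate."""
    logger.info("pipeline start | config %s | scene seed %d", config.config_hash(), scene_config.seed)
    scene = generate_scene(scene_config)
    det_df = corrupt_detections(scene)
    stream = simulate_detection_stream(scene, config, det_df)
    frames, frame_labels = assemble_video(stream, scene_config.skeleton, config)
    n_assemblies = sum(len(f[0]) for f in frames)
    logger.info("assembly | %d assemblies over %d frames", n_assemblies, len(frames))
    tracklets = track_video(
        frames,
        method=method,
        min_hits=config.min_hits,
        max_age=config.max_age,
        iou_threshold=config.iou_threshold,
        box_margin=config.box_margin,
    )
    logger.info("tracking | %d tracklets", len(tracklets))
    k = config.n_animals if config.n_animals > 1 else scene_config.n_animals
    tracks, report = stitch_tracklets(
        tracklets,
        k,
        min_length=config.residual_min_length,
        max_gap=tracking_max_gap if tracking_max_gap is not None else config.max_gap,
        affinity_weights=config.affinity_weights,
        embeddings=embeddings,
        appearance_strength=config.appearance_strength,
    )
    logger.info("stitching | %d tracks, %d edges", len(tracks), len(report.edges_used))
    mot = None
    if evaluate:
        mot = mot_evaluate(
            hypothesis_tracks(tracks),
            gt_centroid_tracks(scene),
            default_match_threshold(scene),
        )
        logger.info("evaluation | MOTA %.3f", mot.mota)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_detections(det_df, outdir / "detections.csv")
        mio.write_tracks(tracklets, outdir / "tracklets.csv", outdir / "tracklets.json")
        mio.write_tracks(tracks, outdir / "tracks.csv", outdir / "tracks.json")
        mio.write_coco(scene, outdir / "ground_truth.json")
        config.to_yaml(str(outdir / "config.yaml"))
    return PipelineResult(scene, frames, tracklets, tracks, report, mot, frame_labels)
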