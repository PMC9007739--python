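"""Readers and writers for the pipeline's interchange formats.

* Detection tables: one tabular file per video with columns
  (frame, bodypart, x, y, confidence[, gt_animal][, id_prob_0..id_prob_n-1]),
  comma-separated with a header row; an HDF5 container with the same schema
  is available behind the same functions (chosen by file extension .h5).
* Tracklet / track tables: (track_id, frame, bodypart, x, y, confidence)
  plus a JSON manifest of track spans.
* Ground truth: COCO-keypoints JSON (images, annotations with flattened
  [x, y, v] keypoint triplets, v=2 visible / v=0 absent).
* Target tensors: HDF5 datasets "scoremaps" (H, W, K), "locref"
  (H, W, K, 2) and "pafs" (H, W, 2L) with a "stride" attribute; PAF channel
  pair (2l, 2l+1) belongs to skeleton edge l, channel order follows
  bodypart order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .stitching import Track
from .synthdata import DETECTION_COLUMNS, GroundTruthScene, TargetTensors
from .tracking import Tracklet, TrackletObservation


class FormatError(ValueError):
    """A file does not conform to its documented schema."""


# ---------------------------------------------------------------------------
# Detection tables
# ---------------------------------------------------------------------------


def write_detections(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".h5":
        df.to_hdf(path, key="detections", mode="w", format="table")
    else:
        df.to_csv(path, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".h5":
        df = pd.read_hdf(path, key="detections")
    else:
        df = pd.read_csv(path)
    required = [c for c in DETECTION_COLUMNS if c != "gt_animal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing detection columns {missing}")
    for col in ("frame", "x", "y", "confidence"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise FormatError(
                f"{path}: malformed value in column {col!r} at row {int(bad[0])}"
            )
    df["frame"] = df["frame"].astype(int)
    return df


def identity_columns(df: pd.DataFrame) -> list[str]:
    return sorted(
        (c for c in df.columns if c.startswith("id_prob_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )


# ---------------------------------------------------------------------------
# Tracklet / track tables
# ---------------------------------------------------------------------------


def tracks_to_table(items: Sequence[Tracklet] | Sequence[Track]) -> pd.DataFrame:
    rows = []
    for item in items:
        if isinstance(item, Track):
            frames = {f: item.observation_at(f) for f in item.frames}
        else:
            frames = item.observations
        for f in sorted(frames):
            obs = frames[f]
            for part, xy in obs.keypoints.items():
                rows.append(
                    (item.id, f, part, xy[0], xy[1], obs.confidences.get(part, 1.0))
                )
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "bodypart", "x", "y", "confidence"]
    )


def write_tracks(
    items: Sequence[Tracklet] | Sequence[Track],
    path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    tracks_to_table(items).to_csv(path, index=False)
    if manifest_path is not None:
        manifest = []
        for item in items:
            frames = item.frames
            manifest.append(
                {
                    "id": int(item.id),
                    "start": int(min(frames)) if frames else None,
                    "end": int(max(frames)) if frames else None,
                    "n_frames": len(frames),
                }
            )
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))


def read_tracklets(path: str | Path) -> list[Tracklet]:
    df = pd.read_csv(path)
    required = ["track_id", "frame", "bodypart", "x", "y", "confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing track columns {missing}")
    tracklets: dict[int, Tracklet] = {}
    for (tid, frame), grp in df.groupby(["track_id", "frame"], sort=True):
        tr = tracklets.setdefault(int(tid), Tracklet(int(tid)))
        kps = {}
        confs = {}
        for _, row in grp.iterrows():
            part = row["bodypart"]
            part = int(part) if str(part).lstrip("-").isdigit() else part
            kps[part] = np.array([float(row["x"]), float(row["y"])])
            confs[part] = float(row["confidence"])
        tr.observations[int(frame)] = TrackletObservation(
            kps, confs, float(np.mean(list(confs.values())))
        )
    return [tracklets[k] for k in sorted(tracklets)]


# ---------------------------------------------------------------------------
# COCO keypoints JSON
# ---------------------------------------------------------------------------


def scene_to_coco(
    scene: GroundTruthScene, bodypart_names: Sequence[str] | None = None
) -> dict:
    names = (
        list(bodypart_names)
        if bodypart_names
        else [f"bodypart{k}" for k in range(scene.n_bodyparts)]
    )
    h, w = scene.config.image_size
    images, annotations = [], []
    ann_id = 1
    for t in range(scene.n_frames):
        images.append({"id": t, "width": w, "height": h, "file_name": f"frame{t:06d}.png"})
        for a in range(scene.n_animals):
            kps = []
            n_vis = 0
            for k in range(scene.n_bodyparts):
                x, y = scene.coords[t, a, k]
                v = 2 if scene.visible[t, a, k] else 0
                n_vis += v > 0
                kps.extend([float(x), float(y), int(v)])
            if n_vis == 0:
                continue
            pts = scene.coords[t, a][scene.visible[t, a]]
            x0, y0 = pts.min(axis=0)
            x1, y1 = pts.max(axis=0)
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": t,
                    "category_id": 1,
                    "keypoints": kps,
                    "num_keypoints": int(n_vis),
                    "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                    "area": float((x1 - x0) * (y1 - y0)),
                    "iscrowd": 0,
                    "individual": scene.identities[a],
                }
            )
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": 1, "name": "animal", "keypoints": names, "skeleton": [
                [i + 1, j + 1] for i, j in scene.config.skeleton
            ]}
        ],
    }


def write_coco(scene: GroundTruthScene, path: str | Path, **kwargs) -> None:
    Path(path).write_text(json.dumps(scene_to_coco(scene, **kwargs), indent=2))


def read_coco(path: str | Path) -> dict[int, list[dict[int, np.ndarray]]]:
    """Per-frame ground-truth animals: frame -> list of {bodypart: (x, y)}.

    Keypoints with visibility flag 0 are read as absent.
    """
    data = json.loads(Path(path).read_text())
    frames: dict[int, list[dict[int, np.ndarray]]] = {}
    for ann in data.get("annotations", []):
        kps = ann["keypoints"]
        if len(kps) % 3:
            raise FormatError(f"{path}: annotation {ann.get('id')}: keypoints not triplets")
        animal = {}
        for k in range(len(kps) // 3):
            x, y, v = kps[3 * k : 3 * k + 3]
            if v > 0:
                animal[k] = np.array([float(x), float(y)])
        frames.setdefault(int(ann["image_id"]), []).append(animal)
    return frames


# ---------------------------------------------------------------------------
# Target tensors (HDF5)
# ---------------------------------------------------------------------------


def write_targets(targets: TargetTensors, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("scoremaps", data=targets.score_maps)
        fh.create_dataset("locref", data=targets.locref)
        fh.create_dataset("pafs", data=targets.pafs)
        fh.attrs["stride"] = targets.stride


def read_targets(path: str | Path) -> TargetTensors:
    with h5py.File(path, "r") as fh:
        for name in ("scoremaps", "locref", "pafs"):
            if name not in fh:
                raise FormatError(f"{path}: missing dataset {name!r}")
        return TargetTensors(
            fh["scoremaps"][()],
            fh["locref"][()],
            fh["pafs"][()],
            int(fh.attrs["stride"]),
        )


# ---------------------------------------------------------------------------
# Graph and embedding sidecars
# ---------------------------------------------------------------------------


def write_graph(edges, path: str | Path, discriminability=None) -> None:
    lines = []
    for e in edges:
        if discriminability and tuple(e) in discriminability:
            lines.append(f"{e[0]}\t{e[1]}\t{discriminability[tuple(e)]:.6f}")
        else:
            lines.append(f"{e[0]}\t{e[1]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_graph(path: str | Path) -> list[tuple[int, int]]:
    edges = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: malformed edge at line {ln}")
        edges.append((int(parts[0]), int(parts[1])))
    return edges


def write_embeddings(embeddings: Mapping[int, np.ndarray], path: str | Path) -> None:
    rows = [
        [int(tid), *np.asarray(vec, dtype=float).tolist()]
        for tid, vec in sorted(embeddings.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, header=False)


def read_embeddings(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path, header=None)
    return {
        int(row.iloc[0]): row.iloc[1:].to_numpy(dtype=float)
        for _, row in df.iterrows()
    }
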