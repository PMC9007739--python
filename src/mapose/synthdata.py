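"""Synthetic multi-animal scenes and training-target tensors.

The generator emulates several animals with a shared body plan moving through
an arena: per-animal rigid translation with a randomly turning heading, small
per-keypoint articulation noise, whole-animal occlusion events, entries and
exits at the arena walls. From the ground-truth keypoints it renders the
target tensors a bottom-up pose network is trained on — binary score maps,
location-refinement offset fields and part-affinity fields — and produces
noisy per-frame detection tables (jitter, dropout, clutter) whose hidden
ground-truth animal labels drive the evaluation metrics.

Coordinate convention: 0-based pixel indices, x rightward, y downward,
keypoints are continuous subpixel positions. Map cell (p, q) — p the column
index, q the row index — corresponds to the full-image point
(p * stride + stride / 2, q * stride + stride / 2), which makes decoding the
exact inverse of rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import validate_skeleton

DETECTION_COLUMNS = ["frame", "bodypart", "x", "y", "confidence", "gt_animal"]


@dataclass
class SceneConfig:
    """Parameters of a synthetic multi-animal scene.

    Geometry is in full-image pixels; the rendering grid has shape
    (H // stride, W // stride), so ``stride`` must divide both image sides.
    """

    n_animals: int = 3
    n_bodyparts: int = 5
    skeleton: list[tuple[int, int]] = field(default_factory=list)
    image_size: tuple[int, int] = (512, 512)  # (H, W)
    n_frames: int = 100
    stride: int = 4
    target_radius: float = 5.0
    pafwidth: float = 8.0
    # motion model
    speed: float = 3.0  # px / frame
    turn_sd: float = 0.3  # rad / frame
    body_scale: float = 24.0  # spread of the body plan, px
    articulation_sd: float = 0.0  # per-keypoint wobble, px
    elongation: float = 1.0  # >1 stretches the body plan along the heading
    # occlusion model
    occlusion_rate: float = 0.01  # events / animal / frame
    occlusion_duration: int = 5  # frames
    # detection noise
    jitter_sd: float = 1.0  # px
    dropout: float = 0.05  # probability a true keypoint is missed
    clutter_rate: float = 0.5  # spurious detections / frame (Poisson)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.n_bodyparts < 1 or self.n_frames < 1:
            raise ValueError("n_animals, n_bodyparts and n_frames must be >= 1")
        h, w = self.image_size
        if h % self.stride or w % self.stride:
            raise ValueError("stride must divide both image dimensions")
        for p in (self.dropout, self.occlusion_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.skeleton:
            # chain plus skip connections: redundant enough that a single
            # dropped keypoint does not split the animal in two
            self.skeleton = [(i, i + 1) for i in range(self.n_bodyparts - 1)]
            self.skeleton += [(i, i + 2) for i in range(self.n_bodyparts - 2)]
        self.skeleton = validate_skeleton(self.skeleton, self.n_bodyparts)

    @property
    def grid_shape(self) -> tuple[int, int]:
        h, w = self.image_size
        return h // self.stride, w // self.stride


@dataclass
class GroundTruthScene:
    """Ground-truth trajectories: coords[t, a, k] = (x, y), visibility mask."""

    coords: np.ndarray  # (T, A, K, 2) float
    visible: np.ndarray  # (T, A, K) bool
    identities: list[str]
    config: SceneConfig

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_animals(self) -> int:
        return self.coords.shape[1]

    @property
    def n_bodyparts(self) -> int:
        return self.coords.shape[2]

    def centroids(self) -> np.ndarray:
        """(T, A, 2) centroid of visible keypoints (NaN when fully hidden)."""
        masked = np.where(self.visible[..., None], self.coords, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(masked, axis=2)


@dataclass
class TargetTensors:
    """Rendered training targets for one frame.

    score_maps : (Hg, Wg, K) binary
    locref     : (Hg, Wg, K, 2) full-image px offsets (x, y), defined where
                 the score map is 1
    pafs       : (Hg, Wg, 2L) unit-vector components, channel pair
                 (2l, 2l + 1) holding (x, y) for skeleton edge l
    """

    score_maps: np.ndarray
    locref: np.ndarray
    pafs: np.ndarray
    stride: int


def _body_plan(rng: np.random.Generator, cfg: SceneConfig) -> np.ndarray:
    """Fixed keypoint offsets shared by all animals (one body plan)."""
    k = cfg.n_bodyparts
    angles = np.linspace(0.0, 2 * np.pi, k, endpoint=False)
    radii = cfg.body_scale * (0.4 + 0.6 * rng.random(k))
    plan = np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)
    plan -= plan.mean(axis=0)
    plan[:, 0] *= cfg.elongation  # stretch along local x (the heading)
    return plan


def generate_scene(config: SceneConfig) -> GroundTruthScene:
    """Simulate animal trajectories; pure function of (config, seed).

    Each animal translates with constant speed and a heading following a
    wrapped Gaussian random walk, reflecting off the arena walls. All animals
    share one rigid body plan, rotated to the heading, plus optional
    per-frame articulation noise. Occlusion events hide all keypoints of an
    animal for ``occlusion_duration`` frames.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    a, k, t = config.n_animals, config.n_bodyparts, config.n_frames
    plan = _body_plan(rng, config)
    margin = float(np.abs(plan).max()) + 1.0
    lo = np.array([margin, margin])
    hi = np.array([w - 1 - margin, h - 1 - margin])
    if np.any(hi <= lo):
        raise ValueError("image too small for the configured body scale")

    centers = lo + rng.random((a, 2)) * (hi - lo)
    headings = rng.uniform(-np.pi, np.pi, size=a)
    coords = np.empty((t, a, k, 2))
    visible = np.ones((t, a, k), dtype=bool)
    occluded_until = np.full(a, -1)

    for frame in range(t):
        for ai in range(a):
            rot = np.array(
                [
                    [np.cos(headings[ai]), -np.sin(headings[ai])],
                    [np.sin(headings[ai]), np.cos(headings[ai])],
                ]
            )
            pts = centers[ai] + plan @ rot.T
            if config.articulation_sd > 0:
                pts = pts + rng.normal(0.0, config.articulation_sd, size=(k, 2))
            coords[frame, ai] = np.clip(pts, [0, 0], [w - 1, h - 1])
            # occlusion bookkeeping
            if frame <= occluded_until[ai]:
                visible[frame, ai] = False
            elif rng.random() < config.occlusion_rate:
                visible[frame, ai] = False
                occluded_until[ai] = frame + config.occlusion_duration - 1
        # advance motion
        if config.speed > 0:
            step = config.speed * np.stack(
                [np.cos(headings), np.sin(headings)], axis=1
            )
            centers = centers + step
            # reflect at walls
            for dim in range(2):
                low, high = lo[dim], hi[dim]
                over = centers[:, dim] > high
                under = centers[:, dim] < low
                centers[over, dim] = 2 * high - centers[over, dim]
                centers[under, dim] = 2 * low - centers[under, dim]
                flip = over | under
                if dim == 0:
                    headings[flip] = np.pi - headings[flip]
                else:
                    headings[flip] = -headings[flip]
            headings = headings + rng.normal(0.0, config.turn_sd, size=a)
            headings = np.mod(headings + np.pi, 2 * np.pi) - np.pi

    identities = [f"animal{ai}" for ai in range(a)]
    return GroundTruthScene(coords, visible, identities, config)


def _grid_centers(grid_shape: tuple[int, int], stride: int) -> tuple[np.ndarray, np.ndarray]:
    hg, wg = grid_shape
    cx = np.arange(wg) * stride + stride / 2.0  # per column p
    cy = np.arange(hg) * stride + stride / 2.0  # per row q
    return np.meshgrid(cx, cy)  # each (Hg, Wg)


def render_targets(
    frame_coords: np.ndarray,
    config: SceneConfig,
    visible: np.ndarray | None = None,
) -> TargetTensors:
    """Render score maps, location-refinement fields and PAFs for one frame.

    Parameters
    ----------
    frame_coords : (A, K, 2) subpixel keypoint positions.
    visible : (A, K) bool, hidden keypoints are not rendered.

    The score map of bodypart k is 1 exactly on grid cells whose full-image
    centre lies strictly within ``target_radius`` of a keypoint; the locref
    field stores the (x, y) offset from the cell centre to the nearest such
    keypoint; PAF cells whose centre lies within ``pafwidth`` of a limb
    segment hold the limb's unit direction vector (nearest limb instance
    wins where animals overlap).
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    a, k = frame_coords.shape[:2]
    if visible is None:
        visible = np.ones((a, k), dtype=bool)
    h, w = config.image_size
    hg, wg = config.grid_shape
    gx, gy = _grid_centers((hg, wg), config.stride)

    score = np.zeros((hg, wg, k), dtype=np.uint8)
    locref = np.zeros((hg, wg, k, 2))
    best_d2 = np.full((hg, wg, k), np.inf)

    in_image = (
        (frame_coords[..., 0] >= 0)
        & (frame_coords[..., 0] <= w - 1)
        & (frame_coords[..., 1] >= 0)
        & (frame_coords[..., 1] <= h - 1)
    )
    if np.any(visible & ~in_image):
        warnings.warn("keypoints outside the image were excluded from rendering")

    for ai in range(a):
        for ki in range(k):
            if not (visible[ai, ki] and in_image[ai, ki]):
                continue
            x, y = frame_coords[ai, ki]
            d2 = (gx - x) ** 2 + (gy - y) ** 2
            inside = d2 < config.target_radius**2
            score[inside, ki] = 1
            closer = inside & (d2 < best_d2[..., ki])
            best_d2[closer, ki] = d2[closer]
            locref[closer, ki, 0] = x - gx[closer]
            locref[closer, ki, 1] = y - gy[closer]

    n_limbs = len(config.skeleton)
    pafs = np.zeros((hg, wg, 2 * n_limbs))
    limb_best = np.full((hg, wg, n_limbs), np.inf)
    for li, (i, j) in enumerate(config.skeleton):
        for ai in range(a):
            if not (visible[ai, i] and in_image[ai, i]):
                continue
            if not (visible[ai, j] and in_image[ai, j]):
                continue
            p1, p2 = frame_coords[ai, i], frame_coords[ai, j]
            seg = p2 - p1
            length = np.hypot(*seg)
            if length < 1e-12:
                continue
            u = seg / length
            rel_x, rel_y = gx - p1[0], gy - p1[1]
            along = rel_x * u[0] + rel_y * u[1]
            perp = np.abs(rel_x * u[1] - rel_y * u[0])
            band = (along >= 0) & (along <= length) & (perp <= config.pafwidth)
            closer = band & (perp < limb_best[..., li])
            limb_best[closer, li] = perp[closer]
            pafs[closer, 2 * li] = u[0]
            pafs[closer, 2 * li + 1] = u[1]

    return TargetTensors(score, locref, pafs, config.stride)


def corrupt_detections(
    scene: GroundTruthScene,
    config: SceneConfig | None = None,
    bodypart_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Derive noisy per-frame detection tables from the ground truth.

    Visible keypoints receive Gaussian jitter and are dropped with
    probability ``dropout``; clutter detections (Poisson count per frame,
    uniform position, random bodypart, confidence ~ U(0.1, 0.6)) are
    injected with hidden label ``gt_animal = -1``. True detections keep
    their ground-truth animal index as a hidden evaluation label.
    """
    config = config or scene.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD37EC7]))
    h, w = config.image_size
    names = list(bodypart_names) if bodypart_names else list(range(scene.n_bodyparts))
    rows: list[tuple] = []
    for t in range(scene.n_frames):
        for ai in range(scene.n_animals):
            for ki in range(scene.n_bodyparts):
                if not scene.visible[t, ai, ki]:
                    continue
                if config.dropout > 0 and rng.random() < config.dropout:
                    continue
                x, y = scene.coords[t, ai, ki]
                if config.jitter_sd > 0:
                    x += rng.normal(0.0, config.jitter_sd)
                    y += rng.normal(0.0, config.jitter_sd)
                rows.append((t, names[ki], x, y, 1.0, ai))
        n_clutter = rng.poisson(config.clutter_rate) if config.clutter_rate > 0 else 0
        for _ in range(n_clutter):
            rows.append(
                (
                    t,
                    names[rng.integers(scene.n_bodyparts)],
                    rng.uniform(0, w - 1),
                    rng.uniform(0, h - 1),
                    rng.uniform(0.1, 0.6),
                    -1,
                )
            )
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def sample_crop_centers(
    keypoints: np.ndarray,
    image_size: tuple[int, int],
    n: int,
    crop_size: float,
    seed: int | np.random.Generator = 0,
    strategy: str | None = None,
) -> np.ndarray:
    """Sample keypoint-aware crop centres.

    Each centre is drawn by one of two strategies chosen uniformly at random
    (or forced via ``strategy``): "uniform" over the whole image, or
    "density", picking a labelled keypoint with probability proportional to
    1 + its number of neighbours within a radius of 10% of the smallest
    image side. Centres are then shifted along both axes by random amounts
    no greater than 40% of the crop size. With no keypoints the density
    strategy falls back to uniform sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    h, w = image_size
    keypoints = np.asarray(keypoints, dtype=float).reshape(-1, 2)
    radius = 0.1 * min(h, w)
    if len(keypoints):
        d = np.linalg.norm(keypoints[:, None] - keypoints[None, :], axis=-1)
        weights = 1.0 + ((d <= radius).sum(axis=1) - 1)  # exclude self
        weights = weights / weights.sum()
    else:
        weights = None

    centers = np.empty((n, 2))
    for idx in range(n):
        mode = strategy or ("uniform" if rng.random() < 0.5 else "density")
        if mode == "density" and weights is not None:
            centers[idx] = keypoints[rng.choice(len(keypoints), p=weights)]
        else:
            centers[idx] = [rng.uniform(0, w - 1), rng.uniform(0, h - 1)]
        centers[idx] += rng.uniform(-0.4, 0.4, size=2) * crop_size
    return centers
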