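"""Pipeline configuration: every named hyperparameter with its default.

The defaults collect the constants used throughout the pipeline: score-map
smoothing sigma, PAF sampling, assembly thresholds, tracker gating, residual
handling and evaluation settings. Unknown keys in a config file are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters.

    Attributes
    ----------
    sigma : float
        Gaussian spread for score-map smoothing before peak finding (cells).
    min_confidence : float
        Minimum smoothed score-map value for a peak to become a detection.
    nms_radius : int
        Half-width of the non-maximum-suppression window (cells).
    n_samples : int
        Number of equally spaced points (endpoints included) at which the
        part-affinity field is sampled along the segment joining two
        keypoint proposals.
    paf_cost : str
        "projection" scores the field projected on the segment direction
        (sign-discriminative); "norm" integrates the raw field magnitude.
    paf_lookup : str
        "nearest" reads the PAF at the nearest grid cell; "linear" uses
        bilinear interpolation.
    paf_threshold : float
        Minimum affinity cost for a connection to count as strong during
        per-edge optimal pairing.
    stride : int
        Overall stride (lambda) between image pixels and map cells.
    target_radius : float
        Radius r (full-image px) of the positive disk in target score maps.
    pafwidth : float
        Half-width (px) of the band around a limb that carries the limb's
        unit direction vector in the target PAF.
    gamma_t : float
        Decay of the temporal-coherence kernel over frame gaps.
    temporal_weight_mode : str
        "multiplicative" scales the affinity by (1 + weight); "replace"
        substitutes the weight for the cost.
    iou_threshold : float
        Minimum tracker/detection similarity for an association to be kept.
    min_hits : int
        Minimum number of matched frames a tracker must accumulate.
    max_age : int
        Maximum consecutive unmatched frames before a tracker is killed.
    box_margin : float
        Margin (px) added around keypoint bounding boxes.
    residual_min_length : int
        Tracklets shorter than this many frames are residuals and do not
        enter the stitching graph.
    max_gap : int | None
        Maximum temporal gap (frames) between stitchable tracklets; None
        derives it automatically as ceil(1.5 * tau).
    affinity_weights : dict
        Relative weight of each normalized affinity in the stitch cost.
    appearance_strength : float
        Strength s of the appearance down-weighting w * (1 - s * cos_sim).
    identity_weight : float
        Blend weight of identity soft votes in tracker association.
    n_animals : int
        Number of tracks k the stitcher must form.
    pck_fraction : float
        PCK threshold as a fraction of the reference limb length.
    oks_sd : float
        Per-keypoint standard deviation used in object keypoint similarity.
    seed : int
        Base seed for every stochastic component.
    """

    sigma: float = 1.0
    min_confidence: float = 0.01
    nms_radius: int = 2
    n_samples: int = 10
    paf_cost: str = "projection"
    paf_lookup: str = "nearest"
    paf_threshold: float = 0.1
    stride: int = 4
    target_radius: float = 5.0
    pafwidth: float = 8.0
    gamma_t: float = 0.01
    temporal_weight_mode: str = "multiplicative"
    iou_threshold: float = 0.6
    min_hits: int = 1
    max_age: int = 1
    box_margin: float = 0.0
    residual_min_length: int = 5
    max_gap: int | None = None
    affinity_weights: dict = field(
        default_factory=lambda: {
            "motion": 1.0,
            "proximity": 1.0,
            "shape": 1.0,
            "dynamics": 1.0,
        }
    )
    appearance_strength: float = 0.0
    identity_weight: float = 0.0
    n_animals: int = 1
    pck_fraction: float = 1.0 / 3.0
    oks_sd: float = 0.1
    seed: int = 0

    _DOMAINS = {
        "sigma": lambda v: v >= 0,
        "min_confidence": lambda v: 0 < v < 1,
        "nms_radius": lambda v: v >= 1,
        "n_samples": lambda v: v >= 2,
        "paf_cost": lambda v: v in ("projection", "norm"),
        "paf_lookup": lambda v: v in ("nearest", "linear"),
        "paf_threshold": lambda v: -1 <= v <= 1,
        "stride": lambda v: v in (2, 4, 8),
        "target_radius": lambda v: v > 0,
        "pafwidth": lambda v: v > 0,
        "gamma_t": lambda v: v >= 0,
        "temporal_weight_mode": lambda v: v in ("multiplicative", "replace"),
        "iou_threshold": lambda v: 0 <= v <= 1,
        "min_hits": lambda v: v >= 1,
        "max_age": lambda v: v >= 1,
        "box_margin": lambda v: v >= 0,
        "residual_min_length": lambda v: v >= 1,
        "max_gap": lambda v: v is None or v >= 1,
        "appearance_strength": lambda v: 0 <= v <= 1,
        "identity_weight": lambda v: 0 <= v <= 1,
        "n_animals": lambda v: v >= 1,
        "pck_fraction": lambda v: v > 0,
        "oks_sd": lambda v: v > 0,
        "seed": lambda v: v >= 0,
        "affinity_weights": lambda v: isinstance(v, Mapping)
        and all(w >= 0 for w in v.values()),
    }

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, ok in self._DOMAINS.items():
            value = getattr(self, name)
            if not ok(value):
                raise ValueError(f"config parameter {name!r} out of domain: {value!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the canonical serialized form, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_skeleton(
    skeleton: Sequence[tuple[int, int]], n_bodyparts: int
) -> list[tuple[int, int]]:
    """Check that every skeleton edge references a known bodypart index."""
    edges = []
    for a, b in skeleton:
        if not (0 <= a < n_bodyparts and 0 <= b < n_bodyparts) or a == b:
            raise ValueError(f"skeleton edge ({a}, {b}) references unknown bodypart")
        edges.append((int(a), int(b)))
    if len(set(map(frozenset, edges))) != len(edges):
        raise ValueError("duplicate skeleton edges")
    return edges
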