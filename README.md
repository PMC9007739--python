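# mapose

Bottom-up multi-animal pose assembly and tracking for laboratory video:
grouping keypoint detections into individuals with part-affinity fields
(PAFs), tracking them locally with Kalman-filtered box or ellipse trackers,
and stitching the resulting tracklets into full per-animal trajectories by
globally optimal min-cost network flow.

The package is aimed at behavioural researchers who already have per-frame
keypoint detections (or the score-map / location-refinement / PAF tensors a
bottom-up pose network emits) for several animals of the same body plan —
mice in an open field, pairs of marmosets, schooling fish — and need
identity-preserving trajectories despite occlusions, crossings and
detection noise. No neural network is included or required: a built-in
synthetic scene generator renders the same target tensors a network would
be trained on, so the entire pipeline is testable end to end without any
dataset.

## The method

**Decoding.** A score map `S^k` for bodypart `k` lives on a grid with
stride `λ`. After Gaussian smoothing (σ = 1) and max-pool non-maximum
suppression, each peak cell `(p*, q*)` becomes a subpixel detection

    x* = p*·λ + λ/2 + L_x^k(p*, q*),   y* = q*·λ + λ/2 + L_y^k(p*, q*)

where `L^k` is the location-refinement field. The cost of linking two
detections across a candidate limb is the PAF line integral: the field is
sampled at `n = 10` equally spaced points on the segment `γ` joining them,
projected on the segment direction and averaged (length-normalized), giving
a cost in [−1, 1] that is positive along true limbs and negative against
their orientation.

**Skeleton selection.** Rather than hand-drawing a skeleton, within- and
between-animal affinity-cost histograms (bin width 0.01) are accumulated on
labelled frames for every bodypart pair, ranked by auROC, and the maximum
spanning tree over auROC weights becomes the minimal data-driven graph; up
to nine progressively denser candidates are scored by assembly purity and
connected-keypoint fraction.

**Assembly.** Per edge, a one-to-one matching over affinity costs keeps
strong connections; their connected components seed individuals; remaining
connections are greedily linked in descending cost order under a
no-duplicate-bodypart rule, optionally gated by a Mahalanobis test against
a multivariate-Gaussian pose prior over all pairwise keypoint distances,
and optionally re-weighted by temporal coherence with recent frames,
`(1/j) Σ exp(−γ Δt ‖c − c_n‖²)`, γ = 0.01.

**Tracking.** SORT-style tracking-by-detection: each assembled animal is
summarized as a bounding box (`s = [x, y, A, r, ẋ, ẏ, Ȧ]`) or a 2σ
covariance error ellipse (`s = [x, y, h, w, θ, …]`) propagated by a
constant-velocity Kalman filter; Hungarian association uses IoU or the
ellipse similarity `c = 0.8(1−d) + 0.2(1−d)cos(θ_d − θ_p)` with a gate of
0.6, `min_hits = max_age = 1`.

**Stitching.** Tracklets ≥ 5 frames become nodes of a DAG (edges between
temporally disjoint tracklets separated by ≤ 1.5τ frames), each split into
unit-demand/unit-supply halves; edge weights combine motion extrapolation
error, tail-head proximity, Hausdorff shape distance, Hankel-rank dynamic
similarity and (optionally) appearance-embedding cosine similarity. A
min-cost flow of `k` units covers all tracklets with `k` node-disjoint
paths — the `k` animals — and short residual tracklets are greedily
reinserted into temporal gaps.

**Evaluation.** Keypoint RMSE, PCK, COCO-style OKS-mAP (thresholds
0.50–0.95, keypoint SD 0.1), assembly purity / unconnected fraction,
CLEAR-MOT (MOTA, misses, false positives, switches, fragments,
mostly-tracked), coordinate-crossing swap flagging, and a Proximity Index
quantifying animal crowding.

## Worked example

```python
from mapose import PipelineConfig, SceneConfig, run_pipeline

scene = SceneConfig(n_animals=3, n_bodyparts=5, n_frames=100,
                    image_size=(256, 256), body_scale=18,
                    occlusion_rate=0.02, occlusion_duration=5, seed=0)
result = run_pipeline(PipelineConfig(), scene, method="ellipse",
                      tracking_max_gap=10)
print(len(result.tracklets), "tracklets ->", len(result.tracks), "tracks")
print(f"MOTA {result.mot.mota:.3f}  misses {result.mot.misses}  "
      f"switches {result.mot.switches}")
```

Output:

```
23 tracklets -> 3 tracks
MOTA 0.993  misses 1  switches 0
```

Three animals, 100 frames, whole-animal occlusions of 5 frames at rate
0.02/frame, 1 px detection jitter, 5% keypoint dropout and Poisson clutter:
the local ellipse tracker fragments the video into 23 tracklets, the
stitcher reassembles them into exactly 3 identity-consistent tracks, and
CLEAR-MOT against the hidden ground truth scores MOTA 0.993 with no
identity switches (a raw ID-join of the 23 tracklets scores 20 switches on
the same scene).

The same stages are scriptable from the shell:

```bash
mapose simulate --n-animals 3 --n-frames 100 --seed 0 out/
mapose decode out/frame000000_targets.h5 out/detections_decoded.csv
mapose run --n-animals 3 --n-frames 100 --seed 0 out/run
mapose stitch -k 3 out/run/tracklets.csv out/run/stitched.csv
mapose evaluate out/run/stitched.csv out/run/ground_truth.json out/report.json
```

## Layout

| Module | Contents |
| --- | --- |
| `mapose.synthdata` | scene generator, target-tensor renderer, detection corruption, keypoint-aware crop sampling |
| `mapose.decoding` | smoothing, NMS peak finding, subpixel refinement, PAF line costs |
| `mapose.graphsel` | cost histograms, auROC ranking, maximum spanning tree, candidate graphs |
| `mapose.assembly` | per-edge matching, connected components, greedy linking, pose prior, temporal coherence |
| `mapose.tracking` | box/ellipse Kalman trackers, Hungarian association, SORT loop |
| `mapose.stitching` | tracklet affinities, flow network, solver, residual reinsertion |
| `mapose.identity` | soft voting, embedding cosine, triplet accuracy |
| `mapose.metrics` | RMSE, PCK, OKS-mAP, purity, CLEAR-MOT, swap flags, Proximity Index |
| `mapose.cli` / `mapose.pipeline` | subcommands and the end-to-end run |
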