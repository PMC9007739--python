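# Methods

This note documents the models and procedures implemented in `mapose`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Coordinate and rendering conventions

Pixel indices are 0-based, x grows rightward and y downward; keypoints are
continuous subpixel positions. The map grid cell `(p, q)` (p = column,
q = row) corresponds to the full-image point `(p·λ + λ/2, q·λ + λ/2)`,
which makes the subpixel decoding rule the exact algebraic inverse of
target rendering: the location-refinement field stores, at every positive
score-map cell, the offset from that cell's centre to the true keypoint, so
a noiseless render→decode round trip is exact to numerical precision (the
test suite asserts ≤ 1e−9 px over random subpixel keypoints).

Target score maps are binary — 1 on cells whose centre lies strictly within
radius `r` of the keypoint, 0 otherwise — rather than Gaussian-blurred;
this is the literal reading of the target rule and the blur would not
change decoding, which operates on peaks. PAF targets place the limb's unit
direction vector on cells within `pafwidth` of the segment; where limbs of
several animals overlap, the instance whose segment is closest wins the
cell (keeping every stored vector of unit norm rather than averaging to a
shorter one).

## Synthetic scenes

The generator emulates several same-body-plan animals in an arena:

* **Motion.** Per-animal rigid translation at constant speed with a heading
  following a Gaussian random walk (`turn_sd`), reflecting at walls. All
  animals share one body plan (random radial offsets of scale
  `body_scale`), rotated to the heading; `elongation > 1` stretches the
  plan along the heading to emulate elongated bodies (fish-like). Optional
  per-keypoint articulation noise.
* **Occlusion.** Whole-animal events: with probability `occlusion_rate`
  per frame, all keypoints of an animal disappear for
  `occlusion_duration` frames. Whole-animal occlusion is the regime the
  tracklet stitcher exists for; partial occlusion is covered separately by
  keypoint dropout.
* **Detection noise.** Gaussian jitter (`jitter_sd`), independent keypoint
  dropout (`dropout`), and Poisson clutter with confidence ~ U(0.1, 0.6)
  so confidence thresholds are exercisable (true detections carry
  confidence 1).

Defaults (speed 3 px/frame, turn s.d. 0.3 rad, jitter 1 px, dropout 0.05,
clutter 0.5/frame, occlusion 0.01/frame for 5 frames on a 512×512 arena,
stride 4, r = 5 px, pafwidth = 8 px) are what we consider moderate noise
for overhead lab video at this resolution: jitter below the target radius,
dropout low enough that an animal rarely loses a majority of keypoints in
one frame, clutter sparse relative to true detections.

What the generator does **not** emulate: appearance (no RGB rendering, so
identity scores and embeddings are always externally supplied or
synthesized), body deformation beyond articulation noise, partial-animal
occlusion by scene objects, imaging artefacts (blur, scale change), and
correlated detector failures. Passing tests on these scenes therefore
demonstrates the correctness and robustness of the *assembly/tracking/
stitching machinery* under geometric ambiguity — crossings, occlusion
gaps, clutter — not the performance of any keypoint detector on real
images.

The default skeleton is a chain plus skip connections `(i, i+2)`; the
redundancy means a single dropped keypoint cannot split an animal into two
connected components, mirroring the redundancy that data-driven graph
selection produces on real data.

## Decoding

Score maps are Gaussian-smoothed (σ = 1 cell) before peak finding;
smoothing-then-threshold is the implemented order. NMS returns cells equal
to the max of their `(2·nms_radius+1)²` window (default radius 2) above
`min_confidence` (default 0.01); on plateaus of equal values the cell with
the lowest `(p, q)` wins, making output deterministic.

The PAF line cost samples the field at `n_samples = 10` equally spaced
points including both endpoints, reading the nearest grid cell (bilinear
lookup available via config). Each sample is projected onto the segment's
unit direction; the projection convention (rather than integrating the raw
field norm) is what makes the cost sign-discriminative — reversing a
segment on a constant field flips the sign — which the within/between
auROC separation relies on. The raw-norm variant is available behind
`paf_cost="norm"`.

## Skeleton selection

Within-/between-animal cost histograms use bin width 0.01 over [−1, 1].
auROC is computed from the histograms as the Mann–Whitney statistic
(ties within a bin count ½), which equals the trapezoidal area under the
binned ROC; the test suite checks it against an exact O(n²) pairwise
comparison oracle to 0.01. The minimal skeleton is the maximum spanning
tree over auROC weights; candidates extend it in approximately equal edge
increments up to the complete graph (default 9 candidates), plus an
optional baseline family grown from a user skeleton with edges added from
least to most discriminative. "Jointly maximizing purity and connected
fraction" is scalarized as their unweighted mean with ties broken toward
the smaller graph — the smallest adequate skeleton is cheapest downstream.
Edge ranking uses training-split costs only.

## Assembly

Per-edge strong connections are the optimal one-to-one assignment over
costs ≥ `paf_threshold` (default 0.1); this concrete reading matches the
one-to-one semantics the connected-components step assumes. Remaining
above-threshold connections are applied greedily in descending cost order;
a connection is skipped if it would give a group two detections of one
bodypart or merge two groups sharing a bodypart. Redundant internal
connections simply add to the assembly score (mean of member connection
costs, later used as tracker confidence).

The pose prior is the Gaussian matching a kernel density estimate of the
pairwise-distance vectors with Scott's-rule bandwidth: mean = sample mean,
covariance = sample covariance × (1 + n^(−2/(d+4))); singular covariances
get `εI` with `ε = 1e−8 · trace/dim`. Gating on partial poses restricts
mean and covariance to the observed distance coordinates (sub-block
selection — the marginal of a Gaussian); a growth step is accepted iff it
does not increase the Mahalanobis distance, and an inapplicable gate
accepts.

The temporal coherence weight multiplies the affinity cost by
`(1 + weight)` (replacement mode available via config); `γ = 0.01`
controls the influence of distant frames.

Frames are independent work units; results are order-independent.

## Tracking

Kalman filters are linear constant-velocity with SORT-style noise
settings: initial covariance 10 on observed coordinates and 1000 on the
unobservable velocities (which start at 0), process noise 1e−2 (1e−4 on
velocities), measurement noise 1. The box state is `[x, y, A, r]` + three
velocities; the ellipse state `[x, y, h, w, θ]` + five velocities, with the
measured θ unwrapped toward the filter state to avoid ±π/2 jumps.

Ellipse similarity uses the wrapped angle difference — an ellipse's
inclination is π-periodic, so `θ_d − θ_p` is reduced into (−π/2, π/2]
before the cosine; without this, near-vertical ellipses whose measured
angles alternate between ≈ +π/2 and ≈ −π/2 look maximally dissimilar and
tracking fragments badly. The centroid distance `d` is normalized by the
longest semi-axis of the pair and clamped at 1 so the similarity stays in
[0, 1] (the printed formula can go negative otherwise).

`max_age` counts the consecutive undetected frames after which a tracker
is terminated, so at the default `max_age = 1` a tracker dies on its first
miss and every tracklet is a maximal run of consecutive matched frames
(contiguity is only guaranteed at this default; with `max_age > 1` a
tracker may re-match after a short gap and its frames are then strictly
increasing but not contiguous). Tracklets with fewer than `min_hits`
observed frames are discarded. Output contains observed frames only — an
unmatched-but-alive tracker contributes no predicted positions.

## Stitching

Tracklets shorter than 5 frames (configurable) are residuals. The search
window is `ceil(1.5·τ)` with τ the largest nearest-successor gap, unless
overridden. Affinities:

* **Motion** — tail/head velocities averaged over the three terminal
  instantaneous velocities; forward and backward rectilinear extrapolation
  errors averaged.
* **Proximity** — tail-to-head centroid distance (the overlapping-branch
  mean distance is used only when scoring residual insertion, since
  time-overlapping tracklets get no graph edge: an animal cannot be in two
  places at once).
* **Shape** — undirected Hausdorff distance between the terminal keypoint
  sets; an empty set maps to the worst normalized cost rather than
  dropping the edge.
* **Dynamics** — effective Hankel ranks. Each tracklet's Hankel matrix
  stacks delayed copies of its mean-centred centroid signal (x rows over y
  rows, square-as-possible depth); the effective rank counts singular
  values ≥ 1% of the largest. The *joint* matrix is built from the
  concatenated centroid sequence of both tracklets with the temporal gap
  bridged by linear interpolation. Two segments of one rectilinear
  trajectory then give r₁ = r₂ = 2 and r_joint = 2 (ratio 0.5); a
  time-reversed or displaced continuation produces a piecewise signal of
  higher joint rank (ratio > 0.5). This formulation was chosen over
  column-concatenating the two Hankel blocks, which is numerically fragile:
  a large inter-tracklet displacement dominates the singular spectrum and
  collapses the relative-threshold rank regardless of the dynamics.
  Mean-centring is applied for the same reason — the rank threshold is
  relative to the largest singular value, and an absolute-position offset
  otherwise swamps the motion component. Tracklets shorter than 4 frames
  mark the affinity unavailable.

Each available affinity is min-max normalized over the candidate edge set
and combined as a weighted sum (default weights equal); appearance
embeddings, when supplied, rescale the weight multiplicatively by
`(1 − s·cos_sim)` with strength `s ∈ [0, 1]` — similar appearance cheapens
an edge. Flow solvers need integer costs, so weights are scaled by 10⁴ and
rounded.

The flow network splits each tracklet into a unit-demand input and a
unit-supply output; source and sink carry `k` units (k = number of animals,
user input per video). Covering the DAG with `k` node-disjoint minimum-cost
paths is solved with the capacity-scaling successive-shortest-path
algorithm; the test suite verifies exact agreement with an exhaustive
path-cover enumeration on random instances. When no `k`-cover exists the
solver reports the offending frame range; the orchestrating
`stitch_tracklets` first widens the gap twice (the automatic 1.5τ window
can be too tight when an early tracklet has no successor within it) and
then demotes the shortest most-overlapping tracklet to a residual — more
than `k` tracklets overlapping in time means some animal was spuriously
split or duplicated, and the demoted fragment is reinserted greedily
afterwards instead of aborting the whole video.

Residual reinsertion first grows residual chains along weighted longest
paths of a small association DAG (edge score decreasing with tail-head
distance), then places grown residuals — longest first — into tracks where
all their frames are free, choosing the track minimizing the distance to
the neighbouring tracklets; a grown group that fits nowhere as a whole
falls back to placing its members individually, and genuinely unplaceable
residuals are reported, never forced.

## Identity

Identity enters as data, never as a model: per-detection probability
vectors over named individuals (extra `id_prob_i` columns of the detection
table) or per-tracklet embedding vectors (a plain numeric sidecar table).
Soft voting treats bodyparts as individual classifiers and takes the
argmax of the mean probability vector, ties broken by individual order.
The synthetic embedding generator (a labelled stand-in for a trained
re-identification model) assigns each identity a random unit prototype
plus isotropic noise; triplet accuracy counts `cos(a, p) > cos(a, n)` with
ties as failures.

## Evaluation

* **RMSE** — per ground-truth keypoint, distance to the closest
  prediction, aggregated as root-mean-square.
* **PCK** — fraction of predictions within `fraction` (default 1/3) of a
  reference limb length; zero-reference frames are skipped with a warning.
* **OKS-mAP** — COCO convention: `exp(−d²/(2·area·(2σ)²))` per labelled
  keypoint with σ = 0.1 and area = the animal's bounding-box area,
  averaged; greedy decreasing-score matching per threshold
  (0.50:0.05:0.95) and all-point PR interpolation. Configured symmetric
  keypoint pairs are scored under their best flip (pairs are independent,
  so each flip is decided separately).
* **Purity / unconnected** — purity is the fraction of an assembly's
  keypoints belonging to its most frequent ground-truth animal, averaged
  over assemblies; unconnected counts true detections left in no assembly.
* **CLEAR-MOT** — per-frame distance-thresholded assignment with match
  persistence (a standing correspondence survives while within threshold);
  MOTA = 1 − (misses + FPs + switches)/total ground-truth objects. The
  matching distance is Euclidean between centroids with a configurable
  threshold defaulting to half the mean animal bounding-box diagonal.
  Fragments count interruptions of a trajectory's tracked status;
  mostly-tracked uses the standard 80%-of-lifespan rule. The
  implementation is cross-checked count-for-count against an independent
  brute-force accumulator in the test suite.
* **Swap flagging** — a frame is flagged for a track pair when both the x
  and the y orderings invert between consecutive frames (simultaneity
  required).
* **Proximity Index** — per animal, the number of other animals' keypoints
  inside the smallest centroid-centred disk covering its own keypoints,
  divided by its own keypoint count.

## Problem sizes in the test and acceptance runs

The default suite and `scripts/acceptance.py` use scenes of 2–3 animals,
3–5 bodyparts and 60–100 frames on 256×256 arenas, 8–10 seeds per
experiment, and oracle instances small enough for exhaustive enumeration
(≤ 6×6 assignment matrices, ≤ 10-tracklet path covers, 2–3 animal
partition spaces). These sizes keep every brute-force oracle exact while
exercising crossings, occlusion gaps and clutter; all pipeline algorithms
are the same ones that run at arbitrary scale.

## Known limitations

* Assembly is greedy, not an exact k-dimensional matching (NP-hard); the
  oracle-equivalence test quantifies the gap on small frames (≥ 95%
  agreement) rather than bounding it in general.
* The stitcher assumes a constant number of animals `k` in view; animals
  permanently entering/leaving mid-video require splitting the video or
  adjusting `k`.
* Dynamic similarity models centroid motion only; it cannot separate
  animals with identical trajectories (e.g. perfectly parallel swimmers).
* The CLEAR-MOT switch count follows the classic convention (persisting
  last known match); tools with IDF1-style global matching will report
  different switch totals on the same data.
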