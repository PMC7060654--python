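# Methods

## Problem setting

Single-class object detection in dense field imagery, trained under an
annotation budget. Two label types exist: a *weak* label is one click near an
object's centre; a *strong* label is a tight bounding box. The package
implements a three-pool active-learning cycle in which weak labels are bought
in bulk, a click-conditioned uncertainty score decides which weakly labeled
images deserve boxes, and only those are promoted.

## Geometry conventions

Coordinates are continuous pixels, origin top-left. Boxes are half-open
`[xmin, xmax) × [ymin, ymax)`: a click on the right/bottom edge is outside,
which avoids double-assignment on shared edges and makes tiling exact.
Zero-area boxes are rejected at construction. Distances are Euclidean.

## Region proposal filtering

A proposal survives for click `w` iff it (1) contains `w`, (2) has its centre
within `ε` of `w`, (3) has area ≤ `α`, and (4) contains no other click of the
image. Comparisons at exactly `ε` and `α` are inclusive ("should not exceed"
read as ≤). A proposal covering two clicks is dropped outright rather than
assigned twice — duplicating it would let one ambiguous proposal inflate two
objects' uncertainty.

`ε` and `α` are estimated from whatever strong labels exist (by default the
seed pool): `ε` as the 20th percentile of nearest-neighbour distances between
box centres, rounded to the nearest multiple of 10; `α` as the 90th
percentile of box areas, rounded to two significant figures. Percentiles use
linear interpolation between order statistics (the common deterministic
convention). The percentile levels trade off two failure modes: a large `ε`
lets a retained proposal straddle a second object; a small `α` filters out
the true box. Both the levels and the rounding rules are configurable.

## Uncertainty metrics

Scores of surviving proposals for one object are treated as Bernoulli
probabilities. Per group: population variance (no Bessel correction — the
group is the whole population of retained proposals) and mean binary entropy
in bits. Image scores are maxima over the image's clicks. The combined
`mev = λ₁·u_ent + λ₂·u_var` uses `λ = (1, 4)` by default: variance of values
in [0, 1] is bounded by 0.25 (Bhatia–Davis, `σ² ≤ (M−μ)(μ−m)` at `μ = 0.5`),
entropy by `log₂ 2 = 1`, so ×4 equalises the attainable ranges. The two terms
are complementary: a group scored uniformly at 0.5 has maximal entropy but
zero variance, yet clearly reflects an undecided model.

**Empty groups.** A click whose group survived no proposals contributes the
metric's maximum (1.0 entropy / 0.25 variance) under the default `max`
policy — an object the proposal stage missed entirely signals maximal
ignorance. A `skip` policy (ignore such clicks; 0 if all groups are empty) is
available. Note the `max` policy saturates: one missed object pins the image
at the global maximum regardless of everything else, so in dense scenes a
high proposal-recall detector is assumed.

**Baselines.** Least confidence `1 − max p` (empty image → 1.0), margin
`Σ(top1 − top2)` summed over boxes and selected ascending, and categorical
entropy in bits summed over boxes (summation mirrors the margin convention;
per-image averaging would down-weight dense images). Empty images under
margin/entropy return a 0.0 sentinel with a warning. Top-k selection breaks
ties lexicographically by image id, which makes runs reproducible.

## Annotation cost model

Unit times are ImageNet crowd-sourcing medians: 25.5 s draw, 9.0 s verify,
7.8 s per-image "any objects left?" check, 3.0 s per centre click. Hence
Type-1 = 7.8 s/image + 3.0 s/object and Type-2 = 34.5 s/object; the per-image
check is charged once, at weak-label time, and promotion to boxes adds only
box time. Costs are reported in seconds and hours.

## Evaluation

Detections are matched to ground truth greedily in descending score; a match
requires IoU ≥ 0.5 (inclusive, the standard convention); duplicates on an
already-matched box are false positives. The precision–recall curve is
evaluated at every distinct score cut, and AP is the area under the monotone
precision envelope (all-point interpolation). With one class, mAP = AP.
Count agreement uses Pearson r (undefined, and signalled, for constant
sequences) and RMSE at a configurable score cut (default 0.5).

## The synthetic benchmark

The generator emulates the *structure* of dense crop tiles, not their pixels:
500×500 scenes, 5–60 objects each, box sides log-normal (median 40 px,
log-sd 0.25, clipped to [8, 160]), centres ≥ 25 px apart by rejection
sampling. Per-object difficulty proxies (blur, occlusion, lighting ∈ [0, 1])
are hierarchical: a scene-level Beta(2, 6) base per attribute plus
per-object Gaussian perturbation (sd 0.08) — blur and lighting are largely
properties of the photograph, so images genuinely differ in difficulty,
as real field tiles do. The click oracle places one click per box at the
centre plus isotropic Gaussian noise (default sd 3 px), clamped inside the
box.

The simulated detector's latent state is a training mass
`m = Σ (1 + β·difficulty_i)` over the labeled pool (β = 2: hard images teach
more — without some such coupling, *which* images get labeled could not
affect learning and every query strategy would be equivalent by
construction). Competence is `c = m / (m + κ)` with κ = 30, and per object
`c_obj = c · (1 − γ·difficulty)` with γ = 0.5. Proposals: K = 12 per object,
centres jittered by 0.10 of the box side, sizes by a log-normal factor
(log-sd 0.35 — wide, mimicking a region proposal network's multi-scale
clusters, and wide enough that objects larger than `α` still yield some
sub-`α` survivors), plus Poisson(4) background boxes. Objectness scores are
Beta-distributed with mean `0.5 + 0.5·c_obj` (clipped to [0.05, 0.97]) and
concentration `2 + 40·c_obj`: an untrained model scores near-uniformly (high
entropy and variance), a competent one saturates towards 1 with vanishing
spread. Detections appear per object with probability
`0.15 + 0.9·c_obj` (capped at 0.98) and background false positives fade as
`4·(1 − c)`. All κ, γ, β, K, ν values are simulator conventions chosen so a
learning curve on a 300-image pool traverses AP ≈ 0.7 → 0.85 within ten
episodes of budgets (b_W, b_S) = (20, 10) from a 50-image seed — the regime
in which query strategies can be compared at desk scale — not estimates of
any real crop or detector.

Every stochastic operation takes an explicit seed; propose/detect derive
their RNG from (detector seed, image id, stage, training mass), so they are
deterministic given a model state, and one experiment seed drives named
substreams for the split, the random sampler and the click oracle.

**What passing tests do and do not show.** The benchmark demonstrates the
mechanics and the qualitative claims — uncertainty shrinks with training,
uncertainty-guided promotion prefers hard images, point supervision reaches a
target AP with fewer boxes than random sampling. It does not render pixels,
model detector failure modes beyond a scalar competence (no systematic
localisation bias, no correlated errors across images), and its effect sizes
say nothing about any real dataset; real-data AP values are out of reach
without training an actual detector.

## Active loop details

Stage-1 criteria are computed on detections over the unlabeled pool
(`rand` uses the seeded sampler). Stage-2 metrics are recomputed for the
*entire* weak pool each episode with the current model, so leftover weak
images from earlier episodes compete on fresh uncertainty. Budgets clamp to
pool sizes; the experiment stops when both the unlabeled and weak pools are
empty or `max_episodes` is reached. Standard pool-based AL (`stage2: none`)
moves `b_W` images straight to the labeled pool under the no-clicks cost
formula. The evaluation split (default 40% held out) and the IoU threshold
are configurable. The seed pool is charged at the standard (no-clicks) rate
in the episode-0 log, so cumulative cost is exactly the sum of per-episode
costs.

## Dataset tiling

Images are sliced into a non-overlapping grid. "Partial object" means any
box not fully contained in its tile. `drop-image` (strict): a tile with any
partial object, or with no object, is removed. `drop-annotation` (lenient):
partial annotations are removed and the tile is kept if at least one whole
object remains; tiles left with zero objects are removed for consistency
with the strict rule. Coordinates are re-expressed in the tile frame, and
per-object difficulty follows its box. Pixel resampling is out of scope —
the package manipulates coordinates only.

## Known limitations

- The `max` empty-group policy saturates the image score; with a
  low-recall proposal stage, `mev` rankings degrade towards arbitrary
  tie-breaking (see above).
- The simulated detector has a single scalar skill; it cannot express
  class-confusion or calibration pathologies of real detectors.
- `estimate_epsilon` needs at least one image with two objects, and the
  rounding rules can in principle round a very small raw percentile to 0,
  which is rejected when constructing `RpfParams`.
- Margin and entropy baselines on images with no detections return
  sentinels (0.0) rather than attempting a principled imputation.
- Multi-class detection, rotated boxes and mask labels are out of scope.
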