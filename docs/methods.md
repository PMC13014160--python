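# Methods

## Problem setting

A detector `f_θ` is trained on a labeled source domain of dual-channel 3D
volumes (a PET-like uptake channel and a CT-like anatomical channel,
stacked after resampling to a common grid) and must perform on an
unlabeled target domain from a different tracer. Labels are axis-aligned
boxes, one lesion class. Two shifts separate the domains:

* **Covariate shift** — tracer-specific appearance: contrast, noise, the
  pattern of physiological (non-lesion) uptake.
* **Label shift** — the target cohort has more lesions per subject and a
  smaller typical lesion volume, with the source holding more of the very
  large (≥150 cc) lesions.

Boxes are half-open voxel-coordinate intervals; physical volumes come from
the voxel spacing (default 4 × 4 × 5 mm, i.e. 0.08 cc per voxel). Ground
truth derived from segmentation masks uses 26-connected components and
discards regions below 0.08 cc (strictly; a region of exactly one working
voxel survives).

## Detection model

The reference detector scores K anchor shapes at every stride-4 grid
point. Features per position are hand-crafted multiscale local statistics:
box-filter means of the PET channel (3/7/15 voxels), dense matched-filter
responses (local means at blob scales 3 and 5, max-pooled over a window
one voxel wider than the stride so off-grid blobs are never invisible),
CT means, and uptake-weighted centre-of-mass offsets and second moments
(windows 9 and 15) that give the regression head direct position and size
cues. A one-hidden-layer ReLU network (64 units) feeds per-anchor
classification and box-regression heads; all gradients are closed-form
and optimization is Adam (lr 1e-2, batch 4 subjects).

The loss is the standard one-stage combination: focal classification
(γ = 2, α = 0.25) summed over non-ignored anchors plus smooth-L1
regression (δ = 1) over positive anchors, both normalized by the positive
count (the raw sums would make crops with many lesions dominate).
Assignment is IoU ≥ 0.5 positive / < 0.4 negative with best-match forcing
so every ground-truth box owns at least one positive anchor. Box
regression uses centre offsets normalized by anchor extent and log extent
ratios; encode/decode round-trips are exact to float precision.

Initial anchors are k-means centroids (k-means++, Euclidean distance on
extent triples, fixed seed) of the labeled source boxes, K = 3 by
default. Inference applies a sigmoid, decodes against the anchor grid,
gates at a 0.05 score floor, and cleans with 3D NMS at IoU 0.25; sliding-
window inference shifts per-window detections to the global frame and
merges with the same NMS. Greedy NMS breaks score ties by insertion
order, so all pipeline outputs are deterministic.

## The adaptation loop

After supervised pretraining on the source (100 epochs by default), each
of R rounds alternates:

1. one supervised epoch on the labeled source;
2. a full inference pass on every unlabeled target subject; detections
   below τ = 0.5 are discarded and NMS at IoU 0.25 yields the cleaned
   candidate set `C_i`;
3. pseudo-label selection (below), online prior and anchor updates;
4. one supervised epoch on the pseudo-labeled target subjects.

The admission factor λ grows linearly from 0.1 to 0.8 across rounds
(0-based, endpoints included), so early rounds admit little while the
priors are still near their source initialization.

### Online target priors

Two statistics summarize the target label distribution: `μ`, the mean
lesions-per-subject, and `h`, a normalized histogram over B = 10
lesion-volume bins (log-spaced edges from 0.08 cc to 150 cc plus an open
top bin — the small-lesion regime where the cross-tracer shift
concentrates gets most of the resolution). Both are EMA updates,

```
μ ← (1 − α_μ) μ + α_μ · mean_i |C_i|
h ← normalize( (1 − α_h) h + α_h · ĥ )
```

with `ĥ` the volume histogram of the pooled cleaned candidates.
`h(0)` is the source box histogram over the same bins and `μ(0)` the
source mean lesions-per-subject.

**Estimation vs admission.** All three target statistics (μ, h, anchor
shapes) are estimated from the *cleaned candidates*, while the quota
machinery controls only what is *admitted for training*. Estimating the
priors from their own selections is circular: the selected count is
capped by the budget that μ defines (the fixed point collapses toward
zero), and the selected histogram is supported only on bins that already
received quota, so h degenerates to a near-delta within a few rounds at
small budgets. The candidate-based estimates have no such feedback.

### Quota selection

Each subject's budget is `N_allow = ⌈λ μ⌉`. Ceiling rather than floor:
the cap exists to stop false-positive-heavy scans from dominating, and
`λμ + 1` still bounds admission, whereas flooring shuts selection off
entirely whenever `λμ < 1` — with few confident candidates per subject
that disables the whole mechanism, an artifact of integerization.

The budget is apportioned across volume bins by the largest-remainder
rule (floors of `h_b · N_allow`, leftover slots to the largest fractional
parts, ties to the smaller-lesion bin), so quotas sum exactly to the
budget and each differs from its fractional share by less than one.
Within a bin candidates are kept in descending score order up to the
quota; an under-filled bin keeps all its candidates and its unused quota
is *not* transferred — transfer would let abundant (source-like) sizes
reclaim the slots the prior reserved for the target's size profile.

The conventional baseline keeps the top `⌈p·n⌉` candidates by confidence
(p = 0.5); the ceiling means a subject with a single candidate still
contributes it.

**Ignore regions.** The quota deliberately declines confident candidates,
and a weak cross-domain detector misses many true lesions outright. On
pseudo-labeled volumes, negatives are therefore only taken where the
current detector sees nothing: unselected detections scoring ≥ 0.25
(configurable) become ignore regions in the anchor assignment. Training
them as background would turn the admission cap into an active
suppressor and collapses target confidence within a round or two. An
optional stricter mode (`focus_radius`) restricts negatives to a
neighbourhood of the pseudo boxes — the patch-sampling idiom of
partial-annotation detection — but did not help consistently at this
scale and is off by default.

### Anchor adaptation

Each round, k-means (fresh, seeded per round) re-estimates K centroids
from the candidate boxes and the anchor set moves by
`s_k ← (1 − β) s_k + β s̃_k` after pairing old anchors to new centroids
by minimum-total-squared-distance assignment (centroid volumes can cross
between rounds; nearest-neighbour pairing would double-assign). Only the
final round's anchors are used for target-domain test inference.

`β` defaults to 0.1: the momentum exists to stabilize early rounds, and
stability requires the *previous* anchors to carry the large weight. At
desk-scale pseudo-box counts a near-replacement update (weight 0.9 on the
fresh k-means) lets one noisy estimate rewrite the anchor set; since
anchor geometry defines which anchors are positive during training, the
classifier then unlearns lesion sizes that lost their anchor. The prior
momenta default to α_μ = α_h = 0.9 (current-round weight); with
candidate-based estimates these are stable, and smaller values only slow
convergence. All three are configurable.

## The simulator

Each synthetic subject is a two-channel volume (default 48³ voxels at
4 × 4 × 5 mm): a CT-like channel of smooth anatomical gradient plus bumps
at distractor sites, and a PET-like channel containing

* lesions: soft ellipsoidal uptake blobs; count ~ Poisson(rate), volume
  log-normal, mild anisotropy, rejection-sampled centres so labeled
  lesions stay distinct components;
* physiological distractors: high-uptake blobs co-located with CT bumps,
  absent from the label mask — deliberate false-positive bait for the
  admission cap;
* structured background-uptake clutter: smoothed positive haze whose
  blobby texture survives z-score normalization, unlike a global contrast
  change;
* voxel noise.

The FDG-like source uses rate 3, median volume 8 cc (σ_log = 1.4, so a
visible ≥150 cc tail), contrast 4.0, two distractors, haze 0.3. The
PSMA-like target uses rate 6, median 1.8 cc (σ_log = 1.0), contrast 3.5,
three distractors, haze 0.4. The label shift between the two is large
(L1 ≈ 0.9 between their box-volume histograms over the default bins) and
the covariate shift is learnable: a detector trained on target-like data
handles the clutter that degrades the source-trained model.

What the simulator does **not** emulate: anatomy (organs are generic
blobs), attenuation/scatter physics, SUV calibration, inter-subject
variability beyond Poisson/log-normal sampling, and lesion texture.
Passing tests therefore show that the adaptation machinery behaves as
designed under a controlled, realistic-magnitude label shift — not that
any particular clinical AP level would be reached on real cohorts.

Ground truth per subject is derived exactly as a real annotation mask
would be: connected components of the rasterized mask, tight boxes, 0.08
cc filter. Cohort splitting uses round-to-nearest sizes with the
remainder applied to the largest split (369 subjects at 70/10/20 give
258/37/74). All randomness flows from one master seed through spawned
per-subject seeds; identical seeds give bitwise-identical volumes.

## Evaluation

Lesion-level matching is greedy and one-to-one: detections in descending
score order claim their highest-IoU unclaimed ground truth at or above
the threshold; extra detections on a claimed lesion are false positives.
AP pools detections across subjects and integrates the precision
envelope (all-points interpolation); reported at IoU 0.1/0.25/0.5. FROC
reports pooled lesion sensitivity against mean false positives per scan
over descending score cutoffs (matching at IoU 0.1); because greedy
matching depends only on higher-scored detections, the sweep is a prefix
count of a single matching. Score ties are broken by subject then
detection index; AP is invariant to subject order and to monotone score
transforms, and non-increasing in the IoU threshold.

## Numerical and degenerate-input conventions

* Empty candidate rounds skip the prior updates; fewer candidates than K
  skip the anchor update (previous anchors carried over).
* Candidate boxes below the first bin edge (sub-voxel slivers) cannot be
  apportioned and are dropped from selection.
* A constant image channel z-scores to zeros (guarded divide).
* Boxes truncated by a training crop are kept only if ≥50% of their
  volume survives.
* Probabilities are clamped to [1e-7, 1 − 1e-7] in the focal loss;
  decoded log-extent ratios are clamped to ±8.
* The detector's `clone()` carries the Adam state: restarting the
  optimizer mid-pipeline takes full-size bias-corrected first steps that
  perturb a calibrated model.

## Known limitations

* **Biased candidate sampling.** The τ-gated candidate stream
  over-represents conspicuous lesions. Under partial admission the
  selected set is biased further (quota support shrinks with the
  budget). The prior- and anchor-recovery guarantees verified by the
  oracle-detector tests therefore hold for the update machinery; with a
  weak real detector, μ underestimates the true lesion rate (it measures
  *confident* lesions per subject) and h leans toward detectable sizes.
* **Score deflation at sparse supervision.** Training epochs whose
  positive set is very small exert net downward pressure on the score
  scale of a small model; the ignore-region mechanism bounds but does not
  eliminate this.
* **Desk scale.** The shipped experiments use tens of subjects, 48³
  volumes, R = 20 rounds and a deliberately small detector; the loop,
  not the backbone, is the subject of this package, and the detection
  contract accepts any model implementing `train_step`/`predict`.
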