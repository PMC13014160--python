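# tracershift

Label-shift-aware self-training for cross-tracer 3D lesion detection in
PET/CT.

A lesion detector trained on one PET tracer (e.g. FDG) degrades on another
(e.g. PSMA) for two reasons at once: the images look different (covariate
shift), and the *lesions themselves* are differently distributed — PSMA
cohorts carry more and smaller lesions per subject, FDG more of the very
large ones (label shift). Conventional unsupervised domain adaptation by
self-training fixes only the first problem: selecting pseudo labels by a
fixed confidence rule favours large, high-contrast lesions and quietly
re-imposes the source domain's size profile on the target.

`tracershift` implements a self-training loop for anchor-based 3D
detectors that models the target label distribution explicitly and adapts
two things the usual loop leaves frozen:

* **Anchor shapes.** The K anchor extents are re-estimated each round by
  k-means over the model's confident target detections and blended across
  rounds with an exponential moving average,
  `s_k ← (1 − β) s_k + β s̃_k`, so box regression stays matched to the
  evolving target size statistics.
* **Pseudo-label selection.** Online priors over the target labels — the
  mean lesions-per-subject `μ` and a normalized histogram `h` over B
  lesion-volume bins — are maintained by EMAs of the cleaned candidate
  statistics. Each subject receives an admission budget
  `N_allow = ⌈λ μ⌉` (λ grows linearly across rounds), apportioned over
  volume bins by the largest-remainder rule `n_b ≈ h_b · N_allow`; within
  each bin the top-scoring candidates are kept, and unused quota is never
  transferred to over-represented bins.

Each adaptation round alternates one supervised epoch on the labeled
source domain with a full inference pass on the unlabeled target (score
gate at τ = 0.5, then 3D NMS at IoU 0.25), prior/anchor updates, and one
supervised epoch on the pseudo-labeled target subjects. Training uses the
standard one-stage detection loss — focal classification over all anchors
plus smooth-L1 regression over positive anchors, with RetinaNet-style
assignment and best-match forcing.

Everything runs on one CPU: the package ships a compact reference detector
(multiscale matched-filter features with per-anchor MLP heads, closed-form
gradients), a seeded dual-tracer volume simulator that reproduces the
FDG→PSMA count/size label shift, and lesion-level AP/FROC evaluation.

## Worked example

`examples/04_full_adaptation.py` pretrains on 40 simulated FDG-like
subjects, adapts to 30 unlabeled PSMA-like subjects for 20 rounds, and
evaluates on 20 held-out target subjects (about two minutes):

```
source-only            AP@0.1 = 0.202
top-50% self-training  AP@0.1 = 0.352
label-shift-aware      AP@0.1 = 0.348

online prior after adaptation:
  mu = 0.30 confident lesions/subject (true target mean 6.67)
  anchors: [(3.9, 3.5, 2.8), (5.3, 5.0, 4.2), (7.1, 6.8, 5.6)]
  (initial: [(4.4, 4.5, 3.7), (8.9, 8.7, 6.8), (14.4, 15.8, 11.2)])
```

The frozen source model loses most of its precision on the shifted
tracer; both self-training arms recover a large part of it, and the
anchor set shrinks toward the target's smaller lesions. Single seeds are
noisy for ranking the two self-training arms against each other; over
three seeds (the experiment in `tests/test_acceptance.py`) the mean
AP@0.1 ordering is

```
source-only 0.292  <  top-50% self-training 0.353  ≤  label-shift-aware 0.385
```

The other examples are smaller: `01_simulate_cohort.py` quantifies the
simulated label shift, `02_pretrain_and_evaluate.py` shows the
cross-domain AP/FROC drop, `03_prior_guided_selection.py` walks through
one quota-selection round step by step.

## Command line

The same pipeline is scriptable from a shell:

```sh
tracershift simulate --outdir data --n-source 20 --n-target 15 --seed 0
tracershift pretrain --dataset data --outdir runs/pre --epochs 100
tracershift adapt    --dataset data --outdir runs/adapt \
                     --pretrained runs/pre/pretrained.npz --rounds 20
tracershift evaluate --dataset data --checkpoint runs/adapt/adapted.npz \
                     --outdir runs/eval
tracershift report   --metrics runs/eval/metrics.json
```

Each stage writes its resolved configuration (with a content hash) next to
its outputs, and every source of randomness flows from `--seed`.

## Documentation

`docs/methods.md` describes the model, the update equations and their
numerical behaviour at small sample sizes, what the simulator does and
does not emulate, and the package's design decisions.
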