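"""Source pretraining and the R-round label-shift-aware self-training loop.

Each adaptation round alternates:

* **Step 1** — one supervised epoch on the labeled source domain;
* **Step 2** — a full inference pass on the unlabeled target domain, cleaning
  (score gate + NMS) and selecting pseudo labels (prior-guided quotas or the
  conventional top-fraction baseline), online updates of the target priors
  (lesions-per-subject mean ``mu``, size histogram ``h``) and of the anchor
  shapes (k-means + EMA), then one supervised epoch on the pseudo-labeled
  target subjects.

The per-round admission factor ``lambda`` grows linearly so early rounds are
conservative while the priors are still close to their source
initialization.  ``mu`` is estimated from the cleaned candidate counts
(post gate-and-NMS, pre-quota): estimating it from the quota-capped selected
counts would make the budget self-referential and collapse it (see
docs/methods.md).  The histogram ``h`` is estimated from the selected pseudo
labels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .anchors import AnchorSet, InsufficientBoxesError, anchors_for_round, kmeans_shapes
from .detector import MinimalDetector, sliding_window_predict
from .geometry import Box3D, Detection, Spacing
from .priors import (
    SizeBinning,
    SizePrior,
    default_binning,
    size_histogram,
    source_prior,
    subject_budget,
    update_histogram,
    update_mu,
)
from .selection import (
    PseudoLabelSet,
    clean_candidates,
    lambda_schedule,
    select_prior_guided,
    select_top_fraction,
)
from .synthetic_data import SubjectSample, normalize_channels, random_crop


@dataclass(frozen=True)
class AdaptationConfig:
    """All knobs of the adaptation loop.

    Defaults follow the working recipe: tau=0.5, NMS IoU 0.25, B=10 bins,
    K=3 anchors, lambda growing 0.1 -> 0.8, 0.08 cc lesion floor, 100
    pretraining epochs.  The prior momenta alpha_mu/alpha_h default to 0.9
    (current-round weight, the printed update form); the anchor momentum
    beta defaults to 0.1 because anchor k-means on a desk-scale pseudo-box
    union is noisy and the anchor set must move slowly to keep anchor
    assignment stable (see docs/methods.md)."""

    R: int = 20
    lam_start: float = 0.1
    lam_end: float = 0.8
    tau: float = 0.5
    nms_iou: float = 0.25
    alpha_mu: float = 0.9
    alpha_h: float = 0.9
    beta: float = 0.1
    K: int = 3
    B: int = 10
    seed: int = 0
    epochs_pretrain: int = 100
    batch_size: int = 4
    lr: float = 1e-2
    stride: int = 4
    crop_size: tuple[int, int, int] | None = None  # None: train on full volumes
    window: tuple[int, int, int] | None = None  # None: single-shot inference
    overlap: float = 0.5
    selection: str = "prior_guided"  # or "top_fraction"
    top_fraction: float = 0.5
    adapt_anchors: bool = True
    ignore_floor: float = 0.25  # unselected detections above this are ignore regions
    focus_radius: float | None = None  # if set, pseudo-epoch negatives only near labels
    bin_vmin: float = 0.08
    bin_vmax: float = 150.0

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.selection not in ("prior_guided", "top_fraction"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        for name in ("lam_start", "lam_end", "tau", "top_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("alpha_mu", "alpha_h", "beta", "nms_iou"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @property
    def binning(self) -> SizeBinning:
        return default_binning(self.B, self.bin_vmin, self.bin_vmax)


@dataclass
class RoundState:
    """Everything round r+1 needs from round r."""

    r: int
    prior: SizePrior
    anchors: AnchorSet
    pseudo: dict[str, PseudoLabelSet] = field(default_factory=dict)


@dataclass
class AdaptationResult:
    detector: object
    anchors: AnchorSet
    prior: SizePrior
    history: list[dict]
    state: RoundState
    initial_anchors: AnchorSet
    initial_prior: SizePrior


def _volume_cc_of(box: Box3D, spacing: Spacing) -> float:
    return box.volume_voxels * spacing.voxel_volume_mm3 / 1000.0


class _FeatureCache:
    """Memoizes per-subject grid features; valid because volumes are fixed
    across epochs whenever training runs on full volumes (no random crop)."""

    def __init__(self) -> None:
        self._store: dict[str, np.ndarray] = {}

    def get(self, detector, sample: SubjectSample) -> np.ndarray | None:
        if not hasattr(detector, "grid_features"):
            return None
        sid = sample.subject_id
        if sid not in self._store:
            self._store[sid] = detector.grid_features(sample.volume())
        return self._store[sid]


def _train_epoch(
    detector,
    samples: Sequence[SubjectSample],
    anchors: AnchorSet,
    cfg: AdaptationConfig,
    rng: np.random.Generator,
    cache: _FeatureCache,
) -> float:
    """One pass over all subjects in shuffled mini-batches; mean loss."""
    if not samples:
        return 0.0
    order = rng.permutation(len(samples))
    losses = []
    for start in range(0, len(order), cfg.batch_size):
        idx = order[start : start + cfg.batch_size]
        batch, feats = [], []
        for i in idx:
            s = samples[int(i)]
            if cfg.crop_size is not None and tuple(cfg.crop_size) != s.pet.shape:
                s = random_crop(s, cfg.crop_size, seed=int(rng.integers(2**31)))
                feats.append(None)
            else:
                feats.append(cache.get(detector, s))
            batch.append(s)
        use_cache = all(f is not None for f in feats)
        loss = detector.train_step(batch, anchors, features=feats if use_cache else None)
        losses.append(loss)
    return float(np.mean(losses))


def _infer(
    detector, sample: SubjectSample, anchors: AnchorSet, cfg: AdaptationConfig,
    cache: _FeatureCache,
) -> list[Detection]:
    """Full-volume inference; sliding-window merge when a window is configured."""
    if hasattr(detector, "predict_subject"):
        return detector.predict_subject(sample, anchors)
    vol = sample.volume()
    if cfg.window is not None and any(
        w < d for w, d in zip(cfg.window, vol.shape[1:])
    ):
        return sliding_window_predict(detector, vol, cfg.window, cfg.overlap, anchors)
    return detector.predict(vol, anchors, features=cache.get(detector, sample))


def pretrain_source(
    detector,
    source_samples: Sequence[SubjectSample],
    anchors0: AnchorSet,
    epochs: int,
    cfg: AdaptationConfig | None = None,
    rng: np.random.Generator | None = None,
    cache: _FeatureCache | None = None,
) -> list[float]:
    """Supervised pretraining on the labeled source domain (anchors fixed).

    Returns the per-epoch mean losses; zero epochs leaves the detector
    untouched.
    """
    if not source_samples:
        raise ValueError("source set must be non-empty")
    cfg = cfg or AdaptationConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    cache = cache or _FeatureCache()
    return [
        _train_epoch(detector, source_samples, anchors0, cfg, rng, cache)
        for _ in range(epochs)
    ]


def self_training_round(
    state: RoundState,
    source_samples: Sequence[SubjectSample],
    target_samples: Sequence[SubjectSample],
    detector,
    cfg: AdaptationConfig,
    rng: np.random.Generator,
    cache: _FeatureCache,
) -> tuple[RoundState, dict]:
    """One alternating round; returns the next state and a log record."""
    spacing = source_samples[0].spacing if source_samples else (
        target_samples[0].spacing if target_samples else Spacing(1, 1, 1)
    )
    binning = cfg.binning
    lam = lambda_schedule(state.r, cfg.R, cfg.lam_start, cfg.lam_end)

    # Step 1: supervised source epoch with the current anchors
    src_loss = _train_epoch(detector, source_samples, state.anchors, cfg, rng, cache)

    # Step 2: target inference, cleaning, selection
    selected: dict[str, PseudoLabelSet] = {}
    unselected: dict[str, tuple[Box3D, ...]] = {}
    candidate_counts: list[int] = []
    candidate_boxes: list[Box3D] = []
    budget = subject_budget(state.prior, lam)
    for sample in target_samples:
        raw = _infer(detector, sample, state.anchors, cfg, cache)
        cands = clean_candidates(raw, cfg.tau, cfg.nms_iou, sample.subject_id)
        candidate_counts.append(len(cands.candidates))
        candidate_boxes.extend(d.box for d in cands.candidates)
        if cfg.selection == "prior_guided":
            pl = select_prior_guided(
                cands, state.prior, binning, spacing, lam, round_index=state.r
            )
            assert len(pl.boxes) <= budget, "pseudo labels exceeded the subject budget"
        else:
            pl = select_top_fraction(cands, cfg.top_fraction, round_index=state.r)
        selected[sample.subject_id] = pl
        # everything the detector sees but the quota does not admit has
        # unknown label status: it must not be trained as background
        chosen = set(pl.boxes)
        unselected[sample.subject_id] = tuple(
            d.box
            for d in raw
            if d.score >= cfg.ignore_floor and d.box not in chosen
        )

    union_boxes: list[Box3D] = [b for pl in selected.values() for b in pl.boxes]

    # prior updates (prior-guided arm only; skipped on an empty round).
    # Both mu and h are estimated from the cleaned candidates rather than
    # from the quota-capped selections: estimating the priors from their own
    # selections would be circular — the budget and quotas would then only
    # ever reproduce themselves (see docs/methods.md).
    prior = state.prior
    if cfg.selection == "prior_guided" and target_samples:
        prior = update_mu(prior, candidate_counts)
        binnable = [
            b for b in candidate_boxes
            if binning.edges[0] <= _volume_cc_of(b, spacing) < binning.edges[-1]
        ]
        if binnable:
            prior = update_histogram(
                prior, size_histogram(binnable, spacing, binning)
            )

    # anchor update from the cleaned target candidates (like mu and h, the
    # anchor shapes are target statistics estimated from the model's
    # confident predictions; the quota-capped selection is a biased sample
    # whose bin support shrinks with the budget)
    anchors = state.anchors
    if cfg.adapt_anchors and candidate_boxes:
        anchors = anchors_for_round(
            candidate_boxes, state.anchors, cfg.K, cfg.beta,
            seed=(cfg.seed * 100003 + state.r) % (2**31),
        )

    # supervised epoch on pseudo-labeled target subjects (non-empty sets only);
    # quota-declined candidates ride along as ignore regions
    pseudo_samples = [
        replace(
            s,
            boxes=selected[s.subject_id].boxes,
            ignore_boxes=unselected[s.subject_id],
            focus_radius=cfg.focus_radius,
        )
        for s in target_samples
        if selected[s.subject_id].boxes
    ]
    tgt_loss = _train_epoch(detector, pseudo_samples, anchors, cfg, rng, cache)

    record = {
        "round": state.r,
        "lambda": lam,
        "budget": budget,
        "mu": prior.mu,
        "h": list(prior.h),
        "anchors": [list(s) for s in anchors.shapes],
        "n_pseudo": len(union_boxes),
        "mean_candidates": float(np.mean(candidate_counts)) if candidate_counts else 0.0,
        "source_loss": src_loss,
        "target_loss": tgt_loss,
    }
    return RoundState(state.r + 1, prior, anchors, selected), record


def run_adaptation(
    source_samples: Sequence[SubjectSample],
    target_samples: Sequence[SubjectSample],
    cfg: AdaptationConfig,
    detector=None,
    skip_pretrain: bool = False,
    normalize: bool = True,
) -> AdaptationResult:
    """Pretrain on source, then run R alternating self-training rounds.

    All randomness flows from ``cfg.seed``; two runs with identical inputs
    and config produce identical pseudo-label, prior and anchor
    trajectories.  Only the final anchors are meant for target-domain test
    inference.
    """
    if not source_samples:
        raise ValueError("source set must be non-empty")
    if normalize:
        source_samples = [normalize_channels(s) for s in source_samples]
        target_samples = [normalize_channels(s) for s in target_samples]
    spacing = source_samples[0].spacing
    binning = cfg.binning

    all_source_boxes = [b for s in source_samples for b in s.boxes]
    if len(all_source_boxes) < cfg.K:
        raise InsufficientBoxesError(
            f"need at least K={cfg.K} source boxes to initialize anchors"
        )
    anchors0 = AnchorSet(
        tuple(map(tuple, kmeans_shapes(all_source_boxes, cfg.K, cfg.seed))),
        round_index=0,
    )
    prior0 = source_prior(
        [s.boxes for s in source_samples], spacing, binning,
        alpha_mu=cfg.alpha_mu, alpha_h=cfg.alpha_h,
    )

    if detector is None:
        detector = MinimalDetector(
            n_anchors=cfg.K, stride=cfg.stride, seed=cfg.seed, lr=cfg.lr,
        )
    rng = np.random.default_rng(cfg.seed)
    cache = _FeatureCache()

    if not skip_pretrain:
        pretrain_source(
            detector, source_samples, anchors0, cfg.epochs_pretrain, cfg, rng, cache
        )

    state = RoundState(0, prior0, anchors0)
    history: list[dict] = []
    for _ in range(cfg.R):
        state, record = self_training_round(
            state, source_samples, target_samples, detector, cfg, rng, cache
        )
        history.append(record)

    return AdaptationResult(
        detector=detector,
        anchors=state.anchors,
        prior=state.prior,
        history=history,
        state=state,
        initial_anchors=anchors0,
        initial_prior=prior0,
    )


def run_baseline_self_training(
    source_samples: Sequence[SubjectSample],
    target_samples: Sequence[SubjectSample],
    cfg: AdaptationConfig,
    detector=None,
    adapt_anchors: bool = False,
    skip_pretrain: bool = False,
) -> AdaptationResult:
    """Conventional self-training arm: top-50%-by-confidence selection.

    Priors are never updated in this arm; anchor adaptation is off by
    default (the "UDA adapted" comparison) and can be enabled to form the
    "UDA + anchor adaptation" arm.
    """
    base_cfg = replace(cfg, selection="top_fraction", adapt_anchors=adapt_anchors)
    return run_adaptation(
        source_samples, target_samples, base_cfg,
        detector=detector, skip_pretrain=skip_pretrain,
    )


class OracleDetector:
    """Diagnostic detector: ground truth at score 1 plus seeded low-score FPs.

    Implements the detection contract (via ``predict_subject``) so the
    adaptation loop can be exercised with a detector whose error structure
    is fully known — used to test that the online priors recover the true
    target lesion statistics.  False positives score strictly below 0.5, so
    the default confidence gate removes them; lowering ``tau`` exposes them.
    """

    def __init__(
        self,
        fp_rate: float = 3.0,
        fp_score_range: tuple[float, float] = (0.05, 0.45),
        seed: int = 0,
    ) -> None:
        self.fp_rate = fp_rate
        self.fp_score_range = fp_score_range
        self.seed = seed

    def train_step(self, batch, anchors, features=None) -> float:
        return 0.0

    def predict(self, volume, anchors) -> list[Detection]:
        raise NotImplementedError(
            "OracleDetector needs subject identity; use predict_subject"
        )

    def predict_subject(self, sample: SubjectSample, anchors: AnchorSet) -> list[Detection]:
        rng = np.random.default_rng(
            (zlib.crc32(sample.subject_id.encode()) + self.seed) % (2**31)
        )
        dets = [Detection(b, 1.0) for b in sample.boxes]
        shape = np.asarray(sample.pet.shape)
        for _ in range(int(rng.poisson(self.fp_rate))):
            extent = rng.uniform(2.0, 6.0, size=3)
            lo = rng.uniform(0, shape - extent)
            dets.append(
                Detection(
                    Box3D(*lo, *(lo + extent)),
                    float(rng.uniform(*self.fp_score_range)),
                )
            )
        return dets
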