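"""Pseudo-label selection: confidence gating, NMS cleaning and quota retention.

Raw target-domain detections are first cleaned (score gate at ``tau`` then 3D
NMS), producing a candidate set per subject.  Two selection rules then turn
candidates into pseudo labels: the conventional top-fraction-by-confidence
baseline, and the prior-guided rule that apportions a per-subject budget
across lesion-size bins so the selected labels track the estimated target
size composition instead of inheriting the source bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import math

from .geometry import Box3D, Detection, Spacing, nms3d
from .priors import SizeBinning, SizePrior, allocate_quotas, subject_budget


@dataclass(frozen=True)
class CandidateSet:
    """Cleaned detections for one subject (all scores >= tau, NMS applied)."""

    subject_id: str
    candidates: tuple[Detection, ...]


@dataclass(frozen=True)
class PseudoLabelSet:
    """Selected pseudo boxes for one subject at a given round (class 1)."""

    subject_id: str
    boxes: tuple[Box3D, ...]
    round_index: int = 0
    scores: tuple[float, ...] = field(default=())


def clean_candidates(
    raw: Sequence[Detection],
    tau: float = 0.5,
    nms_iou: float = 0.25,
    subject_id: str = "",
) -> CandidateSet:
    """Gate detections at ``tau`` (strictly below discarded) then apply NMS."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    gated = [d for d in raw if d.score >= tau]
    kept = nms3d(gated, nms_iou)
    return CandidateSet(subject_id=subject_id, candidates=tuple(kept))


def select_prior_guided(
    cands: CandidateSet,
    prior: SizePrior,
    binning: SizeBinning,
    spacing: Spacing,
    lam: float,
    round_index: int = 0,
) -> PseudoLabelSet:
    """Bin-wise quota selection driven by the target size prior.

    The subject budget ``floor(lam * mu)`` is apportioned across volume bins
    by the prior histogram (largest-remainder), then within each bin the
    top-scoring candidates up to that bin's quota are retained.  An
    under-filled bin keeps all its candidates; its unused quota is *not*
    transferred to other bins, so the selected size composition cannot drift
    back toward the abundant (source-like) bins.

    Candidates whose volume falls outside the binning range (sub-voxel
    slivers below the first edge) cannot be apportioned and are dropped.
    """
    budget = subject_budget(prior, lam)
    if budget == 0 or not cands.candidates:
        return PseudoLabelSet(cands.subject_id, (), round_index)
    quotas = allocate_quotas(prior.h_array, budget)

    by_bin: dict[int, list[tuple[int, Detection]]] = {}
    for idx, det in enumerate(cands.candidates):
        try:
            b = binning.bin_of_volume(_volume_cc(det.box, spacing))
        except ValueError:
            continue
        by_bin.setdefault(b, []).append((idx, det))

    chosen: list[tuple[int, Detection]] = []
    for b, members in by_bin.items():
        members.sort(key=lambda t: (-t[1].score, t[0]))  # stable: earlier wins ties
        chosen.extend(members[: quotas[b]])
    chosen.sort(key=lambda t: (-t[1].score, t[0]))
    return PseudoLabelSet(
        subject_id=cands.subject_id,
        boxes=tuple(d.box for _, d in chosen),
        round_index=round_index,
        scores=tuple(d.score for _, d in chosen),
    )


def select_top_fraction(
    cands: CandidateSet, p: float, round_index: int = 0
) -> PseudoLabelSet:
    """Conventional baseline: keep the top ``ceil(p * n)`` candidates by score.

    The ceiling rule means a subject with a single candidate still
    contributes one pseudo label at p=0.5; flooring would silence sparse
    subjects entirely.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    n_keep = math.ceil(p * len(cands.candidates))
    ranked = sorted(
        enumerate(cands.candidates), key=lambda t: (-t[1].score, t[0])
    )[:n_keep]
    return PseudoLabelSet(
        subject_id=cands.subject_id,
        boxes=tuple(d.box for _, d in ranked),
        round_index=round_index,
        scores=tuple(d.score for _, d in ranked),
    )


def lambda_schedule(
    r: int, R: int, lam_start: float = 0.1, lam_end: float = 0.8
) -> float:
    """Linear admission schedule over rounds, endpoints included.

    Round indexing is 0-based: lambda(0) = lam_start and
    lambda(R-1) = lam_end; a single-round schedule returns lam_start.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not (0 <= r < R):
        raise ValueError(f"round index {r} outside [0, {R})")
    if R == 1:
        return lam_start
    lam = lam_start + (lam_end - lam_start) * r / (R - 1)
    lo, hi = min(lam_start, lam_end), max(lam_start, lam_end)
    return float(min(max(lam, lo), hi))


def _volume_cc(box: Box3D, spacing: Spacing) -> float:
    return box.volume_voxels * spacing.voxel_volume_mm3 / 1000.0
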