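"""Lesion-level detection metrics: greedy matching, AP, and FROC analysis.

Matching is one-to-one: detections are processed in descending score order
and each claims the unclaimed ground-truth lesion it overlaps best (IoU at or
above the threshold); additional detections on an already-claimed lesion
count as false positives.  AP pools detections across subjects and
integrates the precision envelope of the PR curve; FROC reports pooled
lesion sensitivity against mean false positives per scan as the confidence
cutoff sweeps from high to low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import Box3D, Detection, iou3d


class UndefinedMetricError(ValueError):
    """Raised when a metric needs ground-truth lesions but none exist."""


@dataclass
class MatchResult:
    det_is_tp: np.ndarray  # (n_det,) bool
    det_matched_gt: np.ndarray  # (n_det,) int, -1 for false positives
    gt_detected: np.ndarray  # (n_gt,) bool


@dataclass
class EvalCurve:
    """FROC operating points with their score cutoffs (strictly decreasing)."""

    fp_per_subject: np.ndarray
    sensitivity: np.ndarray
    thresholds: np.ndarray


def match_detections(
    dets: Sequence[Detection], gts: Sequence[Box3D], iou_thr: float
) -> MatchResult:
    """Greedy score-descending one-to-one matching at an IoU threshold.

    Each detection claims the highest-IoU unclaimed ground truth with
    IoU >= ``iou_thr`` (ties broken toward the lower ground-truth index);
    score ties are broken by detection order, so the result is deterministic.
    """
    if not (0.0 < iou_thr <= 1.0):
        raise ValueError(f"iou_thr must lie in (0, 1], got {iou_thr}")
    n_det, n_gt = len(dets), len(gts)
    is_tp = np.zeros(n_det, dtype=bool)
    matched = np.full(n_det, -1, dtype=int)
    claimed = np.zeros(n_gt, dtype=bool)
    order = sorted(range(n_det), key=lambda i: (-dets[i].score, i))
    for i in order:
        best_j, best_iou = -1, 0.0
        for j in range(n_gt):
            if claimed[j]:
                continue
            v = iou3d(dets[i].box, gts[j])
            if v >= iou_thr and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            is_tp[i] = True
            matched[i] = best_j
            claimed[best_j] = True
    return MatchResult(is_tp, matched, claimed)


def _pooled_labels(
    per_subject: Sequence[tuple[Sequence[Detection], Sequence[Box3D]]],
    iou_thr: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Match per subject, pool (score, is_tp) pairs, sorted score-descending."""
    scores: list[float] = []
    flags: list[bool] = []
    n_gt = 0
    keys: list[tuple[int, int]] = []
    for si, (dets, gts) in enumerate(per_subject):
        n_gt += len(gts)
        result = match_detections(dets, gts, iou_thr)
        for di, det in enumerate(dets):
            scores.append(det.score)
            flags.append(bool(result.det_is_tp[di]))
            keys.append((si, di))
    if not scores:
        return np.array([]), np.array([], dtype=bool), n_gt
    # sort by score desc; ties by subject then detection index (deterministic)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], keys[i]))
    return (
        np.array([scores[i] for i in order]),
        np.array([flags[i] for i in order]),
        n_gt,
    )


def average_precision(
    per_subject: Sequence[tuple[Sequence[Detection], Sequence[Box3D]]],
    iou_thr: float,
) -> float:
    """Area under the pooled precision-recall curve (precision envelope).

    All-points interpolation: precision at each recall level is replaced by
    the maximum precision at any higher-or-equal recall before integrating,
    the standard continuous AP.  Undefined (raises) without ground truths;
    0.0 without detections.
    """
    scores, flags, n_gt = _pooled_labels(per_subject, iou_thr)
    if n_gt == 0:
        raise UndefinedMetricError("AP is undefined with zero ground-truth lesions")
    if scores.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # envelope: running max of precision from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def froc_curve(
    per_subject: Sequence[tuple[Sequence[Detection], Sequence[Box3D]]],
    iou_thr: float = 0.1,
) -> EvalCurve:
    """FROC: pooled sensitivity vs mean FPs per subject over score cutoffs.

    Matching is computed once per subject on the full score-ordered
    detection list; because greedy matching only depends on higher-scored
    detections, the matches of any score prefix coincide with the prefix of
    this matching, so sweeping the cutoff is a cumulative count.
    """
    n_subjects = len(per_subject)
    if n_subjects == 0:
        raise ValueError("need at least one subject")
    scores, flags, n_gt = _pooled_labels(per_subject, iou_thr)
    if n_gt == 0:
        raise UndefinedMetricError("FROC is undefined with zero ground-truth lesions")
    if scores.size == 0:
        return EvalCurve(np.array([0.0]), np.array([0.0]), np.array([np.inf]))
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    # one operating point per distinct score: last index at each score value
    last = np.flatnonzero(np.diff(scores, append=-np.inf) != 0)
    return EvalCurve(
        fp_per_subject=fp[last] / n_subjects,
        sensitivity=tp[last] / n_gt,
        thresholds=scores[last],
    )


def sensitivity_at_fp(curve: EvalCurve, fp_per_scan: float) -> float:
    """Best sensitivity among operating points within the FP budget; 0 if none."""
    if fp_per_scan < 0:
        raise ValueError("fp_per_scan must be non-negative")
    ok = curve.fp_per_subject <= fp_per_scan
    if not np.any(ok):
        return 0.0
    return float(curve.sensitivity[ok].max())
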