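"""Target-domain label priors: lesions-per-subject mean and size histogram.

The adaptation loop maintains two online statistics of the (unlabeled) target
domain: ``mu``, the mean number of lesions per subject, and ``h``, a
normalized histogram over ``B`` lesion-volume bins (cc).  Both are updated
every round by exponential moving averages and turned into per-subject,
per-bin pseudo-label quotas by the largest-remainder apportionment rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .geometry import Box3D, Spacing, box_volume_cc


class EmptyHistogramError(ValueError):
    """No boxes to histogram this round; the caller skips the EMA update."""


@dataclass(frozen=True)
class SizeBinning:
    """Half-open volume bins ``[edges[i], edges[i+1])`` in cc.

    ``edges`` has B+1 strictly increasing entries; the last is typically
    ``inf`` so every volume above the working range falls in the open top bin.
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2:
            raise ValueError("need at least two edges (one bin)")
        if not np.all(np.diff(e) > 0):
            raise ValueError(f"edges must be strictly increasing: {self.edges}")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_of_volume(self, volume_cc: float) -> int:
        """0-based index of the bin containing ``volume_cc``."""
        if volume_cc < self.edges[0] or volume_cc >= self.edges[-1]:
            raise ValueError(
                f"volume {volume_cc} cc outside binning range "
                f"[{self.edges[0]}, {self.edges[-1]})"
            )
        # np.searchsorted(side='right') puts a volume equal to an interior
        # edge into the higher bin, matching the half-open convention.
        return int(np.searchsorted(np.asarray(self.edges), volume_cc, side="right") - 1)


def default_binning(
    n_bins: int = 10, vmin: float = 0.08, vmax: float = 150.0
) -> SizeBinning:
    """Log-spaced bins from the sub-voxel floor (0.08 cc) up to 150 cc.

    The final bin is the open interval [150 cc, inf), mirroring the
    "very large (>=150 cc)" category used to describe the FDG tail; interior
    edges are geometrically spaced, which resolves the small-lesion regime
    where the cross-tracer shift concentrates.
    """
    edges = np.geomspace(vmin, vmax, n_bins).tolist() + [math.inf]
    return SizeBinning(tuple(edges))


@dataclass(frozen=True)
class SizePrior:
    """EMA state of the target priors: count mean ``mu`` and histogram ``h``."""

    mu: float
    h: tuple[float, ...]
    alpha_mu: float = 0.9
    alpha_h: float = 0.9

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be non-negative, got {self.mu}")
        hv = np.asarray(self.h, dtype=float)
        if np.any(hv < 0) or abs(hv.sum() - 1.0) > 1e-9:
            raise ValueError("h must be non-negative and sum to 1")
        for a in (self.alpha_mu, self.alpha_h):
            if not (0.0 < a < 1.0):
                raise ValueError(f"EMA momentum must lie in (0, 1), got {a}")

    @property
    def h_array(self) -> np.ndarray:
        return np.asarray(self.h, dtype=float)


def bin_of(box: Box3D, spacing: Spacing, binning: SizeBinning) -> int:
    """Map a box to its (0-based) volume bin under the working spacing."""
    return binning.bin_of_volume(box_volume_cc(box, spacing))


def size_histogram(
    boxes: Sequence[Box3D], spacing: Spacing, binning: SizeBinning
) -> np.ndarray:
    """Normalized per-bin counts of box volumes; raises on empty input."""
    if len(boxes) == 0:
        raise EmptyHistogramError("cannot histogram an empty box set")
    counts = np.zeros(binning.n_bins)
    for b in boxes:
        counts[bin_of(b, spacing, binning)] += 1
    return counts / counts.sum()


def update_mu(prior: SizePrior, per_subject_counts: Sequence[int]) -> SizePrior:
    """EMA update of the lesions-per-subject mean toward the round's estimate.

    mu_new = (1 - alpha_mu) * mu_old + alpha_mu * mean(counts); the result is
    a convex combination, so it always lies between the old mean and the new
    round estimate.
    """
    counts = np.asarray(per_subject_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one subject count")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    mu_new = (1.0 - prior.alpha_mu) * prior.mu + prior.alpha_mu * float(counts.mean())
    return replace(prior, mu=mu_new)


def subject_budget(prior: SizePrior, lam: float) -> int:
    """Per-subject pseudo-label cap ``ceil(lambda * mu)``.

    The budget exists to stop scans with many false positives from
    dominating later rounds; the ceiling still bounds admission by
    ``lambda * mu + 1`` while guaranteeing that a fractional budget keeps at
    least one admission slot open.  Flooring instead would shut selection
    off entirely whenever ``lambda * mu < 1`` — with few lesions per subject
    (or early, conservative lambda) that starves self-training of target
    updates altogether, which is an artifact of integerization rather than
    a property of the admission cap.
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"lambda must lie in (0, 1], got {lam}")
    return int(math.ceil(lam * prior.mu))


def update_histogram(prior: SizePrior, h_hat: Sequence[float]) -> SizePrior:
    """EMA update of the size histogram, L1-renormalized.

    h_new = normalize((1 - alpha_h) * h_old + alpha_h * h_hat).  When both
    terms are already normalized the renormalization is a no-op; it guards
    against numerical drift over many rounds.
    """
    h_hat = np.asarray(h_hat, dtype=float)
    if h_hat.shape != (len(prior.h),):
        raise ValueError(f"h_hat must have length {len(prior.h)}, got {h_hat.shape}")
    if np.any(h_hat < 0) or abs(h_hat.sum() - 1.0) > 1e-6:
        raise ValueError("h_hat must be non-negative and sum to 1")
    mix = (1.0 - prior.alpha_h) * prior.h_array + prior.alpha_h * h_hat
    mix = mix / mix.sum()
    return replace(prior, h=tuple(mix.tolist()))


def allocate_quotas(h: Sequence[float], n_allow: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n_allow`` slots across bins.

    Fractional quotas ``h_b * n_allow`` are floored and the remaining slots
    go to the bins with the largest fractional parts, so the integer quotas
    sum exactly to the budget and each differs from its fractional quota by
    less than one.  Ties on fractional part favour the lower bin index
    (smaller lesions), which is deterministic and biases toward the
    small-lesion regime this selection scheme targets.
    """
    h = np.asarray(h, dtype=float)
    if n_allow < 0:
        raise ValueError("n_allow must be non-negative")
    if np.any(h < 0) or abs(h.sum() - 1.0) > 1e-6:
        raise ValueError("h must be normalized")
    frac = h * n_allow
    quotas = np.floor(frac).astype(int)
    remaining = int(n_allow - quotas.sum())
    if remaining > 0:
        remainders = frac - quotas
        # stable sort on (-remainder, bin index): ties go to smaller bins
        order = np.lexsort((np.arange(len(h)), -remainders))
        quotas[order[:remaining]] += 1
    return quotas


def source_prior(
    boxes_per_subject: Sequence[Sequence[Box3D]],
    spacing: Spacing,
    binning: SizeBinning,
    alpha_mu: float = 0.9,
    alpha_h: float = 0.9,
) -> SizePrior:
    """Initialize the prior from labeled source statistics.

    h(0) is the source size histogram over the shared bins; mu(0) is the
    source mean lesions-per-subject (the natural analogue, chosen because
    the source is the only labeled estimate available before round 1).
    """
    all_boxes = [b for subj in boxes_per_subject for b in subj]
    mu0 = len(all_boxes) / max(len(boxes_per_subject), 1)
    if all_boxes:
        h0 = size_histogram(all_boxes, spacing, binning)
    else:
        h0 = np.full(binning.n_bins, 1.0 / binning.n_bins)
    return SizePrior(mu=mu0, h=tuple(h0.tolist()), alpha_mu=alpha_mu, alpha_h=alpha_h)
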