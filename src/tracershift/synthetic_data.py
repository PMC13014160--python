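"""Seeded dual-channel volume simulator emulating a cross-tracer label shift.

Each synthetic subject is a two-channel 3D volume: a PET-like channel with
soft ellipsoidal lesion uptake blobs plus unlabeled high-uptake "physiology"
distractor blobs (the analogue of brain/myocardium uptake under FDG and
salivary-gland/kidney uptake under PSMA), and a CT-like channel of smooth
anatomical background with bumps co-located with the physiological
distractors.  Lesion count is Poisson per subject and lesion volume is
log-normal, so the two built-in domain specs realize both a covariate shift
(contrast, noise, distractor pressure) and a label shift (more, smaller
lesions in the PSMA-like domain; a heavier very-large-lesion tail in the
FDG-like domain).

Distractors are deliberately absent from the label mask: they are
false-positive bait that the per-subject pseudo-label budget is meant to cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import Box3D, Spacing, clip_box, filter_small_boxes, masks_to_boxes

DEFAULT_SPACING = Spacing(4.0, 4.0, 5.0)
MIN_LESION_CC = 0.08


@dataclass(frozen=True)
class DomainSpec:
    """Generator parameters for one tracer-like domain.

    ``log_volume_mean``/``log_volume_sd`` parametrize a log-normal over lesion
    volume in cc (natural log); the remaining fields control appearance
    (covariate) properties.
    """

    name: str
    lesion_rate: float  # Poisson mean lesions per subject
    log_volume_mean: float  # ln(cc)
    log_volume_sd: float
    lesion_contrast: float  # PET uptake amplitude of lesions (z-score units)
    n_distractors: int  # physiological high-uptake blobs per subject
    distractor_intensity: float
    noise_sd: float  # additive Gaussian noise on the PET channel
    background_uptake: float = 0.0  # amplitude of smooth uptake clutter (haze)

    def __post_init__(self) -> None:
        if self.lesion_rate <= 0 or self.lesion_contrast <= 0:
            raise ValueError("lesion rate and contrast must be positive")


def default_domain_specs() -> tuple[DomainSpec, DomainSpec]:
    """The built-in FDG-like source and PSMA-like target domains.

    The PSMA-like spec has twice the lesion rate and a ~4x smaller median
    lesion volume (1.8 cc vs 8 cc), while the FDG-like spec's wider
    log-volume spread places visibly more mass in the very-large (>=150 cc)
    regime — the label shift.  The covariate shift is carried by appearance:
    the PSMA-like domain has lower lesion contrast, an extra physiological
    distractor, and markedly stronger structured background-uptake clutter
    (smooth haze blobs that z-score normalization cannot remove), so a
    source-trained model faces both unfamiliar clutter and unfamiliar lesion
    sizes on the target.
    """
    fdg = DomainSpec(
        name="fdg",
        lesion_rate=3.0,
        log_volume_mean=math.log(8.0),
        log_volume_sd=1.4,
        lesion_contrast=4.0,
        n_distractors=2,
        distractor_intensity=6.0,
        noise_sd=0.5,
        background_uptake=0.3,
    )
    psma = DomainSpec(
        name="psma",
        lesion_rate=6.0,
        log_volume_mean=math.log(1.8),
        log_volume_sd=1.0,
        lesion_contrast=3.5,
        n_distractors=3,
        distractor_intensity=6.0,
        noise_sd=0.5,
        background_uptake=0.4,
    )
    return fdg, psma


@dataclass(eq=False)
class SubjectSample:
    """One synthetic subject: PET + CT channels, spacing, labels.

    ``ignore_boxes`` is empty for generated (fully labeled) subjects; the
    adaptation loop fills it on pseudo-labeled copies with confident
    detections that the selection quota declined, so they are excluded from
    the negative class during training.
    """

    subject_id: str
    pet: np.ndarray
    ct: np.ndarray
    spacing: Spacing
    boxes: tuple[Box3D, ...]
    mask: np.ndarray
    domain: str = ""
    n_lesions_drawn: int = 0
    ignore_boxes: tuple[Box3D, ...] = ()
    focus_radius: float | None = None  # if set, negatives only near boxes

    def volume(self) -> np.ndarray:
        """Stacked (2, H, W, Z) input volume (PET first)."""
        return np.stack([self.pet, self.ct])


def _ellipsoid_patch(
    shape: Sequence[int], center: np.ndarray, semi: np.ndarray
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Normalized squared ellipsoid distance rho^2 on a tight subvolume."""
    lo = np.maximum(np.floor(center - semi - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi + 2).astype(int), np.asarray(shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grids = np.meshgrid(
        *[np.arange(s.start, s.stop) + 0.5 for s in sl], indexing="ij"
    )
    rho2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return sl, rho2


def generate_subject(
    spec: DomainSpec,
    shape: Sequence[int] = (48, 48, 48),
    spacing: Spacing = DEFAULT_SPACING,
    seed: int = 0,
    subject_id: str | None = None,
) -> SubjectSample:
    """Draw one subject: lesions, distractors, CT background, noise, labels.

    Deterministic for a fixed seed.  Lesion centers are rejection-sampled
    away from already-placed lesions so labeled lesions stay distinct
    connected components; ground-truth boxes are derived from the rasterized
    mask and passed through the 0.08 cc minimum-volume filter, exactly as a
    real annotation mask would be converted.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError(f"volume must be at least 32 voxels per axis, got {shape}")
    rng = np.random.default_rng(seed)
    vox_cc = spacing.voxel_volume_mm3 / 1000.0

    # CT-like channel: smooth anatomical gradient, independent of lesions
    ct = ndimage.gaussian_filter(rng.normal(size=shape), sigma=6.0)
    ct *= 1.0 / max(ct.std(), 1e-8)
    zgrad = np.linspace(-0.5, 0.5, shape[2])[None, None, :]
    ct = ct + zgrad

    pet = np.zeros(shape, dtype=float)
    mask = np.zeros(shape, dtype=np.int16)

    # structured background-uptake clutter: smooth positive haze whose blobby
    # texture survives z-scoring (unlike a global contrast change)
    if spec.background_uptake > 0:
        haze = ndimage.gaussian_filter(np.abs(rng.normal(size=shape)), sigma=3.0)
        haze /= max(haze.std(), 1e-8)
        pet += spec.background_uptake * haze

    # physiological distractors: hot on PET, bump on CT, absent from the mask
    for _ in range(spec.n_distractors):
        center = rng.uniform(4.0, np.asarray(shape) - 4.0)
        radius = rng.uniform(1.5, 3.5)
        sl, rho2 = _ellipsoid_patch(shape, center, np.full(3, radius))
        pet[sl] += spec.distractor_intensity * np.exp(-2.0 * rho2)
        ct[sl] += 2.0 * np.exp(-rho2)

    n_lesions = int(rng.poisson(spec.lesion_rate))
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n_lesions):
        vol_cc = float(
            np.exp(rng.normal(spec.log_volume_mean, spec.log_volume_sd))
        )
        vol_cc = min(vol_cc, 400.0)  # keep the largest lesions inside the field
        # equivalent-sphere radius in mm, mild per-axis anisotropy
        r_mm = (3.0 * vol_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        anis = rng.uniform(0.8, 1.25, size=3)
        anis /= np.prod(anis) ** (1.0 / 3.0)
        semi = r_mm * anis / np.array([spacing.dx, spacing.dy, spacing.dz])
        semi = np.clip(semi, 0.6, np.asarray(shape) / 2.0 - 2.0)

        margin = semi + 1.5
        center = None
        for _ in range(25):
            cand = rng.uniform(margin, np.asarray(shape) - margin)
            if all(
                np.any(np.abs(cand - c) > (semi + s + 1.0)) for c, s in placed
            ):
                center = cand
                break
        if center is None:
            center = rng.uniform(margin, np.asarray(shape) - margin)
        placed.append((center, semi))

        sl, rho2 = _ellipsoid_patch(shape, center, semi)
        pet[sl] += spec.lesion_contrast * np.exp(-2.0 * rho2)
        region = mask[sl]
        region[rho2 <= 1.0] = i + 1
        # a sub-voxel lesion must still occupy its nearest voxel
        cidx = tuple(np.clip(center.astype(int), 0, np.asarray(shape) - 1))
        if mask[cidx] == 0:
            mask[cidx] = i + 1

    pet += rng.normal(0.0, spec.noise_sd, size=shape)
    ct += rng.normal(0.0, 0.2, size=shape)

    boxes = tuple(
        filter_small_boxes(masks_to_boxes(mask), spacing, MIN_LESION_CC)
    )
    return SubjectSample(
        subject_id=subject_id or f"{spec.name}-{seed}",
        pet=pet,
        ct=ct,
        spacing=spacing,
        boxes=boxes,
        mask=mask,
        domain=spec.name,
        n_lesions_drawn=n_lesions,
    )


def generate_dataset(
    spec: DomainSpec,
    n_subjects: int,
    shape: Sequence[int] = (48, 48, 48),
    spacing: Spacing = DEFAULT_SPACING,
    seed: int = 0,
) -> list[SubjectSample]:
    """Generate a cohort; per-subject seeds are spawned from the master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    return [
        generate_subject(
            spec,
            shape=shape,
            spacing=spacing,
            seed=int(child.generate_state(1)[0] % (2**31)),
            subject_id=f"{spec.name}-{i:04d}",
        )
        for i, child in enumerate(children)
    ]


def split_dataset(
    n: int, fractions: tuple[float, float, float], seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded disjoint train/val/test index split with round-to-nearest sizes.

    Split sizes are ``round(n * fraction)`` with any rounding remainder
    applied to the largest split, so the sizes always sum to ``n`` (for 369
    subjects at 70/10/20 this yields 258/37/74).
    """
    if n < 1:
        raise ValueError("n must be positive")
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0):
        raise ValueError("fractions must be non-negative and sum to 1")
    sizes = np.rint(n * fr).astype(int)
    sizes[np.argmax(sizes)] += n - sizes.sum()
    if np.any(sizes < 0):
        raise ValueError("fractions incompatible with n")
    perm = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return perm[:a], perm[a:b], perm[b:]


def normalize_channels(sample: SubjectSample) -> SubjectSample:
    """Z-score each channel independently; a constant channel maps to zeros."""

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        if sd < 1e-12:
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    return replace(sample, pet=zscore(sample.pet), ct=zscore(sample.ct))


def random_crop(
    sample: SubjectSample, size: Sequence[int], seed: int = 0
) -> SubjectSample:
    """Uniformly random crop with label bookkeeping.

    Boxes are intersected with the crop window and translated to crop
    coordinates; a box retaining less than 50% of its original volume is
    dropped from the crop's labels (a mostly-truncated lesion is a poor
    regression target).
    """
    size = tuple(int(s) for s in size)
    shape = sample.pet.shape
    if any(s > d for s, d in zip(size, shape)):
        raise ValueError(f"crop size {size} exceeds volume shape {shape}")
    rng = np.random.default_rng(seed)
    corner = np.array([rng.integers(0, d - s + 1) for s, d in zip(size, shape)])
    sl = tuple(slice(int(c), int(c + s)) for c, s in zip(corner, size))

    new_boxes = []
    for box in sample.boxes:
        shifted = Box3D(
            box.x0 - corner[0],
            box.y0 - corner[1],
            box.z0 - corner[2],
            box.x1 - corner[0],
            box.y1 - corner[1],
            box.z1 - corner[2],
        )
        clipped = clip_box(shifted, size)
        if clipped is not None and clipped.volume_voxels >= 0.5 * box.volume_voxels:
            new_boxes.append(clipped)

    return replace(
        sample,
        pet=sample.pet[sl].copy(),
        ct=sample.ct[sl].copy(),
        mask=sample.mask[sl].copy(),
        boxes=tuple(new_boxes),
    )
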