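"""Axis-aligned 3D box arithmetic for volumetric lesion detection.

Boxes live in voxel coordinates with a half-open convention
``[x0, x1) x [y0, y1) x [z0, z1)``, so a one-voxel lesion at index
``(i, j, k)`` has the box ``(i, j, k, i+1, j+1, k+1)`` and box volume in
voxels is exactly the product of extents.  Physical volumes (cc) enter only
through a :class:`Spacing`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage


class InvalidBoxError(ValueError):
    """Raised when a box has non-positive extent or non-finite coordinates."""


@dataclass(frozen=True)
class Spacing:
    """Voxel edge lengths in millimetres along x, y, z."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"spacing must be strictly positive, got {self}")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.dx * self.dy * self.dz


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned box in voxel coordinates, half-open on every axis."""

    x0: float
    y0: float
    z0: float
    x1: float
    y1: float
    z1: float

    def __post_init__(self) -> None:
        coords = (self.x0, self.y0, self.z0, self.x1, self.y1, self.z1)
        if not all(np.isfinite(c) for c in coords):
            raise InvalidBoxError(f"non-finite box coordinates: {coords}")
        if not (self.x1 > self.x0 and self.y1 > self.y0 and self.z1 > self.z0):
            raise InvalidBoxError(f"box must have positive extent on every axis: {coords}")

    @property
    def extents(self) -> np.ndarray:
        """Edge lengths (w, h, d) in voxels."""
        return np.array([self.x1 - self.x0, self.y1 - self.y0, self.z1 - self.z0])

    @property
    def center(self) -> np.ndarray:
        return np.array(
            [(self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0, (self.z0 + self.z1) / 2.0]
        )

    @property
    def volume_voxels(self) -> float:
        return float(np.prod(self.extents))

    def as_array(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.z0, self.x1, self.y1, self.z1], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "Box3D":
        return Box3D(*(float(v) for v in a))

    @staticmethod
    def from_center_extent(center: Sequence[float], extent: Sequence[float]) -> "Box3D":
        c = np.asarray(center, dtype=float)
        e = np.asarray(extent, dtype=float)
        lo = c - e / 2.0
        hi = c + e / 2.0
        return Box3D(lo[0], lo[1], lo[2], hi[0], hi[1], hi[2])


@dataclass(frozen=True)
class Detection:
    """A candidate lesion: a box plus a confidence score in [0, 1]."""

    box: Box3D
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


def iou3d(a: Box3D, b: Box3D) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, symmetric."""
    ix = min(a.x1, b.x1) - max(a.x0, b.x0)
    iy = min(a.y1, b.y1) - max(a.y0, b.y0)
    iz = min(a.z1, b.z1) - max(a.z0, b.z0)
    if ix <= 0 or iy <= 0 or iz <= 0:
        return 0.0
    inter = ix * iy * iz
    union = a.volume_voxels + b.volume_voxels - inter
    return float(inter / union)


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two (N, 6) and (M, 6) arrays of box coordinates."""
    a = np.atleast_2d(np.asarray(boxes_a, dtype=float))
    b = np.atleast_2d(np.asarray(boxes_b, dtype=float))
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    lo = np.maximum(a[:, None, :3], b[None, :, :3])
    hi = np.minimum(a[:, None, 3:], b[None, :, 3:])
    inter = np.prod(np.clip(hi - lo, 0.0, None), axis=-1)
    vol_a = np.prod(a[:, 3:] - a[:, :3], axis=-1)
    vol_b = np.prod(b[:, 3:] - b[:, :3], axis=-1)
    union = vol_a[:, None] + vol_b[None, :] - inter
    return inter / union


def nms3d(dets: Sequence[Detection], iou_thr: float) -> list[Detection]:
    """Greedy score-descending non-maximum suppression.

    Every retained pair has IoU strictly below ``iou_thr``.  Ties on score are
    broken by insertion order (earlier detection wins), so the output is
    deterministic.  Output is sorted by score descending.
    """
    if not (0.0 < iou_thr < 1.0):
        raise ValueError(f"iou_thr must lie in (0, 1), got {iou_thr}")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept: list[Detection] = []
    for i in order:
        d = dets[i]
        if all(iou3d(d.box, k.box) < iou_thr for k in kept):
            kept.append(d)
    return kept


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def masks_to_boxes(mask: np.ndarray) -> list[Box3D]:
    """Tight bounding boxes of connected foreground components of a label field.

    Components are found with 26-connectivity on ``mask > 0`` (diagonal
    contact merges), so touching lesions with different label values become a
    single box, matching how a reader would delineate one contiguous region.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {mask.shape}")
    if np.any(mask < 0):
        raise ValueError("mask values must be non-negative")
    labeled, n = ndimage.label(mask > 0, structure=_STRUCT_26)
    boxes: list[Box3D] = []
    for sl in ndimage.find_objects(labeled):
        if sl is None:  # pragma: no cover - find_objects contract
            continue
        (sx, sy, sz) = sl
        boxes.append(Box3D(sx.start, sy.start, sz.start, sx.stop, sy.stop, sz.stop))
    return boxes


def box_volume_cc(box: Box3D, spacing: Spacing) -> float:
    """Physical box volume in cubic centimetres (1 cc = 1000 mm^3)."""
    return box.volume_voxels * spacing.voxel_volume_mm3 / 1000.0


def filter_small_boxes(
    boxes: Iterable[Box3D], spacing: Spacing, min_cc: float
) -> list[Box3D]:
    """Drop boxes with physical volume strictly below ``min_cc``; keep order.

    The discard rule is strict: a box of exactly ``min_cc`` is retained
    (one voxel at 4 x 4 x 5 mm is 0.08 cc and survives the default filter).
    """
    if min_cc < 0:
        raise ValueError(f"min_cc must be non-negative, got {min_cc}")
    return [b for b in boxes if box_volume_cc(b, spacing) >= min_cc]


def clip_box(box: Box3D, shape: Sequence[int]) -> Box3D | None:
    """Intersect a box with the volume ``[0, shape)``; None if empty."""
    x0 = max(box.x0, 0.0)
    y0 = max(box.y0, 0.0)
    z0 = max(box.z0, 0.0)
    x1 = min(box.x1, float(shape[0]))
    y1 = min(box.y1, float(shape[1]))
    z1 = min(box.z1, float(shape[2]))
    if x1 <= x0 or y1 <= y0 or z1 <= z0:
        return None
    return Box3D(x0, y0, z0, x1, y1, z1)


# ---------------------------------------------------------------------------
# serialization: JSON-lines box records and NIfTI volumes


def write_boxes_jsonl(path: str | Path, records: Iterable[dict]) -> None:
    """Write box records (subject_id, x0..z1, optional score/round) as JSON-lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_boxes_jsonl(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def box_record(subject_id: str, box: Box3D, score: float | None = None, **extra) -> dict:
    rec = {
        "subject_id": subject_id,
        "x0": box.x0,
        "y0": box.y0,
        "z0": box.z0,
        "x1": box.x1,
        "y1": box.y1,
        "z1": box.z1,
    }
    if score is not None:
        rec["score"] = float(score)
    rec.update(extra)
    return rec


def record_to_box(rec: dict) -> Box3D:
    return Box3D(rec["x0"], rec["y0"], rec["z0"], rec["x1"], rec["y1"], rec["z1"])


def write_volume_nifti(path: str | Path, volume: np.ndarray, spacing: Spacing) -> None:
    import nibabel as nib

    affine = np.diag([spacing.dx, spacing.dy, spacing.dz, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def read_volume_nifti(path: str | Path) -> tuple[np.ndarray, Spacing]:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj, dtype=np.float32), Spacing(*map(float, zooms))
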