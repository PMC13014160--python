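"""Anchor-shape estimation and cross-round exponential-moving-average updates.

Anchor shapes (w, h, d extents in voxels) are estimated by k-means on box
extents — first on the labeled source boxes, then each adaptation round on
the union of selected target pseudo boxes — and blended across rounds by an
EMA so a single noisy round cannot reshape the anchor set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .geometry import Box3D


class InsufficientBoxesError(ValueError):
    """Fewer boxes than clusters; callers fall back to the previous anchors."""


@dataclass(frozen=True)
class AnchorSet:
    """K anchor extents in voxels, sorted by volume ascending."""

    shapes: tuple[tuple[float, float, float], ...]
    round_index: int = 0

    def __post_init__(self) -> None:
        if len(self.shapes) < 1:
            raise ValueError("need at least one anchor shape")
        arr = np.asarray(self.shapes, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("anchor extents must be strictly positive")

    @property
    def K(self) -> int:
        return len(self.shapes)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.shapes, dtype=float)


def _sorted_by_volume(shapes: np.ndarray) -> np.ndarray:
    return shapes[np.argsort(np.prod(shapes, axis=1), kind="stable")]


def kmeans_shapes(boxes: Sequence[Box3D], K: int, seed: int) -> np.ndarray:
    """Cluster box extents with k-means (k-means++, Euclidean, fixed seed).

    Returns the K centroid extents sorted by volume ascending.  Deterministic
    for a fixed seed and input order.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(boxes) < K:
        raise InsufficientBoxesError(f"{len(boxes)} boxes < K={K}")
    extents = np.stack([b.extents for b in boxes])
    if K == 1:
        return extents.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=seed)
    km.fit(extents)
    return _sorted_by_volume(km.cluster_centers_)


def ema_update_anchors(
    prev: AnchorSet, new_shapes: np.ndarray, beta: float
) -> AnchorSet:
    """Blend fresh k-means centroids into the anchor set.

    s_k <- (1 - beta) * s_k + beta * s~_k after pairing previous anchors with
    new centroids one-to-one by minimum total squared distance (the pairing
    is not given by either estimate alone: centroid volumes can cross between
    rounds, and nearest-neighbour pairing would then double-assign).
    """
    new_shapes = np.asarray(new_shapes, dtype=float)
    if new_shapes.shape != (prev.K, 3):
        raise ValueError(f"expected {prev.K} shapes, got {new_shapes.shape}")
    if not (0.0 < beta < 1.0):
        raise ValueError(f"beta must lie in (0, 1), got {beta}")
    prev_arr = prev.array
    cost = ((prev_arr[:, None, :] - new_shapes[None, :, :]) ** 2).sum(axis=-1)
    rows, cols = linear_sum_assignment(cost)
    blended = (1.0 - beta) * prev_arr[rows] + beta * new_shapes[cols]
    blended = _sorted_by_volume(blended)
    return AnchorSet(tuple(map(tuple, blended)), round_index=prev.round_index + 1)


def anchors_for_round(
    selected_boxes: Sequence[Box3D],
    prev: AnchorSet,
    K: int,
    beta: float,
    seed: int,
) -> AnchorSet:
    """One round of anchor adaptation from the union of selected pseudo boxes.

    If the union holds fewer than K boxes there is nothing to cluster and the
    previous anchors are carried over unchanged.
    """
    try:
        fresh = kmeans_shapes(selected_boxes, K, seed)
    except InsufficientBoxesError:
        return prev
    return ema_update_anchors(prev, fresh, beta)
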