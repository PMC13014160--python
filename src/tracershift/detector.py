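"""Anchor-based 3D detection: losses, anchor assignment, and a reference model.

The training/inference contract (:class:`DetectorContract`) is deliberately
small — ``train_step`` on labeled crops and ``predict`` on a volume — so the
adaptation loop is agnostic to the backbone.  The bundled
:class:`MinimalDetector` is a lightweight CPU reference implementation: it
scores K anchors at every stride-spaced grid point using hand-crafted
multiscale local statistics of the PET/CT channels (means, maxima,
uptake-weighted centre-of-mass offsets and second moments) fed into
per-anchor linear classification and box-regression heads, trained with the
standard focal + smooth-L1 detection loss via Adam.  It is fully
deterministic for a fixed seed and fast enough to run hundreds of
self-training rounds on one CPU.

Box regression uses the common anchor parametrization: three centre offsets
normalized by the anchor extents and three log extent ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from .anchors import AnchorSet
from .geometry import Box3D, Detection, clip_box, iou_matrix, nms3d

_EPS = 1e-7


# ---------------------------------------------------------------------------
# box <-> regression-target parametrization


def encode_boxes(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """(N, 6) boxes against (N, 6) anchors -> (N, 6) regression targets."""
    boxes = np.atleast_2d(boxes)
    anchors = np.atleast_2d(anchors)
    bc = (boxes[:, :3] + boxes[:, 3:]) / 2.0
    be = boxes[:, 3:] - boxes[:, :3]
    ac = (anchors[:, :3] + anchors[:, 3:]) / 2.0
    ae = anchors[:, 3:] - anchors[:, :3]
    return np.concatenate([(bc - ac) / ae, np.log(be / ae)], axis=1)


def decode_boxes(t: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_boxes`; exact round trip to float precision."""
    t = np.atleast_2d(t)
    anchors = np.atleast_2d(anchors)
    ac = (anchors[:, :3] + anchors[:, 3:]) / 2.0
    ae = anchors[:, 3:] - anchors[:, :3]
    bc = t[:, :3] * ae + ac
    be = np.exp(np.clip(t[:, 3:], -8.0, 8.0)) * ae
    return np.concatenate([bc - be / 2.0, bc + be / 2.0], axis=1)


# ---------------------------------------------------------------------------
# anchor grid and assignment


def build_anchor_grid(
    volume_shape: Sequence[int], stride: int, anchors: AnchorSet
) -> np.ndarray:
    """Tile K anchors at every stride-spaced grid point; clip to the volume.

    Returns an (n_points * K, 6) array ordered position-major (the K anchors
    of one grid point are contiguous), matching the head-output layout of
    :class:`MinimalDetector`.
    """
    shape = np.asarray(volume_shape, dtype=float)
    centers = [
        (np.arange(int(d) // stride) + 0.5) * stride for d in volume_shape
    ]
    grid = np.stack(
        np.meshgrid(*centers, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    shapes = anchors.array  # (K, 3)
    lo = grid[:, None, :] - shapes[None, :, :] / 2.0
    hi = grid[:, None, :] + shapes[None, :, :] / 2.0
    boxes = np.concatenate([lo, hi], axis=-1).reshape(-1, 6)
    boxes[:, :3] = np.clip(boxes[:, :3], 0.0, shape - 1.0)
    boxes[:, 3:] = np.clip(boxes[:, 3:], 1.0, shape)
    return boxes


@dataclass
class AnchorAssignment:
    """Per-anchor class (+1 positive / 0 negative / -1 ignore) and targets."""

    labels: np.ndarray  # (N,) int8
    matched_gt: np.ndarray  # (N,) int, -1 where unmatched
    reg_targets: np.ndarray  # (N, 6), zeros for non-positives


def assign_anchors(
    anchor_boxes: np.ndarray,
    gt_boxes: Sequence[Box3D],
    iou_pos: float = 0.5,
    iou_neg: float = 0.4,
    ignore_boxes: Sequence[Box3D] = (),
) -> AnchorAssignment:
    """RetinaNet-style assignment with best-match forcing.

    An anchor is positive when its best IoU reaches ``iou_pos`` *or* it is
    the best anchor for some ground truth (so every lesion owns at least one
    positive anchor even when all overlaps are poor); negative below
    ``iou_neg``; ignored in between.

    ``ignore_boxes`` mark regions whose label status is unknown rather than
    background — in pseudo-label training these are confident detections the
    selection quota declined to admit.  Negative anchors overlapping an
    ignore box (IoU >= 0.25) are excluded from the classification loss, so a
    capped admission budget caps what is *learned from*, without actively
    teaching the detector that the remaining candidates are background.
    """
    if iou_neg > iou_pos:
        raise ValueError("iou_neg must not exceed iou_pos")
    n = anchor_boxes.shape[0]
    labels = np.zeros(n, dtype=np.int8)
    matched = np.full(n, -1, dtype=int)
    targets = np.zeros((n, 6))

    def _mask_ignore() -> None:
        if len(ignore_boxes) == 0:
            return
        ign_arr = np.stack([b.as_array() for b in ignore_boxes])
        ign_iou = iou_matrix(anchor_boxes, ign_arr).max(axis=1)
        labels[(labels == 0) & (ign_iou >= 0.25)] = -1

    if len(gt_boxes) == 0:
        _mask_ignore()
        return AnchorAssignment(labels, matched, targets)

    gt_arr = np.stack([b.as_array() for b in gt_boxes])
    iou = iou_matrix(anchor_boxes, gt_arr)  # (N, M)
    best_iou = iou.max(axis=1)
    best_gt = iou.argmax(axis=1)

    labels[best_iou >= iou_pos] = 1
    labels[(best_iou < iou_neg)] = 0
    labels[(best_iou >= iou_neg) & (best_iou < iou_pos)] = -1
    # force the argmax anchor of every ground truth to be positive
    forced = iou.argmax(axis=0)
    labels[forced] = 1
    matched[labels == 1] = best_gt[labels == 1]
    matched[forced] = np.arange(gt_arr.shape[0])

    _mask_ignore()
    pos = labels == 1
    targets[pos] = encode_boxes(gt_arr[matched[pos]], anchor_boxes[pos])
    return AnchorAssignment(labels, matched, targets)


# ---------------------------------------------------------------------------
# loss components (vectorized; scalar use is the common test path)


def focal_loss(
    p: np.ndarray | float,
    c: np.ndarray | int,
    gamma: float = 2.0,
    alpha_bal: float = 0.25,
) -> np.ndarray | float:
    """Focal loss -alpha_t (1 - p_t)^gamma log p_t; elementwise.

    With gamma=0 and alpha_bal=1 this reduces exactly to binary
    cross-entropy.  Probabilities are clamped away from {0, 1}.
    """
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    c = np.asarray(c)
    p_t = np.where(c == 1, p, 1.0 - p)
    a_t = np.where(c == 1, alpha_bal, 1.0 - alpha_bal)
    out = -a_t * (1.0 - p_t) ** gamma * np.log(p_t)
    return float(out) if out.ndim == 0 else out


def _focal_grad_logit(
    p: np.ndarray, c: np.ndarray, gamma: float, alpha_bal: float
) -> np.ndarray:
    """d focal / d logit, derived in closed form (verified against FD in tests)."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    p_t = np.where(c == 1, p, 1.0 - p)
    a_t = np.where(c == 1, alpha_bal, 1.0 - alpha_bal)
    s = np.where(c == 1, 1.0, -1.0)
    return s * a_t * (1.0 - p_t) ** gamma * (gamma * p_t * np.log(p_t) - (1.0 - p_t))


def smooth_l1(
    t: np.ndarray, t_hat: np.ndarray, delta: float = 1.0
) -> float:
    """Huber-style regression loss summed over components.

    Quadratic (0.5 d^2) for |d| < delta, linear (delta |d| - 0.5 delta^2)
    beyond, so single outlying components cannot dominate the gradient.
    """
    t = np.asarray(t, dtype=float)
    t_hat = np.asarray(t_hat, dtype=float)
    if t.shape != t_hat.shape:
        raise ValueError("t and t_hat must have equal shapes")
    d = np.abs(t - t_hat)
    per = np.where(d < delta, 0.5 * d * d, delta * d - 0.5 * delta * delta)
    return float(per.sum())


def _smooth_l1_grad(residual: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Gradient w.r.t. the prediction for residual = prediction - target."""
    return np.clip(residual, -delta, delta)


def detection_loss(
    cls_probs: np.ndarray,
    reg_pred: np.ndarray,
    assignment: AnchorAssignment,
    gamma: float = 2.0,
    alpha_bal: float = 0.25,
) -> float:
    """Focal sum over non-ignored anchors + smooth-L1 sum over positives.

    Both terms are normalized by the number of positive anchors (min 1),
    which keeps magnitudes comparable across crops with very different
    lesion counts.
    """
    labels = assignment.labels
    active = labels >= 0
    n_pos = max(int((labels == 1).sum()), 1)
    cls_term = float(
        np.sum(focal_loss(cls_probs[active], labels[active], gamma, alpha_bal))
    )
    pos = labels == 1
    reg_term = (
        smooth_l1(assignment.reg_targets[pos], reg_pred[pos]) if pos.any() else 0.0
    )
    return cls_term / n_pos + reg_term / n_pos


# ---------------------------------------------------------------------------
# detector contract and the reference implementation


@runtime_checkable
class DetectorContract(Protocol):
    """Behavioral contract the adaptation loop relies on."""

    def train_step(self, batch: Sequence, anchors: AnchorSet) -> float: ...

    def predict(self, volume: np.ndarray, anchors: AnchorSet) -> list[Detection]: ...


class MinimalDetector:
    """CPU reference detector: multiscale features + a small shared MLP trunk.

    A one-hidden-layer network (ReLU, ``n_hidden`` units) over the grid
    features feeds per-anchor classification and box-regression heads; all
    gradients are computed in closed form.

    Parameters
    ----------
    n_anchors:
        K, the number of anchor shapes scored at each grid point.
    stride:
        Grid spacing in voxels; features are sampled at grid-cell centres.
    seed:
        Seeds the hidden-layer initialization (heads start at zero with a
        background-biased classification offset).
    """

    MEAN_SCALES = (3, 7, 15)  # box-filter means of the PET channel
    RESPONSE_SCALES = (3, 5)  # matched-filter (local-mean) responses, max-pooled
    COM_SCALES = (9, 15)  # uptake-weighted centre-of-mass offset windows
    VAR_SCALES = (9, 15)  # uptake second-moment (size cue) windows

    def __init__(
        self,
        n_anchors: int = 3,
        stride: int = 4,
        seed: int = 0,
        lr: float = 1e-2,
        n_hidden: int = 64,
        gamma: float = 2.0,
        alpha_bal: float = 0.25,
        score_floor: float = 0.05,
        nms_iou: float = 0.25,
        max_detections: int = 200,
    ) -> None:
        self.K = int(n_anchors)
        self.stride = int(stride)
        self.seed = int(seed)
        self.lr = float(lr)
        self.H = int(n_hidden)
        self.gamma = float(gamma)
        self.alpha_bal = float(alpha_bal)
        self.score_floor = float(score_floor)
        self.nms_iou = float(nms_iou)
        self.max_detections = int(max_detections)
        self.d = self._n_features() + 1  # +1 bias feature
        rng = np.random.default_rng(seed)
        hb = self.H + 1  # hidden activations + bias unit
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / self.d), size=(self.H, self.d)),
            "W_cls": np.zeros((self.K, hb)),
            "W_reg": np.zeros((self.K, 6, hb)),
        }
        # bias toward background so the untrained model is quiet everywhere
        self.params["W_cls"][:, -1] = -3.0
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- features ----------------------------------------------------------

    def _n_features(self) -> int:
        pet_feats = 1 + len(self.MEAN_SCALES) + len(self.RESPONSE_SCALES)
        ct_feats = 1 + 2
        com = 3 * len(self.COM_SCALES)
        second_moment = 3 * len(self.VAR_SCALES)
        return pet_feats + ct_feats + com + second_moment

    def feature_volumes(self, volume: np.ndarray) -> np.ndarray:
        """(2, H, W, Z) input -> (d-1, H, W, Z) feature stack (no bias).

        The response features are dense matched filters (box-filter means at
        blob scales) max-pooled over a window one voxel wider than the grid
        stride, so a small high-uptake blob anywhere between grid points
        still produces a strong response at its nearest grid centre.  The
        centre-of-mass and second-moment features of thresholded uptake give
        the regression head direct position and size cues.
        """
        if volume.ndim != 4 or volume.shape[0] != 2:
            raise ValueError(
                f"expected a (2, H, W, Z) PET+CT volume, got shape {volume.shape}"
            )
        pet = np.asarray(volume[0], dtype=float)
        ct = np.asarray(volume[1], dtype=float)
        pool = self.stride + 1
        feats: list[np.ndarray] = [pet]
        for s in self.MEAN_SCALES:
            feats.append(ndimage.uniform_filter(pet, s))
        for s in self.RESPONSE_SCALES:
            feats.append(
                ndimage.maximum_filter(ndimage.uniform_filter(pet, s), pool)
            )
        feats.append(ct)
        for s in (3, 7):
            feats.append(ndimage.uniform_filter(ct, s))

        pos = np.maximum(ndimage.uniform_filter(pet, 3), 0.0)
        coords = np.meshgrid(
            *[np.arange(n, dtype=float) for n in pet.shape], indexing="ij"
        )
        m0 = {s: ndimage.uniform_filter(pos, s) + 1e-6 for s in self.COM_SCALES}
        m1: dict[tuple[int, int], np.ndarray] = {}
        for s in self.COM_SCALES:
            for ax, g in enumerate(coords):
                m1[(s, ax)] = ndimage.uniform_filter(pos * g, s)
                com = m1[(s, ax)] / m0[s] - g
                feats.append(np.clip(com, -s, s) / s)
        for s in self.VAR_SCALES:
            for ax, g in enumerate(coords):
                m2 = ndimage.uniform_filter(pos * g * g, s)
                mean = m1[(s, ax)] / m0[s]
                var = np.clip(m2 / m0[s] - mean * mean, 0.0, None)
                feats.append(np.log1p(var) / 4.0)
        return np.stack(feats)

    def grid_features(self, volume: np.ndarray) -> np.ndarray:
        """Features sampled at the anchor-grid centres: (n_points, d)."""
        fv = self.feature_volumes(volume)
        idx = [
            (np.arange(n // self.stride) * self.stride + self.stride // 2)
            for n in volume.shape[1:]
        ]
        sub = fv[np.ix_(np.arange(fv.shape[0]), *idx)]
        flat = sub.reshape(fv.shape[0], -1).T  # (P, d-1)
        bias = np.ones((flat.shape[0], 1))
        return np.concatenate([flat, bias], axis=1)

    # -- forward / backward ------------------------------------------------

    def _forward(self, F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (hidden activations with bias, probs (P,K), t_pred (P,K,6))."""
        A = F @ self.params["W1"].T  # (P, H) pre-activation
        Hb = np.concatenate([np.maximum(A, 0.0), np.ones((F.shape[0], 1))], axis=1)
        logits = Hb @ self.params["W_cls"].T  # (P, K)
        probs = 1.0 / (1.0 + np.exp(-logits))
        t_pred = np.einsum("ph,keh->pke", Hb, self.params["W_reg"])  # (P, K, 6)
        self._last_A = A
        return Hb, probs, t_pred

    def train_step(
        self,
        batch: Sequence,
        anchors: AnchorSet,
        features: Sequence[np.ndarray] | None = None,
    ) -> float:
        """One Adam step on a batch of samples; returns the mean batch loss.

        ``batch`` items need ``volume()`` and ``boxes`` (any SubjectSample-
        like object).  Precomputed ``grid_features`` outputs may be supplied
        to skip featurization of unchanged volumes.
        """
        if anchors.K != self.K:
            raise ValueError(f"anchor set has K={anchors.K}, detector expects {self.K}")
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        total_loss = 0.0
        for bi, sample in enumerate(batch):
            vol = sample.volume()
            F = features[bi] if features is not None else self.grid_features(vol)
            anchor_boxes = build_anchor_grid(vol.shape[1:], self.stride, anchors)
            assignment = assign_anchors(
                anchor_boxes,
                list(sample.boxes),
                ignore_boxes=list(getattr(sample, "ignore_boxes", ())),
            )
            focus = getattr(sample, "focus_radius", None)
            if focus is not None and len(sample.boxes) > 0:
                # partial-annotation training: keep negatives only near the
                # (sparse) labeled boxes; far-field background has unknown
                # label status on incompletely labeled volumes
                centers = (anchor_boxes[:, :3] + anchor_boxes[:, 3:]) / 2.0
                box_centers = np.stack([b.center for b in sample.boxes])
                cheb = np.abs(centers[:, None, :] - box_centers[None, :, :]).max(-1)
                far = cheb.min(axis=1) > focus
                assignment.labels[(assignment.labels == 0) & far] = -1
            labels = assignment.labels.reshape(-1, self.K)
            Hb, probs, t_pred = self._forward(F)
            A = self._last_A
            n_pos = max(int((labels == 1).sum()), 1)

            # classification gradient (zero on ignored anchors)
            g_z = _focal_grad_logit(probs, labels, self.gamma, self.alpha_bal)
            g_z = np.where(labels >= 0, g_z, 0.0) / n_pos
            grads["W_cls"] += g_z.T @ Hb
            g_hidden = g_z @ self.params["W_cls"][:, : self.H]  # (P, H)

            # regression gradient on positives
            pos_mask = labels == 1
            if pos_mask.any():
                targets = assignment.reg_targets.reshape(-1, self.K, 6)
                residual = np.where(
                    pos_mask[:, :, None], t_pred - targets, 0.0
                )
                g_t = _smooth_l1_grad(residual) / n_pos
                grads["W_reg"] += np.einsum("pke,ph->keh", g_t, Hb)
                g_hidden += np.einsum(
                    "pke,keh->ph", g_t, self.params["W_reg"][:, :, : self.H]
                )

            grads["W1"] += (g_hidden * (A > 0)).T @ F

            total_loss += detection_loss(
                probs.reshape(-1),
                t_pred.reshape(-1, 6),
                assignment,
                self.gamma,
                self.alpha_bal,
            )

        nb = max(len(batch), 1)
        for k in grads:
            grads[k] /= nb
        self._adam_step(grads)
        return total_loss / nb

    def _adam_step(self, grads: dict, b1: float = 0.9, b2: float = 0.999) -> None:
        self._adam_t += 1
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            m_hat = self._adam_m[k] / (1 - b1**self._adam_t)
            v_hat = self._adam_v[k] / (1 - b2**self._adam_t)
            self.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + 1e-8)

    # -- inference ---------------------------------------------------------

    def predict(
        self,
        volume: np.ndarray,
        anchors: AnchorSet,
        features: np.ndarray | None = None,
    ) -> list[Detection]:
        """Score the anchor grid, decode boxes, gate at the score floor, NMS.

        Deterministic for fixed parameters and input.  NMS (IoU 0.25) is
        applied here so direct and sliding-window inference agree on volumes
        that fit in a single window.
        """
        if anchors.K != self.K:
            raise ValueError(f"anchor set has K={anchors.K}, detector expects {self.K}")
        F = features if features is not None else self.grid_features(volume)
        anchor_boxes = build_anchor_grid(volume.shape[1:], self.stride, anchors)
        _, probs, t_pred = self._forward(F)
        scores = probs.reshape(-1)
        t_flat = t_pred.reshape(-1, 6)
        keep = np.flatnonzero(scores >= self.score_floor)
        if keep.size > self.max_detections:
            order = np.lexsort((keep, -scores[keep]))
            keep = keep[order[: self.max_detections]]
        decoded = decode_boxes(t_flat[keep], anchor_boxes[keep])
        dets: list[Detection] = []
        for row, idx in zip(decoded, keep):
            try:
                box = Box3D.from_array(row)
            except ValueError:
                continue
            clipped = clip_box(box, volume.shape[1:])
            if clipped is None:
                continue
            dets.append(Detection(clipped, float(scores[idx])))
        return nms3d(dets, self.nms_iou)

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = np.asarray(v, dtype=float).copy()

    def clone(self) -> "MinimalDetector":
        other = MinimalDetector(
            n_anchors=self.K,
            stride=self.stride,
            seed=self.seed,
            lr=self.lr,
            n_hidden=self.H,
            gamma=self.gamma,
            alpha_bal=self.alpha_bal,
            score_floor=self.score_floor,
            nms_iou=self.nms_iou,
            max_detections=self.max_detections,
        )
        other.load_state_dict(self.state_dict())
        # carry the optimizer state so continued training does not restart
        # with full-size bias-corrected steps that jolt a calibrated model
        other._adam_m = {k: v.copy() for k, v in self._adam_m.items()}
        other._adam_v = {k: v.copy() for k, v in self._adam_v.items()}
        other._adam_t = self._adam_t
        return other


def sliding_window_predict(
    detector,
    volume: np.ndarray,
    window: Sequence[int],
    overlap_fraction: float,
    anchors: AnchorSet,
) -> list[Detection]:
    """Tile the volume, predict per window, shift to global frame, merge.

    Overlapping windows see boundary lesions whole; the final NMS (IoU 0.25)
    removes the duplicate detections this produces.
    """
    window = tuple(int(w) for w in window)
    shape = volume.shape[1:]
    if any(w > d for w, d in zip(window, shape)):
        raise ValueError(f"window {window} exceeds volume shape {shape}")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")

    starts_per_axis = []
    for w, d in zip(window, shape):
        step = max(int(round(w * (1.0 - overlap_fraction))), 1)
        starts = list(range(0, max(d - w, 0) + 1, step))
        if starts[-1] != d - w:
            starts.append(d - w)
        starts_per_axis.append(sorted(set(starts)))

    merged: list[Detection] = []
    for sx in starts_per_axis[0]:
        for sy in starts_per_axis[1]:
            for sz in starts_per_axis[2]:
                sub = volume[:, sx : sx + window[0], sy : sy + window[1], sz : sz + window[2]]
                for det in detector.predict(sub, anchors):
                    b = det.box
                    merged.append(
                        Detection(
                            Box3D(
                                b.x0 + sx, b.y0 + sy, b.z0 + sz,
                                b.x1 + sx, b.y1 + sy, b.z1 + sz,
                            ),
                            det.score,
                        )
                    )
    if not merged:
        return []
    return nms3d(merged, detector.nms_iou if hasattr(detector, "nms_iou") else 0.25)
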