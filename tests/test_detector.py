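import numpy as np
import pytest

from tracershift import (
    AnchorSet,
    Box3D,
    Detection,
    MinimalDetector,
    assign_anchors,
    build_anchor_grid,
    decode_boxes,
    detection_loss,
    encode_boxes,
    focal_loss,
    iou3d,
    sliding_window_predict,
    smooth_l1,
)
from tracershift.detector import AnchorAssignment, _focal_grad_logit
from tracershift.synthetic_data import default_domain_specs, generate_subject, normalize_channels

ANCHORS = AnchorSet(((4.0, 4.0, 4.0), (7.0, 7.0, 6.0), (12.0, 12.0, 10.0)))


class TestBoxRegression:
    def test_roundtrip_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.uniform(10, 30, 3)
            boxes = np.concatenate([c - rng.uniform(1, 8, 3), c + rng.uniform(1, 8, 3)])
            a = rng.uniform(8, 32, 3)
            anchors = np.concatenate([a - rng.uniform(1, 8, 3), a + rng.uniform(1, 8, 3)])
            t = encode_boxes(boxes, anchors)
            back = decode_boxes(t, anchors)
            assert np.allclose(back, np.atleast_2d(boxes), atol=1e-6)

    def test_identical_box_and_anchor_encode_to_zero(self):
        b = np.array([2.0, 3.0, 4.0, 8.0, 9.0, 10.0])
        assert np.allclose(encode_boxes(b, b), 0.0)


class TestAnchorGrid:
    def test_single_grid_point(self):
        grid = build_anchor_grid((8, 8, 8), stride=8, anchors=ANCHORS)
        assert grid.shape == (3, 6)

    def test_grid_counting(self):
        grid = build_anchor_grid((16, 16, 16), stride=8, anchors=ANCHORS)
        assert grid.shape == (24, 6)

    def test_volume_sized_anchor_covers_volume(self):
        one = AnchorSet(((8.0, 8.0, 8.0),))
        grid = build_anchor_grid((8, 8, 8), stride=8, anchors=one)
        assert np.allclose(grid, [[0, 0, 0, 8, 8, 8]])

    def test_anchors_clipped_to_bounds(self):
        grid = build_anchor_grid((16, 16, 16), stride=8, anchors=ANCHORS)
        assert grid[:, :3].min() >= 0.0
        assert grid[:, 3:].max() <= 16.0


class TestAssignAnchors:
    def test_exact_match_is_positive(self):
        anchors = np.array([[0, 0, 0, 4, 4, 4], [20, 20, 20, 24, 24, 24.0]])
        out = assign_anchors(anchors, [Box3D(0, 0, 0, 4, 4, 4)])
        assert out.labels[0] == 1

    def test_no_ground_truth_all_negative(self):
        anchors = np.array([[0, 0, 0, 4, 4, 4.0]])
        out = assign_anchors(anchors, [])
        assert np.all(out.labels == 0)

    def test_threshold_band_is_ignored(self):
        gt = Box3D(0, 0, 0, 10, 10, 10)
        band = [0, 0, 0, 10, 10, 4.6]  # IoU 0.46: between 0.4 and 0.5
        best = [0, 0, 0, 10, 10, 10.0]  # claims the forced-positive slot
        out = assign_anchors(np.array([band, best]), [gt])
        assert out.labels[0] == -1
        assert out.labels[1] == 1

    def test_every_ground_truth_owns_a_positive(self):
        rng = np.random.default_rng(4)
        anchors = build_anchor_grid((32, 32, 32), stride=8, anchors=ANCHORS)
        gts = [
            Box3D.from_center_extent(rng.uniform(6, 26, 3), rng.uniform(2, 6, 3))
            for _ in range(4)
        ]
        out = assign_anchors(anchors, gts)
        assert set(out.matched_gt[out.labels == 1]) >= set(range(len(gts)))

    def test_ignore_boxes_mask_negatives(self):
        anchors = np.array([[0, 0, 0, 4, 4, 4.0], [20, 20, 20, 24, 24, 24.0]])
        out = assign_anchors(anchors, [], ignore_boxes=[Box3D(0, 0, 0, 4, 4, 4)])
        assert out.labels[0] == -1
        assert out.labels[1] == 0


class TestFocalLoss:
    def test_confident_correct_is_near_zero(self):
        assert focal_loss(0.9999, 1) < 1e-6

    def test_reduces_to_cross_entropy(self):
        for p, c in [(0.3, 1), (0.3, 0), (0.8, 1)]:
            ce = -np.log(p if c == 1 else 1 - p)
            assert focal_loss(p, c, gamma=0.0, alpha_bal=1.0 if c == 1 else 0.0) == (
                pytest.approx(ce if c == 1 else ce)
            )

    def test_hand_evaluated_example(self):
        # alpha * (1-p)^2 * (-log p) = 0.25 * 0.25 * ln 2
        assert focal_loss(0.5, 1, gamma=2.0, alpha_bal=0.25) == pytest.approx(
            0.25 * 0.25 * np.log(2)
        )

    def test_monotone_decreasing_in_pt(self):
        ps = np.linspace(0.05, 0.95, 50)
        losses = focal_loss(ps, np.ones_like(ps, dtype=int))
        assert np.all(np.diff(losses) < 0)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 100)
        c = rng.integers(0, 2, 100)
        assert np.all(focal_loss(p, c) >= 0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            z = rng.uniform(-3, 3)
            c = int(rng.integers(0, 2))
            p = 1 / (1 + np.exp(-z))
            eps = 1e-6
            pp = 1 / (1 + np.exp(-(z + eps)))
            pm = 1 / (1 + np.exp(-(z - eps)))
            fd = (focal_loss(pp, c) - focal_loss(pm, c)) / (2 * eps)
            ana = _focal_grad_logit(np.array(p), np.array(c), 2.0, 0.25)
            assert ana == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestSmoothL1:
    def test_zero_at_equality(self):
        t = np.arange(6.0)
        assert smooth_l1(t, t) == 0.0

    def test_quadratic_region(self):
        assert smooth_l1(np.array([0.5]), np.array([0.0])) == pytest.approx(0.125)

    def test_linear_region(self):
        assert smooth_l1(np.array([2.0]), np.array([0.0])) == pytest.approx(1.5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            smooth_l1(np.zeros(6), np.zeros(5))


class TestDetectionLoss:
    def test_no_positives_means_no_regression_term(self):
        assignment = AnchorAssignment(
            labels=np.zeros(4, dtype=np.int8),
            matched_gt=np.full(4, -1),
            reg_targets=np.zeros((4, 6)),
        )
        probs = np.full(4, 1e-6)
        loss = detection_loss(probs, np.ones((4, 6)), assignment)
        assert loss == pytest.approx(float(np.sum(focal_loss(probs, 0))), abs=1e-9)

    def test_perfect_predictions_near_zero(self):
        assignment = AnchorAssignment(
            labels=np.array([1, 0], dtype=np.int8),
            matched_gt=np.array([0, -1]),
            reg_targets=np.zeros((2, 6)),
        )
        loss = detection_loss(np.array([1 - 1e-9, 1e-9]), np.zeros((2, 6)), assignment)
        assert loss < 1e-6

    def test_two_anchor_composition_oracle(self):
        targets = np.zeros((2, 6))
        targets[0] = 0.3
        assignment = AnchorAssignment(
            labels=np.array([1, 0], dtype=np.int8),
            matched_gt=np.array([0, -1]),
            reg_targets=targets,
        )
        probs = np.array([0.8, 0.3])
        preds = np.zeros((2, 6))
        expected = (
            focal_loss(0.8, 1) + focal_loss(0.3, 0) + smooth_l1(targets[0], preds[0])
        )  # normalized by n_pos = 1
        assert detection_loss(probs, preds, assignment) == pytest.approx(expected)

    def test_ignored_anchors_excluded(self):
        assignment = AnchorAssignment(
            labels=np.array([1, -1], dtype=np.int8),
            matched_gt=np.array([0, -1]),
            reg_targets=np.zeros((2, 6)),
        )
        loss_with_bad_ignored = detection_loss(
            np.array([0.9, 0.9]), np.zeros((2, 6)), assignment
        )
        assert loss_with_bad_ignored == pytest.approx(float(focal_loss(0.9, 1)))


@pytest.fixture(scope="module")
def overfit_setup():
    """One labeled subject plus a detector trained to memorize it."""
    fdg, _ = default_domain_specs()
    sample = normalize_channels(generate_subject(fdg, shape=(48, 48, 48), seed=7))
    assert sample.boxes  # seed chosen to contain lesions
    det = MinimalDetector(n_anchors=3, seed=0)
    feats = det.grid_features(sample.volume())
    losses = [det.train_step([sample], ANCHORS, features=[feats]) for _ in range(200)]
    return sample, det, losses


class TestMinimalDetector:
    def test_untrained_on_noise_is_quiet(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(2, 32, 32, 32))
        det = MinimalDetector(n_anchors=3, seed=0)
        assert det.predict(vol, ANCHORS) == []

    def test_overfit_recovers_ground_truth(self, overfit_setup):
        sample, det, _ = overfit_setup
        dets = det.predict(sample.volume(), ANCHORS)
        for gt in sample.boxes:
            assert max(iou3d(d.box, gt) for d in dets[:10]) >= 0.5

    def test_overfit_loss_decreases(self, overfit_setup):
        _, _, losses = overfit_setup
        assert losses[-1] < 0.5 * losses[0]

    def test_predict_is_deterministic(self, overfit_setup):
        sample, det, _ = overfit_setup
        a = det.predict(sample.volume(), ANCHORS)
        b = det.predict(sample.volume(), ANCHORS)
        assert a == b

    def test_clone_preserves_behaviour(self, overfit_setup):
        sample, det, _ = overfit_setup
        assert det.clone().predict(sample.volume(), ANCHORS) == det.predict(
            sample.volume(), ANCHORS
        )

    def test_anchor_count_mismatch_raises(self, overfit_setup):
        sample, det, _ = overfit_setup
        with pytest.raises(ValueError):
            det.predict(sample.volume(), AnchorSet(((4.0, 4.0, 4.0),)))

    def test_wrong_channel_count_raises(self):
        det = MinimalDetector(n_anchors=3, seed=0)
        with pytest.raises(ValueError):
            det.feature_volumes(np.zeros((3, 16, 16, 16)))


class _PeakStub:
    """Reports a fixed-size box at the brightest voxel of the PET channel."""

    nms_iou = 0.25

    def predict(self, volume, anchors):
        pet = volume[0]
        idx = np.unravel_index(np.argmax(pet), pet.shape)
        if pet[idx] < 1.0:
            return []
        box = Box3D.from_center_extent(np.asarray(idx, dtype=float) + 0.5, (4, 4, 4))
        return [Detection(box, float(min(pet[idx] / 10.0, 1.0)))]


class TestSlidingWindow:
    def test_window_equal_to_volume_matches_direct(self, overfit_setup):
        sample, det, _ = overfit_setup
        vol = sample.volume()
        windowed = sliding_window_predict(det, vol, vol.shape[1:], 0.5, ANCHORS)
        assert windowed == det.predict(vol, ANCHORS)

    def test_seam_lesion_detected_once(self):
        vol = np.zeros((2, 32, 16, 16))
        vol[0, 16, 8, 8] = 5.0  # bright voxel exactly on the window seam
        dets = sliding_window_predict(_PeakStub(), vol, (16, 16, 16), 0.5, ANCHORS)
        assert len(dets) == 1
        assert abs(dets[0].box.center[0] - 16.5) < 1.0

    def test_zero_overlap_disjoint_tiles_union(self):
        vol = np.zeros((2, 32, 16, 16))
        vol[0, 4, 8, 8] = 5.0
        vol[0, 24, 8, 8] = 7.0
        dets = sliding_window_predict(_PeakStub(), vol, (16, 16, 16), 0.0, ANCHORS)
        assert len(dets) == 2

    def test_oversized_window_raises(self):
        with pytest.raises(ValueError):
            sliding_window_predict(_PeakStub(), np.zeros((2, 8, 8, 8)), (16, 8, 8), 0.0, ANCHORS)
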