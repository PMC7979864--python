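"""Detector contracts: parameter counting against a closed-form layer-list
oracle, the two losses, blob post-processing as a left inverse of target
rendering, tiled inference, training mechanics, background extraction and
brood detection."""

import numpy as np
import pytest

from combtrack import detector, nn
from combtrack.detector import (DetectorConfig, ORIGINAL_WIDTHS, angle_loss,
                                build_brood_network, build_network, class_loss,
                                detect_brood, extract_background, fine_tune,
                                infer_tiled, maps_to_detections)
from combtrack.targets import (BeeAnnotation, BeeGeometry, BroodAnnotation,
                               SegmentationTarget, render_bee_targets,
                               render_brood_targets)

GEOM = BeeGeometry()


def closed_form_parameter_count(widths, n_classes=3, recurrent=True, in_ch=1):
    """Spreadsheet-style oracle: enumerate every convolution and sum
    k*k*c_in*c_out + c_out, independently of the network implementation."""
    def conv(ci, co, k=3):
        return k * k * ci * co + co

    def norm(c):  # instance norm: gain + bias per channel
        return 2 * c

    total = 0
    prev = in_ch
    for w in widths:                      # encoder: two (conv + norm) per level
        total += conv(prev, w) + norm(w) + conv(w, w) + norm(w)
        prev = w
    for hi, lo in zip(widths[::-1], widths[-2::-1]):  # decoder per level:
        total += conv(hi, lo) + norm(lo)  # up-conv after upsampling
        total += conv(2 * lo, lo) + norm(lo) + conv(lo, lo) + norm(lo)
    head_in = widths[0] * (2 if recurrent else 1)
    # class head plus the two-channel (sin, cos) orientation head
    total += conv(head_in, n_classes, k=1) + conv(head_in, 2, k=1)
    return total


class TestNetwork:
    def test_parameter_count_matches_closed_form_oracle(self):
        for widths, rec in [((8, 16), True), ((16, 32, 64), False),
                            (ORIGINAL_WIDTHS, False)]:
            cfg = DetectorConfig(encoder_widths=widths, recurrent=rec)
            model = build_network(cfg)
            assert model.count_parameters() == closed_form_parameter_count(
                widths, recurrent=rec)

    def test_reduced_recurrent_network_is_94_percent_smaller(self):
        reduced = build_network(DetectorConfig())  # 16..256, recurrent
        original = build_network(DetectorConfig(encoder_widths=ORIGINAL_WIDTHS,
                                                recurrent=False))
        ratio = reduced.count_parameters() / original.count_parameters()
        assert ratio <= 0.07

    def test_forward_shapes_and_recurrent_prior(self):
        cfg = DetectorConfig(encoder_widths=(4, 8), recurrent=True)
        model = build_network(cfg)
        img = np.random.default_rng(0).random((32, 32))
        logits, angle, prior = model.forward(img)
        assert logits.shape == (3, 32, 32) and angle.shape == (32, 32)
        logits2, _, _ = model.forward(img, prior)
        # a non-zero prior changes the head input, hence the output
        assert not np.allclose(logits, logits2)

    def test_mismatched_prior_shape_rejected(self):
        model = build_network(DetectorConfig(encoder_widths=(4, 8)))
        img = np.zeros((32, 32))
        with pytest.raises(ValueError, match="prior"):
            model.forward(img, np.zeros((1, 4, 16, 16)))

    def test_widths_must_increase(self):
        with pytest.raises(ValueError):
            DetectorConfig(encoder_widths=(16, 16))


class TestLosses:
    def test_perfect_prediction_has_near_zero_class_loss(self):
        classes = np.random.default_rng(1).integers(0, 3, (8, 8))
        logits = np.full((3, 8, 8), -50.0)
        for k in range(3):
            logits[k][classes == k] = 50.0
        assert class_loss(logits, classes) < 1e-12

    def test_uniform_prediction_gives_ln3(self):
        assert class_loss(np.zeros((3, 4, 4)), np.zeros((4, 4), int)) == \
            pytest.approx(np.log(3))

    def test_class_loss_linear_in_weights(self):
        rng = np.random.default_rng(2)
        logits = rng.standard_normal((3, 4, 4))
        classes = rng.integers(0, 3, (4, 4))
        w = rng.random((4, 4)) + 0.5
        assert class_loss(logits, classes, 2 * w) == \
            pytest.approx(2 * class_loss(logits, classes, w))

    def test_invalid_class_label_rejected(self):
        with pytest.raises(ValueError):
            class_loss(np.zeros((3, 2, 2)), np.full((2, 2), 3))

    @pytest.mark.parametrize("delta,expected", [(0, 0.0), (180, 1.0), (90, 0.5)])
    def test_angle_loss_reference_points(self, delta, expected):
        target = np.full((3, 3), 40.0)
        pred = target + delta
        assert angle_loss(pred, target) == pytest.approx(expected)

    def test_angle_loss_period_and_symmetry(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(0, 360, (5, 5))
        target = rng.uniform(0, 360, (5, 5))
        assert angle_loss(pred + 360, target) == pytest.approx(angle_loss(pred, target))
        assert angle_loss(pred, target + 360) == pytest.approx(angle_loss(pred, target))
        assert angle_loss(target, pred) == pytest.approx(angle_loss(pred, target))

    def test_empty_foreground_defined_as_zero(self):
        assert angle_loss(np.zeros((4, 4)), np.full((4, 4), -1.0)) == 0.0


class TestMapsToDetections:
    CFG = DetectorConfig(encoder_widths=(8, 16))

    def test_small_blob_discarded(self):
        cls = np.zeros((32, 32), int)
        cls[5:6, 5:10] = 1  # 5 px
        ang = np.where(cls > 0, 0.0, -1.0)
        assert maps_to_detections(cls, ang, self.CFG) == []

    def test_oversized_blob_discarded(self):
        cls = np.zeros((64, 64), int)
        cls[5:40, 5:40] = 1  # 1225 px > 1000
        ang = np.where(cls > 0, 0.0, -1.0)
        assert maps_to_detections(cls, ang, self.CFG) == []

    @pytest.mark.parametrize("alpha", [0.0, 30.0, 117.0, 250.0])
    def test_round_trip_recovers_rendered_annotation(self, alpha):
        ann = BeeAnnotation(60.0, 60.0, 1, alpha)
        tg = render_bee_targets([ann], (128, 128), GEOM)
        dets = maps_to_detections(tg.class_map, tg.angle_map, self.CFG)
        assert len(dets) == 1
        d = dets[0]
        assert d.b == 1
        assert np.hypot(d.x - ann.x, d.y - ann.y) <= 1.0
        err = abs((d.alpha - alpha + 180) % 360 - 180)
        assert err <= 1.0

    def test_round_trip_cell_bee(self):
        tg = render_bee_targets([BeeAnnotation(40, 40, 2, 0.0)], (80, 80), GEOM)
        dets = maps_to_detections(tg.class_map, tg.angle_map, self.CFG)
        assert len(dets) == 1 and dets[0].b == 2 and dets[0].alpha is None

    def test_pca_axis_disambiguated_by_pixel_angles(self):
        # blob axis is 30 deg mod 180; pixel angles say 210 -> report 210
        tg = render_bee_targets([BeeAnnotation(60, 60, 1, 30.0)], (128, 128), GEOM)
        flipped = np.where(tg.angle_map >= 0, 210.0, -1.0)
        d = maps_to_detections(tg.class_map, flipped, self.CFG)[0]
        assert abs((d.alpha - 210 + 180) % 360 - 180) <= 1.0

    def test_multi_bee_round_trip(self):
        anns = [BeeAnnotation(40, 40, 1, 10.0), BeeAnnotation(150, 60, 1, 300.0),
                BeeAnnotation(100, 150, 2, 0.0)]
        tg = render_bee_targets(anns, (200, 200), GEOM)
        dets = maps_to_detections(tg.class_map, tg.angle_map, self.CFG)
        assert len(dets) == 3
        assert sorted(d.b for d in dets) == [1, 1, 2]


class _ThresholdModel:
    """Stand-in segmentation model: foreground where the image exceeds 0.5."""

    def __init__(self, tile=64, margin=16):
        self.config = DetectorConfig(encoder_widths=(4, 8), tile=tile,
                                     tile_margin=margin)
        self.depth = 1

    def forward(self, image, prior=None):
        fg = image > 0.5
        logits = np.stack([np.where(fg, -10.0, 10.0), np.where(fg, 10.0, -10.0),
                           np.full(image.shape, -10.0)])
        return logits, np.where(fg, 0.0, -1.0), None


class TestTiledInference:
    def test_single_tile_frame_has_no_cropping(self):
        model = _ThresholdModel(tile=64, margin=16)
        img = np.zeros((64, 64))
        img[20:30, 20:30] = 1.0
        cls, ang, _ = infer_tiled(img, model)
        assert np.array_equal(cls == 1, img > 0.5)

    def test_blob_on_tile_boundary_reported_once(self):
        model = _ThresholdModel(tile=64, margin=16)
        img = np.zeros((128, 128))
        # blob straddling the boundary region between tiles
        img[28:36, 60:68] = 1.0
        img[90:96, 90:98] = 1.0
        cls, ang, _ = infer_tiled(img, model)
        whole = _ThresholdModel(tile=128, margin=16)
        cls_whole, ang_whole, _ = infer_tiled(img, whole)
        assert np.array_equal(cls, cls_whole)
        cfg = DetectorConfig(encoder_widths=(4, 8), blob_min=5)
        dets = maps_to_detections(cls, ang, cfg)
        assert len(dets) == 2

    def test_blank_frame_yields_zero_detections(self):
        model = _ThresholdModel()
        cls, ang, _ = infer_tiled(np.zeros((128, 128)), model)
        assert maps_to_detections(cls, ang, model.config) == []

    def test_real_network_tiled_equals_whole_frame_on_single_tile(self):
        cfg = DetectorConfig(encoder_widths=(4, 8), tile=64, tile_margin=16)
        model = build_network(cfg, seed=0)
        img = np.random.default_rng(5).random((64, 64))
        logits, angle, _ = model.forward(img)
        cls_direct = logits.argmax(axis=0)
        cls_tiled, ang_tiled, _ = infer_tiled(img, model)
        assert np.array_equal(cls_tiled, cls_direct)
        assert np.allclose(ang_tiled[cls_tiled != 0], angle[cls_direct != 0])


def _tiny_labeled_frames(n=3, shape=(32, 32), seed=0):
    rng = np.random.default_rng(seed)
    geom = BeeGeometry(body_length=18, body_width=8)
    frames, labeled = [], []
    for _ in range(n):
        ann = BeeAnnotation(float(rng.uniform(10, 22)), float(rng.uniform(10, 22)),
                            1, float(rng.uniform(0, 360)))
        tg = render_bee_targets([ann], shape, geom)
        img = 0.2 + 0.6 * (tg.class_map > 0) + 0.05 * rng.standard_normal(shape)
        labeled.append((img, SegmentationTarget(tg.class_map, tg.angle_map,
                                                np.ones(shape))))
    return labeled


class TestFineTune:
    def test_zero_iterations_leave_parameters_unchanged(self):
        model = build_network(DetectorConfig(encoder_widths=(4, 8)), seed=0)
        before = [p.value.copy() for p in model.params()]
        fine_tune(model, _tiny_labeled_frames(), n_iter=0)
        for b, p in zip(before, model.params()):
            assert np.array_equal(b, p.value)

    def test_zero_learning_rate_keeps_loss_constant(self):
        model = build_network(DetectorConfig(encoder_widths=(4, 8)), seed=0)
        hist = fine_tune(model, _tiny_labeled_frames(), n_iter=3, lr=0.0)
        assert hist[0] == pytest.approx(hist[-1])

    def test_training_reduces_loss_on_small_fixture(self):
        model = build_network(DetectorConfig(encoder_widths=(4, 8)), seed=0)
        hist = fine_tune(model, _tiny_labeled_frames(5), n_iter=10, lr=1e-3)
        assert hist[-1] < hist[0]

    def test_empty_label_set_rejected(self):
        model = build_network(DetectorConfig(encoder_widths=(4, 8)))
        with pytest.raises(ValueError):
            fine_tune(model, [], n_iter=1)


class TestBackgroundExtraction:
    def test_constant_sequence_returns_itself(self):
        rng = np.random.default_rng(0)
        frame = rng.random((16, 16))
        bg = extract_background(np.stack([frame] * 5))
        assert np.allclose(bg, frame)

    def test_moving_foreground_removed(self):
        rng = np.random.default_rng(1)
        comb = rng.random((20, 60))
        frames = []
        for t in range(12):
            f = comb.copy()
            f[:, 5 * t:5 * t + 5] = 5.0  # bright moving block, <40% dwell per pixel
            frames.append(f)
        bg = extract_background(np.stack(frames))
        assert np.abs(bg - comb).max() < 1e-9

    def test_always_moving_pixel_falls_back_to_plain_median(self):
        rng = np.random.default_rng(2)
        frames = np.tile(rng.random((8, 8)), (6, 1, 1))
        frames[:, 4, 4] = np.arange(6) * 10.0  # never static
        bg = extract_background(frames)
        assert bg[4, 4] == pytest.approx(np.median(np.arange(6) * 10.0))

    def test_requires_three_frames(self):
        with pytest.raises(ValueError):
            extract_background(np.zeros((2, 8, 8)))


class TestBroodDetection:
    def test_round_trip_on_rendered_mask(self):
        cells = [BroodAnnotation(30, 40), BroodAnnotation(80, 70)]
        mask, _ = render_brood_targets(cells, (120, 120), GEOM)
        found = detect_brood(np.zeros((120, 120)), lambda img: mask, GEOM)
        assert len(found) == 2
        for c in cells:
            assert min(np.hypot(f.x - c.x, f.y - c.y) for f in found) <= 1.0

    def test_blank_background_gives_no_cells(self):
        assert detect_brood(np.zeros((64, 64)), lambda img: np.zeros((64, 64)),
                            GEOM) == []

    def test_tangent_cells_merge_to_midpoint(self):
        cells = [BroodAnnotation(40, 50), BroodAnnotation(60, 50)]
        mask, _ = render_brood_targets(cells, (100, 100), GEOM)
        found = detect_brood(np.zeros((100, 100)), lambda img: mask, GEOM)
        assert len(found) == 1
        assert found[0].x == pytest.approx(50.0, abs=1.0)
        assert found[0].y == pytest.approx(50.0, abs=1.0)

    def test_brood_network_builds_with_binary_head(self):
        model = build_brood_network(widths=(4, 8))
        logits, _, _ = model.forward(np.zeros((32, 32)))
        assert logits.shape == (2, 32, 32)


def test_checkpoint_round_trip(tmp_path):
    cfg = DetectorConfig(encoder_widths=(4, 8))
    model = build_network(cfg, seed=3)
    detector.save_checkpoint(model, tmp_path / "m.npz")
    loaded = detector.load_checkpoint(tmp_path / "m.npz")
    img = np.random.default_rng(0).random((32, 32))
    a, _, _ = model.forward(img)
    b, _, _ = loaded.forward(img)
    assert np.allclose(a, b)
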