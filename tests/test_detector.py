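"""Detector architecture, target assignment, loss composition and decoding."""

import numpy as np
import pytest

from polypdet.autodiff import Tensor, maxpool2d
from polypdet.boxes import Detection
from polypdet.detector import (
    DetectorConfig,
    assign_targets,
    build_model,
    compute_loss,
    decode,
    encode_box,
    load_checkpoint,
    nms,
    save_checkpoint,
)
from polypdet.gwd import composite_loss, gwd_box_loss

TINY = DetectorConfig(width_multiple=0.25, depth_multiple=0.33)


def logit(x):
    return np.log(x / (1 - x))


class TestBuild:
    def test_same_seed_bit_identical_parameters(self):
        m1 = build_model(TINY, seed=7)
        m2 = build_model(TINY, seed=7)
        s1, s2 = m1.state_dict(), m2.state_dict()
        assert s1.keys() == s2.keys()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_different_seed_differs(self):
        m1, m2 = build_model(TINY, seed=1), build_model(TINY, seed=2)
        assert any(not np.array_equal(a, b) for a, b in
                   zip(m1.state_dict().values(), m2.state_dict().values()))

    def test_tiny_parameter_budget(self):
        assert build_model(TINY, seed=0).num_parameters() < 2_000_000

    def test_attention_flag_off_removes_pcbam_parameters(self):
        m = build_model(DetectorConfig(attention=False), seed=0)
        assert m.attention is None
        assert not any("attention" in k for k, _ in m.named_parameters())

    def test_attention_flag_on_adds_pcbam_parameters(self):
        m = build_model(TINY, seed=0)
        names = [k for k, _ in m.named_parameters()]
        assert any(k.startswith("attention.") for k in names)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(width_multiple=0.0)
        with pytest.raises(ValueError):
            DetectorConfig(box_loss="diou")


class TestForward:
    def test_grid_shapes_at_64(self):
        m = build_model(TINY, seed=0)
        preds = m(Tensor(np.zeros((2, 3, 64, 64), dtype=np.float32)))
        shapes = [p.shape for p in preds]
        assert shapes[0][:4] == (2, 3, 8, 8)
        assert shapes[1][:4] == (2, 3, 4, 4)
        assert shapes[2][:4] == (2, 3, 2, 2)

    def test_doubling_height_doubles_grids(self):
        m = build_model(TINY, seed=0)
        p1 = m(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
        p2 = m(Tensor(np.zeros((1, 3, 128, 64), dtype=np.float32)))
        for a, b in zip(p1, p2):
            assert b.shape[2] == 2 * a.shape[2]
            assert b.shape[3] == a.shape[3]

    def test_indivisible_input_rejected_with_padding_hint(self):
        m = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="pad to 64"):
            m(Tensor(np.zeros((1, 3, 60, 64), dtype=np.float32)))

    def test_sppf_equals_parallel_spp(self):
        """Serial 5×5×3 pooling equals parallel 5/9/13 pooling exactly."""
        rng = np.random.default_rng(0)
        x = Tensor(rng.standard_normal((2, 4, 16, 16)).astype(np.float32))
        y1 = maxpool2d(x, 5, 1, 2)
        y2 = maxpool2d(y1, 5, 1, 2)
        y3 = maxpool2d(y2, 5, 1, 2)
        spp9 = maxpool2d(x, 9, 1, 4)
        spp13 = maxpool2d(x, 13, 1, 6)
        assert np.max(np.abs(y2.data - spp9.data)) == 0.0
        assert np.max(np.abs(y3.data - spp13.data)) == 0.0


class TestAssignAndLoss:
    ANCHORS = np.array([[[0.1, 0.1]], [[0.5, 0.5]], [[2.5, 2.5]]])

    def make_model(self):
        m = build_model(DetectorConfig(width_multiple=0.25, depth_multiple=0.33,
                                       num_classes=2, anchors_per_scale=1), seed=0)
        m.anchors[...] = self.ANCHORS
        return m

    def test_assignment_center_plus_two_neighbors(self):
        targets = np.array([[0, 1, 0.3125, 0.4375, 0.1, 0.1]])
        out = assign_targets(targets, self.ANCHORS, [(8, 8), (4, 4), (2, 2)])
        assert out[1] is None and out[2] is None  # only the small anchor matches
        bi, ai, gj, gi, txy, anc, tbox, tcls = out[0]
        cells = set(zip(gj.tolist(), gi.tolist()))
        assert cells == {(3, 2), (3, 3), (4, 2)}
        assert set(tcls.tolist()) == {1}

    def test_empty_targets_zero_box_loss(self):
        m = self.make_model()
        preds = m(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
        comps = composite_loss(preds, np.zeros((0, 6)), m)
        assert comps.box_loss == 0.0 and comps.cls_loss == 0.0
        assert comps.obj_loss > 0.0
        assert comps.total == comps.obj_loss

    def test_total_is_sum_of_components(self):
        m = self.make_model()
        preds = m(Tensor(np.random.default_rng(0)
                         .random((2, 3, 64, 64)).astype(np.float32)))
        targets = np.array([[0, 0, 0.3, 0.4, 0.12, 0.09],
                            [1, 1, 0.6, 0.6, 0.4, 0.5]])
        comps = composite_loss(preds, targets, m)
        assert comps.total == pytest.approx(
            comps.cls_loss + comps.obj_loss + comps.box_loss)
        assert comps.box_loss > 0 and comps.cls_loss > 0

    def test_loss_matches_straight_line_hand_computation(self):
        """Single positive anchor on one scale, recomputed with explicit numpy."""
        m = self.make_model()
        cfg = m.cfg
        rng = np.random.default_rng(3)
        shapes = [(1, 1, 8, 8, 7), (1, 1, 4, 4, 7), (1, 1, 2, 2, 7)]
        raw = [rng.standard_normal(s) * 0.5 for s in shapes]
        preds = [Tensor(r) for r in raw]
        target = np.array([[0, 1, 0.3125, 0.4375, 0.1, 0.1]])
        _, comps = compute_loss(preds, target, m)

        # hand recomputation from the known assignment (3 cells, scale 0)
        def sig(v):
            return 1 / (1 + np.exp(-v))

        cells = [(3, 2), (3, 3), (4, 2)]
        box_losses, cls_losses = [], []
        for gj, gi in cells:
            ps = raw[0][0, 0, gj, gi]
            cx = (sig(ps[0]) * 2 - 0.5 + gi) / 8
            cy = (sig(ps[1]) * 2 - 0.5 + gj) / 8
            w = (sig(ps[2]) * 2) ** 2 * 0.1
            h = (sig(ps[3]) * 2) ** 2 * 0.1
            box_losses.append(gwd_box_loss((cx, cy, w, h), target[0, 2:6], tau=cfg.tau))
            p_cls = sig(ps[5:])
            tgt = np.array([0.0, 1.0])
            cls_losses.append(-(tgt * np.log(p_cls) + (1 - tgt) * np.log(1 - p_cls)).mean())
        exp_box = np.mean(box_losses)
        exp_cls = np.mean(cls_losses)
        exp_obj = 0.0
        balance = (4.0, 1.0, 0.4)
        for si, r in enumerate(raw):
            t = np.zeros(r.shape[:4])
            if si == 0:
                for gj, gi in cells:
                    t[0, 0, gj, gi] = 1.0
            p = sig(r[..., 4])
            bce = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
            exp_obj += balance[si] * bce
        w_cls, w_obj, w_box = cfg.loss_weights
        assert comps.box_loss == pytest.approx(w_box * exp_box, rel=1e-6)
        assert comps.cls_loss == pytest.approx(w_cls * exp_cls, rel=1e-6)
        assert comps.obj_loss == pytest.approx(w_obj * exp_obj, rel=1e-6)

    def test_perfect_predictions_drive_box_loss_to_floor(self):
        m = self.make_model()
        target = np.array([[0, 1, 0.3125, 0.4375, 0.1, 0.1]])
        shapes = [(1, 1, 8, 8, 7), (1, 1, 4, 4, 7), (1, 1, 2, 2, 7)]
        raw = [np.full(s, -20.0) for s in shapes]
        for gj, gi in [(3, 2), (3, 3), (4, 2)]:
            raw[0][0, 0, gj, gi, :4] = encode_box(target[0, 2:6], (0.1, 0.1),
                                                  (gj, gi), (8, 8))
            raw[0][0, 0, gj, gi, 4] = 20.0   # saturated objectness
            raw[0][0, 0, gj, gi, 5:] = [-20.0, 20.0]
        _, comps = compute_loss([Tensor(r) for r in raw], target, m)
        assert comps.box_loss == pytest.approx(0.0, abs=1e-6)
        assert comps.cls_loss == pytest.approx(0.0, abs=1e-6)
        assert comps.obj_loss == pytest.approx(0.0, abs=1e-6)


class TestDecode:
    def test_zero_objectness_gives_no_detections(self):
        m = build_model(TINY, seed=0)
        preds = [Tensor(np.full((1, 3, g, g, 6), -20.0)) for g in (8, 4, 2)]
        dets = decode(preds, m.anchors, 0.25, 0.45)
        assert dets == [[]]

    def test_single_saturated_cell_decodes_analytically(self):
        anchors = np.array([[[0.1, 0.12]], [[0.5, 0.5]], [[2.5, 2.5]]])
        preds = [np.full((1, 1, 8, 8, 6), -20.0),
                 np.full((1, 1, 4, 4, 6), -20.0),
                 np.full((1, 1, 2, 2, 6), -20.0)]
        preds[0][0, 0, 2, 3, :] = [0.0, 0.0, 0.0, 0.0, 6.0, 6.0]
        dets = decode(preds, anchors, 0.25, 0.45)[0]
        assert len(dets) == 1
        d = dets[0]
        np.testing.assert_allclose(d.box, [(3 + 0.5) / 8, (2 + 0.5) / 8, 0.1, 0.12],
                                   atol=1e-7)
        assert d.confidence == pytest.approx(1 / (1 + np.exp(-6.0)) ** 2, rel=1e-5)

    def test_duplicate_detections_suppressed(self):
        boxes = np.array([[0.5, 0.5, 0.2, 0.2], [0.5, 0.5, 0.2, 0.2]])
        keep = nms(boxes, np.array([0.9, 0.8]), 0.45)
        assert keep == [0]

    def test_disjoint_detections_kept(self):
        boxes = np.array([[0.2, 0.2, 0.1, 0.1], [0.8, 0.8, 0.1, 0.1]])
        keep = nms(boxes, np.array([0.7, 0.9]), 0.45)
        assert sorted(keep) == [0, 1]

    def test_encode_decode_round_trip(self):
        """Ground-truth boxes survive encode → decode to ≤1e-6."""
        anchors = np.array([[[0.08, 0.1]], [[0.3, 0.3]], [[0.9, 0.9]]])
        rng = np.random.default_rng(5)
        for _ in range(25):
            box = np.array([rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8),
                            rng.uniform(0.03, 0.25), rng.uniform(0.03, 0.3)])
            gw = gh = 8
            gi, gj = int(box[0] * gw), int(box[1] * gh)
            raw = [np.full((1, 1, 8, 8, 6), -30.0),
                   np.full((1, 1, 4, 4, 6), -30.0),
                   np.full((1, 1, 2, 2, 6), -30.0)]
            raw[0][0, 0, gj, gi, :4] = encode_box(box, anchors[0, 0], (gj, gi), (gh, gw))
            raw[0][0, 0, gj, gi, 4:] = 30.0
            dets = decode(raw, anchors, 0.25, 0.45)[0]
            assert len(dets) == 1
            np.testing.assert_allclose(dets[0].box, box, atol=1e-6)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            decode([np.zeros((1, 1, 2, 2, 6))], np.zeros((1, 1, 2)), 0.0, 0.45)


class TestCheckpoint:
    def test_round_trip_preserves_forward(self, tmp_path):
        m = build_model(DetectorConfig(width_multiple=0.25, depth_multiple=0.33,
                                       learn_alphas=False), seed=3)
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)).astype(np.float32))
        m.eval()
        before = [p.data.copy() for p in m(x)]
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, m)
        m2 = load_checkpoint(path)
        m2.eval()
        after = m2(x)
        for a, b in zip(before, after):
            np.testing.assert_array_equal(a, b.data)
        assert m2.cfg == m.cfg
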