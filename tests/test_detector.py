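"""Detector graph contracts, decoding arithmetic, NMS, loss sanity."""

import numpy as np
import pytest

from birdparts.autodiff import Tensor
from birdparts.detector import (Checkpoint, DetectionRecord, Hyperparams,
                                NetworkConfig, build_network, decode_predictions,
                                detection_loss, forward_eval, letterbox,
                                load_dataset, nms, train)
from birdparts.voc_io import PartType

import oracles


def _sigmoid(z):
    return 1 / (1 + np.exp(-z))


class TestGraphContracts:
    def test_head_dimensions_num_classes_plus_five(self, tiny_network, rng):
        x = rng.random((1, 3, 160, 160), dtype=np.float32)
        out = forward_eval(tiny_network, x)
        assert [o.shape for o in out] == [(1, 3, 20, 20, 37), (1, 3, 10, 10, 37),
                                         (1, 3, 5, 5, 37)]

    def test_single_class_head_has_six_channels(self):
        cfg = NetworkConfig(num_classes=1, width_multiple=0.125,
                            depth_multiple=1 / 12, input_size=160, seed=0)
        net = build_network(cfg)
        out = forward_eval(net, np.zeros((1, 3, 160, 160), dtype=np.float32))
        assert all(o.shape[-1] == 6 for o in out)

    def test_fully_convolutional_grids_scale_with_input(self, tiny_network, rng):
        """Doubling the input side doubles every detection grid."""
        out = forward_eval(tiny_network, rng.random((1, 3, 320, 320),
                                                    dtype=np.float32))
        assert [(o.shape[2], o.shape[3]) for o in out] == [(40, 40), (20, 20),
                                                           (10, 10)]

    def test_width_multiplier_scales_channels(self, tiny_network):
        # 1280 full-scale channels at the SPPF output scale to 160 at 1/8 width
        assert tiny_network.out_channels[13] == 160
        assert tiny_network.out_channels[0] == 8

    def test_forward_deterministic_in_eval(self, tiny_network, rng):
        img = rng.random((1, 3, 160, 160), dtype=np.float32)
        batch = np.concatenate([img, img], axis=0)
        out = forward_eval(tiny_network, batch)
        for o in out:
            assert np.array_equal(o[0], o[1])
        again = forward_eval(tiny_network, batch)
        for a, b in zip(out, again):
            assert np.array_equal(a, b)

    def test_input_not_divisible_by_32_rejected(self, tiny_network):
        with pytest.raises(ValueError):
            tiny_network(np.zeros((1, 3, 100, 100), dtype=np.float32))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(width_multiple=0.0)
        with pytest.raises(ValueError):
            NetworkConfig(input_size=100)

    def test_res2net_scale_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            build_network(NetworkConfig(num_classes=4, width_multiple=0.125,
                                        depth_multiple=1 / 12, input_size=160,
                                        res2net_scale=3))


class TestDecode:
    def _empty_raw(self, nc=32):
        shapes = [(1, 3, 20, 20, nc + 5), (1, 3, 10, 10, nc + 5),
                  (1, 3, 5, 5, nc + 5)]
        return [np.full(s, -20.0) for s in shapes]

    def test_all_suppressed_logits_give_no_records(self):
        recs = decode_predictions(self._empty_raw(),
                                  anchors=NetworkConfig().anchors,
                                  strides=(8, 16, 32), conf_threshold=0.25)
        assert recs == []

    def test_single_cell_decode_arithmetic(self):
        """Hand-set activation reproduces the published decode formula."""
        raw = self._empty_raw()
        cell = raw[0][0, 1, 3, 4]  # scale stride 8, anchor (16, 30)
        cell[:] = -20.0
        cell[0] = 0.0   # sigma = 0.5 -> cx = (2*0.5 - 0.5 + 4) * 8 = 36
        cell[1] = 0.0   # cy = (0.5 + 3) * 8 = 28
        cell[2] = 0.0   # pw = (2*0.5)^2 * 16 = 16
        cell[3] = 0.0   # ph = (2*0.5)^2 * 30 = 30
        cell[4] = 2.0
        cell[5 + 3] = 1.5
        (rec,) = decode_predictions(raw, NetworkConfig().anchors, (8, 16, 32),
                                    conf_threshold=0.25)
        assert rec.class_id == 3
        assert rec.confidence == pytest.approx(_sigmoid(2.0) * _sigmoid(1.5))
        assert rec.box == pytest.approx((36 - 8, 28 - 15, 36 + 8, 28 + 15))

    def test_threshold_zero_is_superset_of_quarter(self, rng):
        raw = [rng.standard_normal(s) * 3 for s in
               [(1, 3, 8, 8, 9), (1, 3, 4, 4, 9), (1, 3, 2, 2, 9)]]
        anchors = NetworkConfig().anchors
        low = decode_predictions(raw, anchors, (8, 16, 32), 0.0)
        high = decode_predictions(raw, anchors, (8, 16, 32), 0.25)
        assert set((r.box, r.class_id) for r in high) <= \
            set((r.box, r.class_id) for r in low)
        assert len(low) >= len(high)


class TestNms:
    def _rec(self, conf, box, cls=0, img="a"):
        return DetectionRecord(image_id=img, box=box, confidence=conf,
                               class_id=cls)

    def test_single_record_survives(self):
        r = self._rec(0.5, (0, 0, 10, 10))
        assert nms([r], 0.45) == [r]

    def test_identical_boxes_keep_higher_confidence(self):
        a = self._rec(0.9, (0, 0, 10, 10))
        b = self._rec(0.6, (0, 0, 10, 10))
        assert nms([a, b], 0.45) == [a]

    def test_different_classes_do_not_suppress(self):
        a = self._rec(0.9, (0, 0, 10, 10), cls=0)
        b = self._rec(0.6, (0, 0, 10, 10), cls=1)
        assert len(nms([a, b], 0.45)) == 2

    def test_matches_exhaustive_oracle_on_random_boxes(self, rng):
        for trial in range(10):
            recs = []
            for _ in range(10):
                x0, y0 = rng.uniform(0, 60, 2)
                w, h = rng.uniform(5, 40, 2)
                recs.append(self._rec(float(rng.random()),
                                      (x0, y0, x0 + w, y0 + h),
                                      cls=int(rng.integers(2))))
            got = set(map(id, nms(recs, 0.45)))
            want = set(map(id, oracles.nms_oracle(recs, 0.45)))
            assert got == want

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            nms([], 1.5)


class TestTraining:
    def test_loss_finite_positive_and_differentiable(self, tiny_network,
                                                     scene_dataset, rng):
        _, manifest, _, _ = scene_dataset
        images, targets, _ = load_dataset(manifest, 160)
        tiny_network.train()
        preds = tiny_network(Tensor(images[:2]))
        loss, parts = detection_loss(preds, targets, np.array([0, 1]),
                                     tiny_network, Hyperparams())
        assert np.isfinite(loss.data) and loss.data > 0
        assert parts["box"] > 0 and parts["obj"] > 0 and parts["cls"] > 0
        loss.backward()
        grads = [p.grad for p in tiny_network.layers[0].parameters()]
        assert any(g is not None and np.abs(g).max() > 0 for g in grads)
        tiny_network.eval()

    def test_short_training_reduces_loss(self, scene_dataset):
        _, manifest, _, _ = scene_dataset
        cfg = NetworkConfig(num_classes=32, width_multiple=0.125,
                            depth_multiple=1 / 12, input_size=160, seed=5)
        net = build_network(cfg)
        ckpt = train(net, manifest,
                     Hyperparams(epochs=6, batch_size=6, lr=0.01, seed=5))
        assert ckpt.history[-1]["loss"] < ckpt.history[0]["loss"]

    def test_empty_manifest_rejected(self, tiny_network):
        from birdparts.voc_io import DatasetManifest

        with pytest.raises(ValueError):
            train(tiny_network, DatasetManifest(entries=[]), Hyperparams())


def test_checkpoint_round_trip(tmp_path, tiny_network, rng):
    ckpt = Checkpoint(config=tiny_network.config, state=tiny_network.state_dict())
    ckpt.save(tmp_path / "model")
    restored = Checkpoint.load(tmp_path / "model").restore()
    x = rng.random((1, 3, 160, 160), dtype=np.float32)
    a = forward_eval(tiny_network, x)
    b = forward_eval(restored, x)
    for u, v in zip(a, b):
        assert np.allclose(u, v)


def test_letterbox_preserves_aspect_and_maps_boxes():
    img = np.zeros((50, 100, 3), dtype=np.uint8)
    out, boxes = letterbox(img, [(0, 0, 100, 50)], 160)
    assert out.shape == (160, 160, 3)
    x0, y0, x1, y1 = boxes[0]
    assert (x0, x1) == (0, 160)
    assert y1 - y0 == pytest.approx(80)   # 50 * 1.6
    assert y0 == pytest.approx(40)        # centred vertically
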