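"""Model assembly: parameter/FLOP accounting, fusion, plug-and-play graph
equality, NMS, inference and the training smoke contract."""

import numpy as np
import pytest

from ginsengdet import nn
from ginsengdet.model import (InferenceError, ModelConfig,
                              assemble_baseline, assemble_yolo_ginseng,
                              count_flops, count_parameters, fuse_model,
                              letterbox, nms, predict)
from ginsengdet.nn.tensor import Tensor


def tiny_cfg(c3f=None, img=64):
    return ModelConfig(nc=1, width_mult=0.25, depth_mult=0.33, img_size=img,
                       c3f_rn=c3f)


class TestAssembly:
    def test_baseline_rejects_c3f_config_and_vice_versa(self):
        with pytest.raises(ValueError):
            assemble_baseline(ModelConfig(nc=1, c3f_rn={"depth": 2}))
        with pytest.raises(ValueError):
            assemble_yolo_ginseng(ModelConfig(nc=1))

    def test_unsupported_multipliers_rejected(self):
        with pytest.raises(ValueError):
            assemble_baseline(ModelConfig(nc=1, width_mult=3.0))

    def test_class_count_parameter_difference_closed_form(self):
        # each extra class adds one output channel per anchor per scale:
        # (c_in + 1) * 3 anchors summed over the three head widths
        n1 = count_parameters(assemble_baseline(ModelConfig(nc=1)))
        n2 = count_parameters(assemble_baseline(ModelConfig(nc=2)))
        assert n2 - n1 == 3 * ((128 + 1) + (256 + 1) + (512 + 1))

    def test_three_scale_forward_contract(self, rng):
        m = assemble_baseline(tiny_cfg())
        m.eval()
        y = m(Tensor(rng.normal(0, 1, (1, 3, 64, 64)).astype(np.float32)))
        assert [t.shape for t in y] == [(1, 18, 8, 8), (1, 18, 4, 4),
                                       (1, 18, 2, 2)]

    def test_count_invariant_to_resolution(self):
        a = ModelConfig(nc=1, img_size=640)
        b = ModelConfig(nc=1, img_size=320)
        assert (count_parameters(assemble_baseline(a))
                == count_parameters(assemble_baseline(b)))

    def test_graphs_differ_only_in_backbone_stages(self):
        base = assemble_baseline(tiny_cfg())
        gin = assemble_yolo_ginseng(tiny_cfg(
            c3f={"depth": 2, "n_heads": 8, "win_size": 4, "embed_dim": 64}))
        outside = ["l0", "l1", "l3", "l5", "l7", "l9", "l10", "l13", "l14",
                   "l17", "l18", "l20", "l21", "l23", "detect"]
        for name in outside:
            pa = sum(p.size for p in getattr(base, name).parameters())
            pb = sum(p.size for p in getattr(gin, name).parameters())
            assert pa == pb, name
        for name in ["l2", "l4", "l6", "l8"]:
            pa = sum(p.size for p in getattr(base, name).parameters())
            pb = sum(p.size for p in getattr(gin, name).parameters())
            assert pb > pa, name

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = tiny_cfg(c3f={"depth": 2, "n_heads": 8, "win_size": 4,
                            "embed_dim": 64})
        path = tmp_path / "model.yaml"
        cfg.to_yaml(path)
        back = ModelConfig.from_yaml(path)
        assert back == cfg


class TestCounting:
    def test_empty_and_single_conv_counts(self):
        class Empty(nn.Module):
            def forward(self, x):
                return x

        assert count_parameters(Empty()) == 0
        conv = nn.Conv2d(3, 16, 3, bias=True)
        assert count_parameters(conv) == 3 * 3 * 3 * 16 + 16

    def test_fused_count_drops_one_scalar_per_bn_channel(self):
        m = assemble_baseline(tiny_cfg())
        bn_channels = sum(mod.c for mod in m.modules()
                          if isinstance(mod, nn.BatchNorm2d))
        assert (count_parameters(m) - count_parameters(m, fused=True)
                == bn_channels)

    def test_fusion_preserves_eval_forward(self, rng):
        m = assemble_baseline(tiny_cfg())
        # push the BN stats off their init values first
        m.train()
        x = Tensor(rng.normal(0.4, 0.2, (2, 3, 64, 64)).astype(np.float32))
        m(x)
        m.eval()
        before = [t.data.copy() for t in m(x)]
        fuse_model(m)
        after = m(x)
        for b, a in zip(before, after):
            assert np.allclose(b, a.data, atol=1e-3)

    def test_flops_zero_layer_and_single_conv(self):
        class OneConv(nn.Module):
            def __init__(self):
                super().__init__()
                self.c = nn.Conv2d(3, 8, 1)

            def forward(self, x):
                return self.c(x)

        class Empty(nn.Module):
            def forward(self, x):
                return x

        assert count_flops(Empty(), 64, probe=64) == 0.0
        g = count_flops(OneConv(), 64, probe=64)
        assert np.isclose(g, 2 * 3 * 8 * 64 * 64 / 1e9)

    def test_flops_probe_independence_for_conv_graph(self):
        m = assemble_baseline(tiny_cfg())
        a = count_flops(m, 640, probe=64)
        b = count_flops(m, 640, probe=32)
        assert np.isclose(a, b, rtol=1e-6)

    def test_flops_scale_quadratically_with_resolution(self):
        m = assemble_baseline(tiny_cfg())
        assert np.isclose(count_flops(m, 640) / count_flops(m, 320), 4.0)


class TestNMS:
    def test_identical_boxes_one_survivor(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8]), 0.5)
        assert len(keep) == 1 and keep[0] == 0

    def test_disjoint_boxes_all_survive(self):
        boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30],
                          [40, 40, 45, 45]], dtype=float)
        assert len(nms(boxes, np.array([0.5, 0.9, 0.1]), 0.01)) == 3

    def test_iou_one_seventh_survives_at_half(self):
        boxes = np.array([[0, 0, 2, 2], [1, 1, 3, 3]], dtype=float)
        assert len(nms(boxes, np.array([0.9, 0.8]), 0.5)) == 2

    def test_equal_confidence_tiebreak_order_independent(self, rng):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 9, 9], [0, 0, 6, 6],
                          [30, 30, 42, 40]], dtype=float)
        conf = np.array([0.7, 0.7, 0.7, 0.7])
        ref = set(map(tuple, boxes[nms(boxes, conf, 0.4)].tolist()))
        for _ in range(5):
            perm = rng.permutation(len(boxes))
            got = set(map(tuple, boxes[perm][nms(boxes[perm], conf[perm],
                                                 0.4)].tolist()))
            assert got == ref


class TestInference:
    def test_letterbox_geometry(self):
        img = np.zeros((100, 200, 3), dtype=np.uint8)
        canvas, r, (px, py) = letterbox(img, 64)
        assert canvas.shape == (64, 64, 3)
        assert np.isclose(r, 64 / 200)
        assert px == 0 and py == (64 - 32) // 2

    def test_predict_returns_detection_sets(self, rng):
        m = assemble_baseline(tiny_cfg())
        imgs = [rng.integers(0, 255, (80, 60, 3), dtype=np.uint8)]
        out = predict(m, imgs, conf_thr=0.9)
        assert len(out) == 1
        assert out[0].boxes.shape[1] == 4

    def test_nan_activations_raise_inference_error(self, rng):
        m = assemble_baseline(tiny_cfg())
        m.detect.m[0].weight.data[...] = np.nan
        with pytest.raises(InferenceError, match="stride-8"):
            predict(m, [rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)])


class TestTrainContract:
    def test_one_epoch_smoke_checkpoint_and_log(self, tmp_path, toy_scenes_64):
        from ginsengdet.compress import ToyDetector
        from ginsengdet.train import load_checkpoint, train

        items = toy_scenes_64[:2]
        model = ToyDetector(img_size=64, seed=0)
        ckpt = tmp_path / "toy.npz"
        model, log = train(model, items, items,
                           hyp={"epochs": 1, "batch_size": 2, "seed": 0},
                           ckpt_path=str(ckpt))
        assert len(log) == 1
        assert {"epoch", "loss", "ap"} <= set(log[0])
        assert ckpt.exists()

    def test_fixed_seed_loss_reproducible(self, toy_scenes_64):
        from ginsengdet.compress import ToyDetector
        from ginsengdet.train import train

        items = toy_scenes_64[:4]
        losses = []
        for _ in range(2):
            model = ToyDetector(img_size=64, seed=3)
            _, log = train(model, items, items,
                           hyp={"epochs": 1, "batch_size": 2, "seed": 5})
            losses.append(log[0]["loss"])
        assert losses[0] == losses[1]

    def test_empty_dataset_rejected_before_training(self):
        from ginsengdet.compress import ToyDetector
        from ginsengdet.train import train

        with pytest.raises(ValueError, match="empty"):
            train(ToyDetector(), [], [], hyp={"epochs": 1})

    def test_degenerate_labels_rejected(self):
        from ginsengdet.compress import ToyDetector
        from ginsengdet.synthetic import LabeledImage
        from ginsengdet.train import train

        bad = LabeledImage(np.zeros((64, 64, 3), dtype=np.uint8),
                           [[0, 0.5, 0.5, 0.0, 0.1]], name="bad")
        with pytest.raises(ValueError, match="degenerate"):
            train(ToyDetector(), [bad], [bad], hyp={"epochs": 1})

    def test_checkpoint_roundtrip_preserves_forward(self, rng, tmp_path):
        from ginsengdet.train import load_checkpoint, save_checkpoint

        m = assemble_baseline(tiny_cfg())
        m.eval()
        x = Tensor(rng.normal(0, 1, (1, 3, 64, 64)).astype(np.float32))
        ref = [t.data.copy() for t in m(x)]
        save_checkpoint(m, tmp_path / "m.npz")
        back = load_checkpoint(tmp_path / "m.npz")
        back.eval()
        for a, b in zip(ref, back(x)):
            assert np.allclose(a, b.data, atol=1e-6)
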