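"""Detector assembly: small-width CSP baseline and its C3f-RN variant.

The baseline is the familiar small single-stage detector (width 0.50,
depth 0.33): CSP backbone, SPPF, FPN+PAN neck and a three-scale anchor
head.  The improved model replaces the four backbone C3 stages with
C3f-RN blocks of matching width and repeat count; the neck and head are
untouched, which is asserted in tests by diffing the two graphs.

Parameter accounting is exact and purely structural; ``count_parameters``
can also report the deploy-time count in which every Conv+BN pair has
been folded into a biased convolution (one scalar per pair fewer).
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import yaml

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor
from .layers import C3, SPPF, ConvBlock, make_divisible
from .c3f_rn import C3fRN, C3fRNConfig
from .primitives import SwinStageConfig

__all__ = [
    "ModelConfig", "DetectionSet", "YoloModel", "assemble_baseline",
    "assemble_yolo_ginseng", "count_parameters", "count_flops", "fuse_model",
    "predict", "nms", "letterbox", "InferenceError", "DEFAULT_ANCHORS",
]

DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),       # stride 8
    ((30, 61), (62, 45), (59, 119)),      # stride 16
    ((116, 90), (156, 198), (373, 326)),  # stride 32
)


class InferenceError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    """Everything that determines the graph (and hence the exact parameter
    count): class count, width/depth multipliers, and the optional C3f-RN
    settings."""

    nc: int = 1
    width_mult: float = 0.50
    depth_mult: float = 0.33
    img_size: int = 640
    anchors: tuple = DEFAULT_ANCHORS
    c3f_rn: Optional[dict] = None   # {"depth", "n_heads", "win_size", "embed_dim"}

    def __post_init__(self):
        if self.nc < 1:
            raise ValueError("nc must be >= 1")

    def to_yaml(self, path):
        d = asdict(self)
        d["anchors"] = [[list(a) for a in s] for s in self.anchors]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "anchors" in d:
            d["anchors"] = tuple(tuple(tuple(a) for a in s) for s in d["anchors"])
        return cls(**d)


@dataclass
class DetectionSet:
    """Axis-aligned boxes (x1, y1, x2, y2) in pixels + confidences + class ids."""

    boxes: np.ndarray
    confidences: np.ndarray
    class_ids: np.ndarray

    def __len__(self):
        return len(self.boxes)


class Detect(nn.Module):
    """Anchor head: one 1x1 biased conv per scale (three scales for the
    full detector; toy models may use fewer)."""

    def __init__(self, channels, nc, anchors, strides=(8, 16, 32)):
        super().__init__()
        self.strides = tuple(strides)
        self.nc = nc
        self.no = nc + 5
        self.na = len(anchors[0])
        self.anchors = np.asarray(anchors, dtype=np.float32)  # (3, na, 2)
        self.m = nn.ModuleList([nn.Conv2d(c, self.na * self.no, 1, bias=True)
                                for c in channels])
        self._init_biases()

    def _init_biases(self):
        for conv, s in zip(self.m, self.strides):
            b = conv.bias.data.reshape(self.na, self.no)
            b[:, 4] += np.log(8.0 / (640.0 / s) ** 2)
            if self.nc > 1:
                b[:, 5:] += np.log(0.6 / (self.nc - 0.99))
            else:
                b[:, 5:] += np.log(0.99 / 0.01)
            conv.bias.data[...] = b.reshape(-1)

    def forward(self, feats):
        return [m(f) for m, f in zip(self.m, feats)]


class YoloModel(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        w = lambda c: make_divisible(c * cfg.width_mult, 8)
        d = lambda n: max(round(n * cfg.depth_mult), 1)
        ns = [d(3), d(6), d(9), d(3)]           # backbone repeats
        nh = d(3)                                # head repeats
        cs = [w(64), w(128), w(256), w(512), w(1024)]

        def stage(c, n):
            if cfg.c3f_rn is None:
                return C3(c, c, n)
            s = dict(cfg.c3f_rn)
            swin = SwinStageConfig(depth=s.get("depth", 2),
                                   n_heads=s.get("n_heads", 8),
                                   win_size=s.get("win_size", 4),
                                   embed_dim=s.get("embed_dim", 64))
            if (c // 2) % swin.n_heads and swin.embed_dim % swin.n_heads:
                raise ValueError("stage width incompatible with n_heads")
            return C3fRN(C3fRNConfig(c, c, n_repeats=n, swin=swin))

        self.l0 = ConvBlock(3, cs[0], 6, 2, padding=2)
        self.l1 = ConvBlock(cs[0], cs[1], 3, 2)
        self.l2 = stage(cs[1], ns[0])
        self.l3 = ConvBlock(cs[1], cs[2], 3, 2)
        self.l4 = stage(cs[2], ns[1])
        self.l5 = ConvBlock(cs[2], cs[3], 3, 2)
        self.l6 = stage(cs[3], ns[2])
        self.l7 = ConvBlock(cs[3], cs[4], 3, 2)
        self.l8 = stage(cs[4], ns[3])
        self.l9 = SPPF(cs[4], cs[4])
        self.l10 = ConvBlock(cs[4], cs[3], 1)
        self.l13 = C3(2 * cs[3], cs[3], nh, shortcut=False)
        self.l14 = ConvBlock(cs[3], cs[2], 1)
        self.l17 = C3(2 * cs[2], cs[2], nh, shortcut=False)
        self.l18 = ConvBlock(cs[2], cs[2], 3, 2)
        self.l20 = C3(2 * cs[2], cs[3], nh, shortcut=False)
        self.l21 = ConvBlock(cs[3], cs[3], 3, 2)
        self.l23 = C3(2 * cs[3], cs[4], nh, shortcut=False)
        self.detect = Detect([cs[2], cs[3], cs[4]], cfg.nc, cfg.anchors)
        self.up = nn.Upsample()

    def forward(self, x):
        x = self.l1(self.l0(x))
        p3 = self.l4(self.l3(self.l2(x)))
        p4 = self.l6(self.l5(p3))
        p5 = self.l9(self.l8(self.l7(p4)))
        t10 = self.l10(p5)
        f13 = self.l13(F.concat([self.up(t10), p4], axis=1))
        t14 = self.l14(f13)
        f17 = self.l17(F.concat([self.up(t14), p3], axis=1))
        f20 = self.l20(F.concat([self.l18(f17), t14], axis=1))
        f23 = self.l23(F.concat([self.l21(f20), t10], axis=1))
        return self.detect([f17, f20, f23])


def assemble_baseline(cfg: ModelConfig) -> YoloModel:
    """Build the small-width CSP baseline (no C3f-RN)."""
    if cfg.c3f_rn is not None:
        raise ValueError("baseline config must not carry a c3f_rn block")
    _check_mults(cfg)
    return YoloModel(cfg)


def assemble_yolo_ginseng(cfg: ModelConfig) -> YoloModel:
    """Build the detector with all four backbone C3 stages replaced by
    C3f-RN blocks of matching width and repeat count."""
    if cfg.c3f_rn is None:
        raise ValueError("ginseng config requires a c3f_rn block")
    _check_mults(cfg)
    return YoloModel(cfg)


def _check_mults(cfg: ModelConfig):
    if not (0 < cfg.width_mult <= 2) or not (0 < cfg.depth_mult <= 2):
        raise ValueError("unsupported width/depth multipliers")


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def count_parameters(model: nn.Module, fused: bool = False) -> int:
    """Exact count of learnable scalars.

    With ``fused=True`` the model is (a copy is) first put into deploy form:
    every Conv+BN pair folds into one biased convolution, losing exactly
    one scalar per BN channel.
    """
    if fused:
        model = fuse_model(copy.deepcopy(model))
    return int(sum(p.size for p in model.parameters()))


def fuse_model(model: nn.Module) -> nn.Module:
    """In-place conv+BN fusion of every ConvBlock; returns the model."""
    for m in model.modules():
        if isinstance(m, ConvBlock):
            m.fuse()
    return model


def count_flops(model: nn.Module, img_size: int = 640,
                probe: int = 64) -> float:
    """GFLOPs at the given input resolution: 2 x multiply-accumulates of
    convolution and linear layers only (the usual profiling convention).

    The model is probed at a small resolution and the count is scaled
    quadratically, which is exact for the convolutional graph.
    """
    if img_size % 32:
        raise ValueError("img_size must be divisible by 32")
    probe = min(probe, img_size)
    mode = model.training
    model.eval()
    F.reset_flop_counter()
    F.enable_flop_counter(True)
    try:
        model(Tensor(np.zeros((1, 3, probe, probe), dtype=np.float32)))
    finally:
        F.enable_flop_counter(False)
        model.train(mode)
    macs = F.flop_counter_value()
    return 2.0 * macs * (img_size / probe) ** 2 / 1e9


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def letterbox(img: np.ndarray, size: int, color: int = 114):
    """Aspect-preserving resize onto a size x size gray canvas.

    Returns (canvas, scale, (pad_x, pad_y))."""
    h, w = img.shape[:2]
    r = min(size / h, size / w)
    nh, nw = int(round(h * r)), int(round(w * r))
    # nearest-neighbour resize (no external deps needed here)
    yi = (np.arange(nh) / r).astype(int).clip(0, h - 1)
    xi = (np.arange(nw) / r).astype(int).clip(0, w - 1)
    resized = img[yi][:, xi]
    canvas = np.full((size, size, img.shape[2]), color, dtype=img.dtype)
    py, px = (size - nh) // 2, (size - nw) // 2
    canvas[py:py + nh, px:px + nw] = resized
    return canvas, r, (px, py)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (M,4) / (N,4) corner-format box arrays."""
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression.

    Ties in confidence are broken by larger box area (stable and
    order-independent)."""
    if len(boxes) == 0:
        return np.zeros(0, dtype=int)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    order = np.lexsort((-areas, -scores))
    keep = []
    iou = box_iou_matrix(boxes, boxes)
    alive = np.ones(len(boxes), dtype=bool)
    for i in order:
        if not alive[i]:
            continue
        keep.append(i)
        alive &= iou[i] <= iou_thr
        alive[i] = False
    return np.asarray(keep, dtype=int)


def _decode(raw, model: YoloModel, conf_thr: float):
    det = model.detect
    na, no = det.na, det.no
    out = []
    for p, s, anchors in zip(raw, det.strides, det.anchors):
        a = p.data if isinstance(p, Tensor) else p
        if not np.isfinite(a).all():
            raise InferenceError(f"non-finite activations in the stride-{s} "
                                 "detection head")
        N, _, H, W = a.shape
        a = a.reshape(N, na, no, H, W).transpose(0, 1, 3, 4, 2)
        z = 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60)))
        gy, gx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        xy = (z[..., :2] * 2.0 - 0.5 + np.stack([gx, gy], axis=-1)) * s
        wh = (z[..., 2:4] * 2.0) ** 2 * anchors[:, None, None, :]
        conf = z[..., 4:5] * (z[..., 5:] if det.nc > 1 else 1.0)
        cls = conf.argmax(axis=-1)
        score = conf.max(axis=-1)
        m = score > conf_thr
        out.append(np.concatenate([
            (xy - wh / 2)[m], (xy + wh / 2)[m],
            score[m][:, None], cls[m][:, None]], axis=1))
    return np.concatenate(out, axis=0) if out else np.zeros((0, 6))


def predict(model: YoloModel, images, conf_thr: float = 0.25,
            iou_thr: float = 0.45):
    """Run the detector on a list of HxWx3 uint8 images.

    Images are letterboxed to the configured input size; decoded boxes are
    thresholded, NMS-suppressed, and mapped back to the original frame.
    Returns one :class:`DetectionSet` per image.
    """
    size = model.cfg.img_size
    mode = model.training
    model.eval()
    results = []
    try:
        for img in images:
            canvas, r, (px, py) = letterbox(img, size)
            x = canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
            raw = model(Tensor(x))
            dets = _decode(raw, model, conf_thr)
            if len(dets):
                keep = nms(dets[:, :4], dets[:, 4], iou_thr)
                dets = dets[keep]
            boxes = dets[:, :4].copy()
            boxes[:, [0, 2]] = (boxes[:, [0, 2]] - px) / r
            boxes[:, [1, 3]] = (boxes[:, [1, 3]] - py) / r
            h, w = img.shape[:2]
            boxes[:, [0, 2]] = boxes[:, [0, 2]].clip(0, w)
            boxes[:, [1, 3]] = boxes[:, [1, 3]].clip(0, h)
            ok = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
            results.append(DetectionSet(boxes[ok],
                                        dets[ok, 4].copy(),
                                        dets[ok, 5].astype(int)))
    finally:
        model.train(mode)
    return results
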