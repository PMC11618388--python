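"""Composite single-stage detection loss: CIoU box + BCE objectness
(+ BCE classification when nc > 1), with the standard anchor-based target
assignment (shape-ratio filter, 0.5-cell neighbour expansion)."""

from __future__ import annotations

import math

import numpy as np

from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["DetectionLoss"]


def _ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between predicted (M,4) cx,cy,w,h tensors and constant
    targets of the same layout."""
    px = pred.narrow(1, 0, 1)
    py = pred.narrow(1, 1, 1)
    pw = F.clamp_min(pred.narrow(1, 2, 1), 1e-4)
    ph = F.clamp_min(pred.narrow(1, 3, 1), 1e-4)
    tx, ty = target[:, 0:1], target[:, 1:2]
    tw, th = target[:, 2:3], target[:, 3:4]

    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    tx1, tx2 = tx - tw / 2, tx + tw / 2
    ty1, ty2 = ty - th / 2, ty + th / 2

    iw = _minimum(px2, tx2) - _maximum(px1, tx1)
    ih = _minimum(py2, ty2) - _maximum(py1, ty1)
    iw = F.clamp_min(iw, 0.0)
    ih = F.clamp_min(ih, 0.0)
    inter = iw * ih
    union = pw * ph + tw * th - inter + 1e-7
    iou = inter / union

    cw = _maximum(px2, tx2) - _minimum(px1, tx1)
    ch = _maximum(py2, ty2) - _minimum(py1, ty1)
    c2 = cw * cw + ch * ch + 1e-7
    rho2 = (px - tx) ** 2.0 + (py - ty) ** 2.0
    t_atan = np.arctan(tw / np.maximum(th, 1e-7)).astype(np.float32)
    v = (4.0 / math.pi ** 2) * (t_atan - F.atan(pw / ph)) ** 2.0
    alpha = v.data / (1.0 - iou.data + v.data + 1e-7)   # treated as constant
    return iou - rho2 / c2 - v * alpha


def _maximum(a: Tensor, b) -> Tensor:
    bd = b.data if isinstance(b, Tensor) else np.asarray(b, dtype=np.float32)
    mask = a.data >= bd
    if isinstance(b, Tensor):
        def bw(g):
            if a.requires_grad:
                a._accum(g * mask)
            if b.requires_grad:
                b._accum(g * ~mask)
        return Tensor._make(np.maximum(a.data, bd), (a, b), bw)
    return Tensor._make(np.maximum(a.data, bd), (a,),
                        lambda g: a._accum(g * mask))


def _minimum(a: Tensor, b) -> Tensor:
    bd = b.data if isinstance(b, Tensor) else np.asarray(b, dtype=np.float32)
    mask = a.data <= bd
    if isinstance(b, Tensor):
        def bw(g):
            if a.requires_grad:
                a._accum(g * mask)
            if b.requires_grad:
                b._accum(g * ~mask)
        return Tensor._make(np.minimum(a.data, bd), (a, b), bw)
    return Tensor._make(np.minimum(a.data, bd), (a,),
                        lambda g: a._accum(g * mask))


class DetectionLoss:
    def __init__(self, model, box=0.05, obj=1.0, cls=0.5, anchor_t=4.0):
        det = model.detect
        self.na, self.no, self.nc = det.na, det.no, det.nc
        self.strides = det.strides
        self.anchors = det.anchors / np.asarray(det.strides)[:, None, None]
        self.hyp = dict(box=box, obj=obj, cls=cls, anchor_t=anchor_t)
        self.balance = (4.0, 1.0, 0.4)

    def build_targets(self, shapes, targets: np.ndarray):
        """Assign ground-truth rows (img, cls, cx, cy, w, h; normalised) to
        anchors and grid cells for every scale."""
        na, nt = self.na, len(targets)
        out = []
        ai = np.tile(np.arange(na, dtype=np.float32)[:, None], (1, nt))
        t0 = np.concatenate(
            [np.tile(targets[None], (na, 1, 1)), ai[..., None]], axis=2)
        g = 0.5
        offs = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1]],
                        dtype=np.float32) * g
        for i, (H, W) in enumerate(shapes):
            anchors = self.anchors[i]
            gain = np.array([1, 1, W, H, W, H, 1], dtype=np.float32)
            t = t0 * gain
            if nt:
                r = t[..., 4:6] / anchors[:, None]
                keep = np.maximum(r, 1 / r).max(axis=2) < self.hyp["anchor_t"]
                t = t[keep]
                gxy = t[:, 2:4]
                gxi = gain[2:4] - gxy
                j, k = ((gxy % 1 < g) & (gxy > 1)).T
                l, m = ((gxi % 1 < g) & (gxi > 1)).T
                sel = np.stack([np.ones_like(j), j, k, l, m])
                t = np.tile(t[None], (5, 1, 1))[sel]
                offsets = (np.zeros_like(gxy)[None] + offs[:, None])[sel]
            else:
                t = np.zeros((0, 7), dtype=np.float32)
                offsets = np.zeros((0, 2), dtype=np.float32)
            b = t[:, 0].astype(int)
            c = t[:, 1].astype(int)
            gxy = t[:, 2:4]
            gwh = t[:, 4:6]
            gij = (gxy - offsets).astype(int)
            gi = gij[:, 0].clip(0, W - 1)
            gj = gij[:, 1].clip(0, H - 1)
            a = t[:, 6].astype(int)
            out.append((b, c, a, gj, gi, gxy - gij, gwh,
                        self.anchors[i][a] if len(a) else
                        np.zeros((0, 2), dtype=np.float32)))
        return out

    def __call__(self, preds, targets: np.ndarray):
        """preds: raw head maps [(N, na*no, H, W)]; targets: (T, 6)."""
        lbox = Tensor(0.0)
        lobj = Tensor(0.0)
        lcls = Tensor(0.0)
        shapes = [(p.shape[2], p.shape[3]) for p in preds]
        assigned = self.build_targets(shapes, targets)
        N = preds[0].shape[0]
        for i, p in enumerate(preds):
            H, W = shapes[i]
            b, c, a, gj, gi, txy, twh, anch = assigned[i]
            pv = p.reshape(N, self.na, self.no, H, W)
            pv = pv.transpose(0, 1, 3, 4, 2)          # N, na, H, W, no
            tobj = np.zeros((N, self.na, H, W), dtype=np.float32)
            if len(b):
                rows = ((b * self.na + a) * H + gj) * W + gi
                flat = rows[:, None] * self.no + np.arange(self.no)
                sel = F.take(pv, flat)                # (M, no)
                ps = F.sigmoid(sel)
                pxy = ps.narrow(1, 0, 2) * 2.0 - 0.5
                pwh = (ps.narrow(1, 2, 2) * 2.0) ** 2.0 * anch
                pbox = F.concat([pxy, pwh], axis=1)
                tbox = np.concatenate([txy, twh], axis=1).astype(np.float32)
                ciou = _ciou(pbox, tbox)
                lbox = lbox + (1.0 - ciou).mean()
                iou_d = np.clip(ciou.data.reshape(-1), 0, None)
                np.maximum.at(tobj, (b, a, gj, gi), iou_d)
                if self.nc > 1:
                    tcls = np.zeros((len(b), self.nc), dtype=np.float32)
                    tcls[np.arange(len(b)), c] = 1.0
                    lcls = lcls + F.bce_with_logits(sel.narrow(1, 5, self.nc),
                                                    tcls)
            obj_logits = pv.narrow(4, 4, 1).reshape(N, self.na, H, W)
            lobj = lobj + F.bce_with_logits(obj_logits, tobj) * self.balance[i]
        loss = (lbox * self.hyp["box"] + lobj * self.hyp["obj"]
                + lcls * self.hyp["cls"])
        parts = {"box": float(lbox.data), "obj": float(lobj.data),
                 "cls": float(lcls.data)}
        return loss * N, parts
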