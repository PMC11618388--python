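"""Channel pruning in three stages: L1-sparse training of BN scale factors,
global-threshold channel removal, and fine-tuning.

The per-channel batch-norm scale gamma measures how much a channel
contributes downstream; an L1 subgradient (``lambda * sign(gamma)``)
added during training drives unimportant scales towards zero, after which
channels whose |gamma| falls below a network-wide quantile threshold are
physically removed — together with the producing filters and the matching
consumer kernel slices — and the slimmed model is fine-tuned from its own
weights until performance recovers.

Surgery operates on *prune groups*: a (conv, BN) pair plus the exact
input segments of every downstream consumer.  Channels that feed residual
additions, channel splits or branch sums are structurally coupled and are
left protected rather than masked jointly; the prunable set (bottleneck
hidden channels, SPPF/C3 partial paths, attention-stage entries, the
coordinate-attention reduction) already covers the bulk of the network's
width.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import nn
from .layers import C3, SPPF, ConvBlock, CspBottleneck
from .c3f_rn import C3fRN, PerceptionBottleneck
from .model import Detect, count_parameters
from .primitives import CoordinateAttention

__all__ = [
    "PruneConfig", "PruneReport", "sparse_step", "gamma_summary",
    "prune_threshold", "prune", "finetune", "compress_pipeline",
    "build_prune_plan", "PruneGroup", "ToyConvNet", "ToyDetector",
    "LAMBDA_GRID", "RATIO_GRID",
]

LAMBDA_GRID = (0.001, 0.002, 0.003, 0.004, 0.005)
RATIO_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass
class PruneConfig:
    """Sparsity rate (L1 coefficient on BN gamma), pruning coefficient
    (global fraction of channels removed) and the protection policy."""

    lam: float = 0.002
    r: float = 0.8
    min_channels: int = 8
    protected: tuple = ()

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("sparsity rate must be >= 0")
        if not (0 <= self.r < 1):
            raise ValueError("pruning coefficient must lie in [0, 1)")


@dataclass
class PruneReport:
    masks: Dict[str, np.ndarray]
    layers_touched: int
    channels_removed: int
    channels_before: int
    params_before: int
    params_after: int

    def to_json(self) -> str:
        return json.dumps({
            "layers_touched": self.layers_touched,
            "channels_removed": self.channels_removed,
            "channels_before": self.channels_before,
            "params_before": self.params_before,
            "params_after": self.params_after,
            "masks": {k: np.asarray(v).astype(int).tolist()
                      for k, v in self.masks.items()},
        })


@dataclass
class PruneGroup:
    """One prunable (conv, BN) pair and its consumer kernel slices."""

    name: str
    block: ConvBlock
    consumers: List = field(default_factory=list)  # filled via plan


# ---------------------------------------------------------------------------
# plan construction
# ---------------------------------------------------------------------------

def build_prune_plan(model: nn.Module):
    """Discover prunable groups and consumer input segments.

    Returns (groups, consumer_segments) where ``consumer_segments`` maps a
    consumer Conv2d to an ordered list of (group_index_or_None, width)
    covering its input channels.
    """
    if hasattr(model, "prune_plan"):
        return model.prune_plan()
    groups: List[PruneGroup] = []
    segs: Dict[int, List] = {}
    conv_of: Dict[int, object] = {}

    def add_group(name, block):
        groups.append(PruneGroup(name, block))
        return len(groups) - 1

    def set_segs(conv2d, seglist):
        segs[id(conv2d)] = seglist
        conv_of[id(conv2d)] = conv2d

    for name, m in model.named_modules():
        if isinstance(m, CspBottleneck):
            gi = add_group(f"{name}.cv1", m.cv1)
            set_segs(m.cv2.conv, [(gi, m.cv1.c2)])
        elif isinstance(m, PerceptionBottleneck):
            gi = add_group(f"{name}.cv1", m.cv1)
            set_segs(m.cv2.conv, [(gi, m.cv1.c2)])
        elif isinstance(m, SPPF):
            gi = add_group(f"{name}.cv1", m.cv1)
            set_segs(m.cv2.conv, [(gi, m.cv1.c2)] * 4)
        elif isinstance(m, C3):
            c_ = m.cv2.c2
            gi = add_group(f"{name}.cv2", m.cv2)
            set_segs(m.cv3.conv, [(None, c_), (gi, c_)])
        elif isinstance(m, C3fRN):
            gi = add_group(f"{name}.sconv", m.sconv)
            set_segs(m.swin.embed, [(gi, m.sconv.c2)])
        elif isinstance(m, CoordinateAttention):
            gi = add_group(f"{name}.conv1", _CABlock(m))
            set_segs(m.conv_h, [(gi, m.mid)])
            set_segs(m.conv_w, [(gi, m.mid)])
    return groups, {k: (conv_of[k], v) for k, v in segs.items()}


class _CABlock:
    """Adapter presenting CoordinateAttention's conv1+bn1 as a ConvBlock."""

    def __init__(self, ca):
        self.conv = ca.conv1
        self.bn = ca.bn1
        self.c2 = ca.mid
        self._ca = ca

    def apply_keep(self, keep):
        _slice_conv_out(self.conv, keep)
        _slice_bn(self.bn, keep)
        self._ca.mid = len(keep)


# ---------------------------------------------------------------------------
# sparse training and the gamma signal
# ---------------------------------------------------------------------------

def _prunable_bns(model) -> Dict[str, nn.BatchNorm2d]:
    groups, _ = build_prune_plan(model)
    return {g.name: g.block.bn for g in groups if g.block.bn is not None}


def sparse_step(model: nn.Module, lam: float):
    """Add the L1 subgradient ``lam * sign(gamma)`` to every prunable BN
    scale gradient; call between ``backward()`` and the optimiser step."""
    if not getattr(model, "training", False):
        raise RuntimeError("sparse_step requires a model in training mode")
    for bn in _prunable_bns(model).values():
        g = np.sign(bn.weight.data) * lam
        if bn.weight.grad is None:
            bn.weight.grad = g.astype(np.float32)
        else:
            bn.weight.grad += g


def gamma_summary(model: nn.Module, bins: int = 50):
    """Distribution summary of |gamma| over all prunable channels."""
    vals = np.concatenate([np.abs(bn.weight.data)
                           for bn in _prunable_bns(model).values()])
    if vals.size == 0:
        raise ValueError("model has no prunable BN layers")
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    hist, edges = np.histogram(vals, bins=bins)
    return {
        "n_channels": int(vals.size),
        "median": float(np.median(vals)),
        "quantiles": {str(q): float(np.quantile(vals, q)) for q in qs},
        "hist_counts": hist.tolist(),
        "hist_edges": edges.tolist(),
        "values": vals,
    }


def prune_threshold(model: nn.Module, r: float) -> float:
    """Global threshold: the r-quantile of |gamma| pooled over all
    prunable channels; channels strictly below it are marked."""
    if not (0 <= r < 1):
        raise ValueError("pruning coefficient must lie in [0, 1)")
    if r == 0:
        return 0.0
    vals = np.concatenate([np.abs(bn.weight.data)
                           for bn in _prunable_bns(model).values()])
    return float(np.quantile(vals, r))


# ---------------------------------------------------------------------------
# surgery
# ---------------------------------------------------------------------------

def _slice_conv_out(conv: nn.Conv2d, keep):
    conv.weight.data = np.ascontiguousarray(conv.weight.data[keep])
    conv.weight.grad = None
    if conv.bias is not None:
        conv.bias.data = np.ascontiguousarray(conv.bias.data[keep])
        conv.bias.grad = None
    conv.c2 = len(keep)


def _slice_conv_in(conv: nn.Conv2d, keep):
    conv.weight.data = np.ascontiguousarray(conv.weight.data[:, keep])
    conv.weight.grad = None
    conv.c1 = len(keep)


def _slice_bn(bn: nn.BatchNorm2d, keep):
    bn.weight.data = np.ascontiguousarray(bn.weight.data[keep])
    bn.bias.data = np.ascontiguousarray(bn.bias.data[keep])
    bn.weight.grad = bn.bias.grad = None
    bn._buffers["running_mean"] = bn.running_mean[keep].copy()
    bn._buffers["running_var"] = bn.running_var[keep].copy()
    bn.c = len(keep)


def prune(model: nn.Module, threshold: float,
          config: Optional[PruneConfig] = None):
    """Remove every prunable channel with |gamma| < threshold.

    Produces a deep-copied, shape-consistent, forward-runnable model plus a
    :class:`PruneReport`.  The protection policy keeps at least
    ``config.min_channels`` (default 8) channels per layer and skips any
    group named in ``config.protected``.
    """
    config = config or PruneConfig(r=0.0)
    model = copy.deepcopy(model)
    params_before = count_parameters(model)
    groups, consumers = build_prune_plan(model)
    masks, keeps = {}, {}
    channels_before = 0
    for gi, grp in enumerate(groups):
        gamma = grp.block.bn.weight.data
        c = gamma.shape[0]
        channels_before += c
        keep_mask = np.abs(gamma) >= threshold
        if grp.name in (config.protected or ()):
            keep_mask[:] = True
        min_keep = min(config.min_channels, c)
        if keep_mask.sum() < min_keep:
            top = np.argsort(-np.abs(gamma), kind="stable")[:min_keep]
            keep_mask[:] = False
            keep_mask[top] = True
        if keep_mask.sum() == 0:
            raise RuntimeError(f"group {grp.name} would lose all channels")
        masks[grp.name] = keep_mask
        keeps[gi] = np.nonzero(keep_mask)[0]

    # phase 1: slice producers
    for gi, grp in enumerate(groups):
        keep = keeps[gi]
        if hasattr(grp.block, "apply_keep"):
            grp.block.apply_keep(keep)
        else:
            _slice_conv_out(grp.block.conv, keep)
            _slice_bn(grp.block.bn, keep)
            grp.block.c2 = len(keep)

    # phase 2: rebuild every consumer's input slice from its segments
    for conv, seglist in consumers.values():
        sel, off = [], 0
        for gref, width in seglist:
            if gref is None:
                sel.append(off + np.arange(width))
            else:
                sel.append(off + keeps[gref])
            off += width
        _slice_conv_in(conv, np.concatenate(sel))

    removed = int(sum(int((~m).sum()) for m in masks.values()))
    touched = int(sum(1 for m in masks.values() if (~m).any()))
    report = PruneReport(masks, touched, removed, channels_before,
                         params_before, count_parameters(model))
    return model, report


def finetune(model, train_set, val_set, hyp=None):
    """Continue training from the pruned weights (structure frozen)."""
    from .train import train
    return train(model, train_set, val_set, hyp=hyp)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def compress_pipeline(model, train_set, val_set, config: PruneConfig,
                      hyp_sparse=None, hyp_finetune=None, quiet=True):
    """Sparse training -> pruning -> fine-tuning, with a four-stage summary
    (AP@0.5, parameter count, weight size, single-image inference time)."""
    from .metrics import evaluate
    from .train import train

    def stage_stats(m):
        t0 = time.perf_counter()
        res = evaluate(m, val_set)
        dt = (time.perf_counter() - t0) / max(len(val_set), 1) * 1e3
        n = count_parameters(m)
        return {"ap": res.ap, "parameters": n,
                "size_mb": round(n * 4 / 1e6, 2), "inference_ms": round(dt, 1)}

    summary = {"initial": stage_stats(model)}
    if config.lam > 0:
        model, _ = train(model, train_set, val_set, hyp=hyp_sparse,
                         on_step=lambda m: sparse_step(m, config.lam),
                         quiet=quiet)
    summary["sparse"] = stage_stats(model)
    thr = prune_threshold(model, config.r)
    model, report = prune(model, thr, config)
    summary["prune"] = stage_stats(model)
    if hyp_finetune is not None or config.r > 0:
        model, _ = finetune(model, train_set, val_set, hyp=hyp_finetune)
    summary["finetune"] = stage_stats(model)
    return model, report, summary


# ---------------------------------------------------------------------------
# toy networks (desk-scale pruning experiments)
# ---------------------------------------------------------------------------

class ToyConvNet(nn.Module):
    """Shortcut-free conv chain for the masked-equivalence oracle."""

    def __init__(self, widths=(3, 8, 8), n_out=4, seed=0):
        super().__init__()
        nn.seed_init(seed)
        blocks = []
        for c1, c2 in zip(widths[:-1], widths[1:]):
            blocks.append(ConvBlock(c1, c2, 3))
        self.body = nn.ModuleList(blocks)
        self.head = nn.Conv2d(widths[-1], n_out, 1, bias=True)

    def forward(self, x):
        for b in self.body:
            x = b(x)
        return self.head(x)

    def prune_plan(self):
        groups, segs = [], {}
        blocks = list(self.body)
        for i, b in enumerate(blocks):
            groups.append(PruneGroup(f"body.{i}", b))
            consumer = blocks[i + 1].conv if i + 1 < len(blocks) else self.head
            segs[id(consumer)] = (consumer, [(i, b.c2)])
        return groups, segs


class ToyDetector(nn.Module):
    """Tiny single-scale detector for the compression experiments:
    four stride-halving conv blocks and a one-scale anchor head."""

    def __init__(self, widths=(8, 16, 16, 16), img_size=64, seed=0):
        super().__init__()
        nn.seed_init(seed)
        from .model import DEFAULT_ANCHORS, ModelConfig
        self.cfg = ModelConfig(nc=1, img_size=img_size)
        w0, w1, w2, w3 = widths
        self.b0 = ConvBlock(3, w0, 3, 2)
        self.b1 = ConvBlock(w0, w1, 3, 2)
        self.b2 = ConvBlock(w1, w2, 3, 2)
        self.b3 = ConvBlock(w2, w3, 3)
        self.detect = Detect([w3], 1, (DEFAULT_ANCHORS[0],), strides=(8,))

    def forward(self, x):
        return self.detect([self.b3(self.b2(self.b1(self.b0(x))))])

    def prune_plan(self):
        chain = [self.b0, self.b1, self.b2, self.b3]
        groups, segs = [], {}
        for i, b in enumerate(chain):
            groups.append(PruneGroup(f"b{i}", b))
            consumer = (chain[i + 1].conv if i + 1 < len(chain)
                        else self.detect.m[0])
            segs[id(consumer)] = (consumer, [(i, b.c2)])
        return groups, segs
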