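"""C3f-RN: dual-branch deep-perception feature-extraction block.

The block keeps the cross-stage-partial idea (split the channels, process
one part, re-merge) but runs two such branches in parallel and finishes
with a switchable atrous convolution and coordinate attention:

* **branch one** - 1x1 conv, channel split; one half bypasses, the other
  passes through ``n`` residual bottlenecks (two 3x3 convs each, SimAM
  tail); concat, 1x1 conv.
* **branch two** - 1x1 conv, channel split; one half passes through ``2n``
  bottlenecks whose residual flags alternate (residual, plain, ...); the
  other half goes through a 3x3 conv and a windowed-attention stage
  (:class:`~ginsengdet.primitives.SwinStage`); concat, 1x1 conv.
* **merge** - both branch outputs are projected by 1x1 convs and summed,
  then refined by switchable atrous convolution (+BN+SiLU) and coordinate
  attention.

Every sub-path preserves H x W, so the block can replace any same-width
backbone stage without touching the rest of the graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import nn
from .nn import functional as F
from .layers import ConvBlock
from .primitives import (CoordinateAttention, SimAM, SwinStage,
                         SwinStageConfig, SwitchableAtrousConv, num_windows)

__all__ = ["BottleneckSpec", "PerceptionBottleneck", "C3fRNConfig", "C3fRN",
           "heads_from_window"]


@dataclass
class BottleneckSpec:
    """Width/flags of one perception bottleneck."""

    channels: int
    residual: bool = True
    simam_tail: bool = True


class PerceptionBottleneck(nn.Module):
    """Two 3x3 convs, optional identity shortcut, optional SimAM tail.

    SimAM adds zero learnable parameters, so ``simam_tail`` never changes
    the parameter count.
    """

    def __init__(self, spec: BottleneckSpec, c_in: int = None):
        super().__init__()
        c = spec.channels
        c_in = c if c_in is None else c_in
        if spec.residual and c_in != c:
            raise ValueError("residual bottleneck requires matching channels")
        self.cv1 = ConvBlock(c_in, c, 3)
        self.cv2 = ConvBlock(c, c, 3)
        self.add = spec.residual
        self.simam = SimAM() if spec.simam_tail else None

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        if self.add:
            y = x + y
        if self.simam is not None:
            y = self.simam(y)
        return y


@dataclass
class C3fRNConfig:
    """Hyper-parameters of one C3f-RN block.

    ``n_repeats`` is inherited from the host backbone stage.  The hidden
    width equals ``hidden_ratio * c_out`` and must split into even halves.
    The attention stage always projects onto ``swin.embed_dim`` channels,
    a width shared by every insertion point.
    """

    c_in: int
    c_out: int
    n_repeats: int = 1
    hidden_ratio: float = 1.0
    swin: SwinStageConfig = field(default_factory=SwinStageConfig)

    def __post_init__(self):
        if self.c_in <= 0 or self.c_out <= 0:
            raise ValueError("channel counts must be positive")
        h = int(self.c_out * self.hidden_ratio)
        if h % 2:
            raise ValueError("hidden width must be even (channel split)")


class C3fRN(nn.Module):
    def __init__(self, cfg: C3fRNConfig):
        super().__init__()
        self.cfg = cfg
        c, n = cfg.c_out, cfg.n_repeats
        h = int(c * cfg.hidden_ratio)
        half = h // 2
        self.half = half

        # branch one: residual bottleneck chain
        self.cv1_a = ConvBlock(cfg.c_in, h, 1)
        self.m_a = nn.Sequential(*[
            PerceptionBottleneck(BottleneckSpec(half, residual=True))
            for _ in range(n)])
        self.cv2_a = ConvBlock(2 * half, h, 1)
        self.proj_a = ConvBlock(h, c, 1)

        # branch two: interleaved bottlenecks + windowed attention
        self.cv1_b = ConvBlock(cfg.c_in, h, 1)
        self.m_b = nn.Sequential(*[
            PerceptionBottleneck(BottleneckSpec(half, residual=(i % 2 == 0)))
            for i in range(2 * n)])
        self.sconv = ConvBlock(half, half, 3)
        self.swin = SwinStage(half, cfg.swin)
        self.cv2_b = ConvBlock(half + cfg.swin.embed_dim, h, 1)
        self.proj_b = ConvBlock(h, c, 1)

        # merge: switchable atrous conv + coordinate attention
        self.sac = SwitchableAtrousConv(c, c, 3, rates=(1, 3))
        self.sac_bn = nn.BatchNorm2d(c)
        self.ca = CoordinateAttention(c, reduction=32)

    def branch_one(self, x):
        y = self.cv1_a(x)
        bypass = y.narrow(1, 0, self.half)
        chain = self.m_a(y.narrow(1, self.half, self.half))
        return self.proj_a(self.cv2_a(F.concat([bypass, chain], axis=1)))

    def branch_two(self, x):
        y = self.cv1_b(x)
        chain = self.m_b(y.narrow(1, 0, self.half))
        attn = self.swin(self.sconv(y.narrow(1, self.half, self.half)))
        return self.proj_b(self.cv2_b(F.concat([chain, attn], axis=1)))

    def forward(self, x):
        if x.shape[1] != self.cfg.c_in:
            raise ValueError(
                f"expected {self.cfg.c_in} input channels, got {x.shape[1]}")
        y = self.branch_one(x) + self.branch_two(x)
        y = F.silu(self.sac_bn(self.sac(y)))
        return self.ca(y)


def heads_from_window(H: int, W: int, win_size: int,
                      embed_dim: int = 64) -> int:
    """Suggested attention-head count from the window tiling.

    ``num_wins = H*W / win_size**2`` (padded when the window does not tile
    evenly); the suggestion is ``round(sqrt(num_wins))`` snapped down to the
    nearest divisor of ``embed_dim``.  The final head count remains a user
    choice validated by experiment.
    """
    if H <= 0 or W <= 0 or win_size <= 0:
        raise ValueError("H, W, win_size must be positive")
    s = max(1, round(math.sqrt(num_windows(H, W, win_size))))
    while embed_dim % s:
        s -= 1
    return s
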