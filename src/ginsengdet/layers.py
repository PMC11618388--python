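"""Convolutional building blocks shared by the baseline and the improved
backbone: Conv+BN+SiLU, the CSP bottleneck/C3 pair, and SPPF."""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F

__all__ = ["ConvBlock", "CspBottleneck", "C3", "SPPF", "make_divisible"]


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(round(x / divisor) * divisor))


class ConvBlock(nn.Module):
    """Conv2d (no bias) + BatchNorm + SiLU; fusable for deployment."""

    def __init__(self, c1, c2, k=1, stride=1, padding=None, act=True):
        super().__init__()
        self.c1, self.c2 = c1, c2
        self.conv = nn.Conv2d(c1, c2, k, stride=stride, padding=padding)
        self.bn = nn.BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        if self.bn is not None:
            y = self.bn(self.conv(x))
        else:
            y = self.conv(x)
        return F.silu(y) if self.act else y

    def fuse(self):
        """Fold the batch norm into the convolution (deploy form).

        The conv gains a bias; the BN disappears, so the block loses exactly
        ``c2`` learnable scalars."""
        if self.bn is None:
            return
        bn, conv = self.bn, self.conv
        inv = 1.0 / np.sqrt(bn.running_var + bn.eps)
        scale = bn.weight.data * inv
        fused = nn.Conv2d(conv.c1, conv.c2, conv.k, stride=conv.stride,
                          padding=conv.padding, dilation=conv.dilation,
                          bias=True)
        fused.weight.data[...] = conv.weight.data * scale.reshape(-1, 1, 1, 1)
        fused.bias.data[...] = bn.bias.data - bn.weight.data * bn.running_mean * inv
        self.conv = fused
        self.bn = None


class CspBottleneck(nn.Module):
    """Standard CSP bottleneck: 1x1 then 3x3, optional identity shortcut."""

    def __init__(self, c1, c2, shortcut=True):
        super().__init__()
        self.cv1 = ConvBlock(c1, c2, 1)
        self.cv2 = ConvBlock(c2, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(nn.Module):
    """Cross-stage-partial block with three 1x1 convs and n bottlenecks."""

    def __init__(self, c1, c2, n=1, shortcut=True):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = ConvBlock(c1, c_, 1)
        self.cv2 = ConvBlock(c1, c_, 1)
        self.cv3 = ConvBlock(2 * c_, c2, 1)
        self.m = nn.Sequential(*[CspBottleneck(c_, c_, shortcut)
                                 for _ in range(n)])

    def forward(self, x):
        return self.cv3(F.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max pools."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBlock(c1, c_, 1)
        self.cv2 = ConvBlock(4 * c_, c2, 1)
        self.k = k

    def forward(self, x):
        y = self.cv1(x)
        p1 = F.maxpool2d(y, self.k, 1, self.k // 2)
        p2 = F.maxpool2d(p1, self.k, 1, self.k // 2)
        p3 = F.maxpool2d(p2, self.k, 1, self.k // 2)
        return self.cv2(F.concat([y, p1, p2, p3], axis=1))
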