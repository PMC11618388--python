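"""Reusable perception operators composed by the C3f-RN block.

All operators preserve the spatial extent of their input feature map
(N, C, H, W): that shape contract is what makes the enclosing block
drop-in compatible with any same-width stage of a detector backbone.

Contents
--------
* :func:`bn_forward` / :class:`BNLayerState` - the batch-normalisation
  affine transform whose per-channel scale gamma later serves as the
  channel-importance signal for pruning.
* :class:`SimAM` - parameter-free energy-based attention.
* :class:`CoordinateAttention` - direction-factorised channel attention.
* :class:`SwitchableAtrousConv` - two dilation rates blended per position
  by a learned switch, sharing one weight-standardised kernel.
* :func:`window_partition` / :func:`window_reverse` - lossless tiling of a
  feature map into square local windows (with right/bottom zero padding).
* :class:`SwinStage` - patch partition + linear embedding + an even stack
  of windowed multi-head self-attention blocks alternating plain and
  shifted window layouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Parameter, Tensor, as_tensor

__all__ = [
    "BNLayerState", "bn_forward", "SimAM", "CoordinateAttention",
    "SwitchableAtrousConv", "window_partition", "window_reverse",
    "SwinStageConfig", "SwinStage", "num_windows",
]


# ---------------------------------------------------------------------------
# batch-norm affine transform
# ---------------------------------------------------------------------------

@dataclass
class BNLayerState:
    """Per-channel batch-norm state (gamma, beta, mu, sigma, eps).

    ``sigma`` is the running standard deviation; the layer output is
    ``y = gamma * (x - mu) / sqrt(sigma^2 + eps) + beta``.
    """

    gamma: np.ndarray
    beta: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    eps: float = 1e-3

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        n = self.gamma.shape[0]
        if not (self.beta.shape[0] == self.mean.shape[0] == self.std.shape[0] == n):
            raise ValueError("BN state vectors must share one channel count")
        if self.eps <= 0:
            raise ValueError("BN eps must be positive")
        if np.any(self.std < 0):
            raise ValueError("BN running std must be non-negative")

    @property
    def channels(self) -> int:
        return self.gamma.shape[0]


def bn_forward(x: np.ndarray, state: BNLayerState) -> np.ndarray:
    """Apply the batch-norm affine transform channel-wise to (N, C, H, W)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4 or x.shape[1] != state.channels:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1] if x.ndim == 4 else '?'}"
            f" channels, state has {state.channels}")
    c = state.channels
    shape = (1, c, 1, 1)
    inv = 1.0 / np.sqrt(state.std.reshape(shape) ** 2 + state.eps)
    return (state.gamma.reshape(shape) * (x - state.mean.reshape(shape)) * inv
            + state.beta.reshape(shape))


# ---------------------------------------------------------------------------
# SimAM
# ---------------------------------------------------------------------------

class SimAM(nn.Module):
    """Parameter-free attention from an energy function over each channel.

    Every activation is weighted by a sigmoid of its (inverse) energy
    ``d / (4 (v + lambda)) + 0.5`` where ``d`` is the squared deviation from
    the channel mean and ``v`` the channel variance over ``n - 1`` positions.
    Adds exactly zero learnable parameters.
    """

    def __init__(self, e_lambda: float = 1e-4):
        super().__init__()
        self.e_lambda = e_lambda

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        n = max(h * w - 1, 1)
        mu = x.mean(axis=(2, 3), keepdims=True)
        d = (x - mu) ** 2.0
        v = d.sum(axis=(2, 3), keepdims=True) * (1.0 / n)
        e_inv = d / ((v + self.e_lambda) * 4.0) + 0.5
        return x * F.sigmoid(e_inv)


# ---------------------------------------------------------------------------
# Coordinate Attention
# ---------------------------------------------------------------------------

def _hard_swish(x: Tensor) -> Tensor:
    # x * relu6(x + 3) / 6
    t = F.clamp_min(x + 3.0, 0.0)
    six = t.data.copy()
    capped = Tensor._make(np.minimum(t.data, 6.0), (t,),
                          lambda g: t._accum(g * (six < 6.0)))
    return x * capped * (1.0 / 6.0)


class CoordinateAttention(nn.Module):
    """Channel attention factorised along the two spatial directions.

    The input is average-pooled along H and along W, the two directional
    encodings are jointly reduced by a 1x1 conv (intermediate width
    ``max(8, c // reduction)``), then split and expanded back into a
    height gate ``a_h`` (C, H, 1) and a width gate ``a_w`` (C, 1, W); the
    output is ``x * a_h * a_w``.
    """

    def __init__(self, c: int, reduction: int = 32):
        super().__init__()
        if reduction <= 0:
            raise ValueError("reduction must be positive")
        mid = max(8, c // reduction)
        self.mid = mid
        self.conv1 = nn.Conv2d(c, mid, 1, bias=True)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv_h = nn.Conv2d(mid, c, 1, bias=True)
        self.conv_w = nn.Conv2d(mid, c, 1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        ph = x.mean(axis=3, keepdims=True)                       # (N,C,H,1)
        pw = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (N,C,W,1)
        y = F.concat([ph, pw], axis=2)                            # (N,C,H+W,1)
        y = _hard_swish(self.bn1(self.conv1(y)))
        yh = y.narrow(2, 0, h)
        yw = y.narrow(2, h, w).transpose(0, 1, 3, 2)
        a_h = F.sigmoid(self.conv_h(yh))
        a_w = F.sigmoid(self.conv_w(yw))
        return x * a_h * a_w


# ---------------------------------------------------------------------------
# Switchable Atrous Convolution
# ---------------------------------------------------------------------------

class SwitchableAtrousConv(nn.Module):
    """3x3 convolution evaluated at two dilation rates and blended per pixel.

    ``y = S(x) * conv_r1(x) + (1 - S(x)) * conv_r2(x)`` with a shared,
    weight-standardised kernel (the second branch adds a learned weight
    delta), a switch head (5x5 average pool + 1x1 conv + sigmoid) and
    global-context 1x1 convolutions applied before and after.
    """

    def __init__(self, c1: int, c2: int, k: int = 3, rates=(1, 3)):
        super().__init__()
        r1, r2 = rates
        if r1 < 1 or r2 < 1:
            raise ValueError("dilation rates must be >= 1")
        if r1 == r2:
            warnings.warn("equal dilation rates: SAC degenerates to a plain "
                          "convolution", stacklevel=2)
        self.rates = (int(r1), int(r2))
        self.k = k
        self.conv = nn.Conv2d(c1, c2, k, bias=False)
        self.weight_diff = Parameter(np.zeros((c2, c1, k, k), dtype=np.float32))
        self.weight_gamma = Parameter(np.ones((c2, 1, 1, 1), dtype=np.float32))
        self.weight_beta = Parameter(np.zeros((c2, 1, 1, 1), dtype=np.float32))
        self.switch = nn.Conv2d(c1, 1, 1, bias=True)
        self.pre_context = nn.Conv2d(c1, c1, 1, bias=True)
        self.post_context = nn.Conv2d(c2, c2, 1, bias=True)

    def _standardised_weight(self) -> Tensor:
        w = self.conv.weight
        mu = w.mean(axis=(1, 2, 3), keepdims=True)
        var = ((w - mu) ** 2.0).mean(axis=(1, 2, 3), keepdims=True)
        w_hat = (w - mu) / F.sqrt(var + 1e-5)
        return self.weight_gamma * w_hat + self.weight_beta

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.pre_context(x.mean(axis=(2, 3), keepdims=True))
        s = F.sigmoid(self.switch(F.avgpool2d(x, 5, 1, 2)))
        w = self._standardised_weight()
        r1, r2 = self.rates
        pad1 = (self.k // 2) * r1
        pad2 = (self.k // 2) * r2
        y1 = F.conv2d(x, w, stride=1, padding=pad1, dilation=r1)
        y2 = F.conv2d(x, w + self.weight_diff, stride=1, padding=pad2,
                      dilation=r2)
        y = s * y1 + (1.0 - s) * y2
        return y + self.post_context(y.mean(axis=(2, 3), keepdims=True))


# ---------------------------------------------------------------------------
# windowed self-attention stage
# ---------------------------------------------------------------------------

def num_windows(H: int, W: int, win_size: int) -> int:
    """Window count of an H x W map tiled by win_size x win_size windows
    (after right/bottom padding to a multiple of the window size)."""
    if win_size <= 0:
        raise ValueError("win_size must be positive")
    hp = -(-H // win_size)
    wp = -(-W // win_size)
    return hp * wp


def window_partition(x, win_size: int):
    """Tile (N, C, H, W) into (N * num_wins, win_size, win_size, C) blocks.

    H and W are zero-padded up to multiples of ``win_size`` on the
    bottom/right; :func:`window_reverse` undoes the tiling and crops the
    padding, restoring the original map bit-for-bit.
    """
    if win_size <= 0:
        raise ValueError("win_size must be positive")
    t = as_tensor(x)
    n, c, h, w = t.shape
    ph = (-h) % win_size
    pw = (-w) % win_size
    if ph or pw:
        t = F.pad2d(t, (0, ph, 0, pw))
    hp, wp = h + ph, w + pw
    nh, nw = hp // win_size, wp // win_size
    t = t.reshape(n, c, nh, win_size, nw, win_size)
    t = t.transpose(0, 2, 4, 3, 5, 1)         # N, nh, nw, ws, ws, C
    return t.reshape(n * nh * nw, win_size, win_size, c)


def window_reverse(wins, win_size: int, H: int, W: int, C: int):
    """Inverse of :func:`window_partition` (crops any padding)."""
    t = as_tensor(wins)
    hp = -(-H // win_size) * win_size
    wp = -(-W // win_size) * win_size
    nh, nw = hp // win_size, wp // win_size
    n = t.shape[0] // (nh * nw)
    t = t.reshape(n, nh, nw, win_size, win_size, C)
    t = t.transpose(0, 5, 1, 3, 2, 4)         # N, C, nh, ws, nw, ws
    t = t.reshape(n, C, hp, wp)
    if hp != H or wp != W:
        t = t.narrow(2, 0, H).narrow(3, 0, W)
    return t


@dataclass
class SwinStageConfig:
    """Hyper-parameters of the windowed-attention stage.

    ``depth`` must be even: blocks come in plain/shifted (W-MSA / SW-MSA)
    pairs.  ``embed_dim`` must be divisible by ``n_heads``.  For an H x W
    input, ``num_wins = H * W / win_size**2`` when the window tiles evenly
    (padding is applied otherwise).
    """

    depth: int = 2
    n_heads: int = 8
    win_size: int = 4
    embed_dim: int = 64
    H: int = field(default=32)
    W: int = field(default=32)

    def __post_init__(self):
        if self.depth <= 0 or self.depth % 2:
            raise ValueError("depth must be a positive even integer")
        if self.n_heads <= 0:
            raise ValueError("n_heads must be positive")
        if self.win_size <= 0:
            raise ValueError("win_size must be positive")
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads "
                f"{self.n_heads}")

    @property
    def num_wins(self) -> int:
        return num_windows(self.H, self.W, self.win_size)


class WindowAttentionBlock(nn.Module):
    """One pre-norm windowed MHSA block with relative position bias + MLP."""

    def __init__(self, dim: int, n_heads: int, win_size: int, shift: int,
                 mlp_ratio: int = 4):
        super().__init__()
        self.dim, self.n_heads, self.win_size = dim, n_heads, win_size
        self.shift = shift % win_size
        self.head_dim = dim // n_heads
        self.scale = self.head_dim ** -0.5
        self.norm1 = nn.LayerNorm(dim)
        self.qkv = nn.Linear(dim, 3 * dim, bias=True)
        self.proj = nn.Linear(dim, dim, bias=True)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, mlp_ratio * dim, bias=True)
        self.fc2 = nn.Linear(mlp_ratio * dim, dim, bias=True)
        tbl = (2 * win_size - 1) ** 2
        self.rel_bias = Parameter(
            np.zeros((tbl, n_heads), dtype=np.float32))
        self._rel_index = self._relative_index(win_size)

    @staticmethod
    def _relative_index(ws: int) -> np.ndarray:
        coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws),
                                      indexing="ij")).reshape(2, -1)
        rel = coords[:, :, None] - coords[:, None, :]
        rel = rel.transpose(1, 2, 0) + (ws - 1)
        return (rel[..., 0] * (2 * ws - 1) + rel[..., 1]).astype(np.int64)

    def _bias(self) -> Tensor:
        T = self.win_size ** 2
        flat = (self._rel_index.reshape(-1)[:, None] * self.n_heads
                + np.arange(self.n_heads)[None, :])
        b = F.take(self.rel_bias, flat.reshape(-1))
        return b.reshape(T, T, self.n_heads).transpose(2, 0, 1)

    @staticmethod
    def _shift_mask(Hp: int, Wp: int, ws: int, shift: int) -> np.ndarray:
        """Additive attention mask forbidding cross-region attention after
        a cyclic shift (the reference scheme)."""
        img = np.zeros((Hp, Wp), dtype=np.int64)
        cnt = 0
        for hs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
            for wsl in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
                img[hs, wsl] = cnt
                cnt += 1
        nh, nw = Hp // ws, Wp // ws
        wins = img.reshape(nh, ws, nw, ws).transpose(0, 2, 1, 3)
        wins = wins.reshape(nh * nw, ws * ws)
        diff = wins[:, :, None] != wins[:, None, :]
        return np.where(diff, np.float32(-100.0), np.float32(0.0))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        ws = self.win_size
        shift = self.shift
        x_sh = F.roll2d(x, (-shift, -shift)) if shift else x
        wins = window_partition(x_sh, ws)                 # (B, ws, ws, C)
        B = wins.shape[0]
        T = ws * ws
        tok = wins.reshape(B, T, c)
        res = tok
        tok = self.norm1(tok)
        qkv = self.qkv(tok).reshape(B, T, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)                # 3, B, heads, T, hd
        q = qkv.narrow(0, 0, 1).reshape(B, self.n_heads, T, self.head_dim)
        k = qkv.narrow(0, 1, 1).reshape(B, self.n_heads, T, self.head_dim)
        v = qkv.narrow(0, 2, 1).reshape(B, self.n_heads, T, self.head_dim)
        logits = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        logits = logits + self._bias().reshape(1, self.n_heads, T, T)
        if shift:
            hp = -(-h // ws) * ws
            wp = -(-w // ws) * ws
            mask = self._shift_mask(hp, wp, ws, shift)    # (nW, T, T)
            nW = mask.shape[0]
            logits = logits.reshape(B // nW, nW, self.n_heads, T, T)
            logits = logits + mask[None, :, None]
            logits = logits.reshape(B, self.n_heads, T, T)
        attn = F.softmax(logits, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, c)
        tok = res + self.proj(out)
        tok = tok + self.fc2(F.gelu(self.fc1(self.norm2(tok))))
        wins = tok.reshape(B, ws, ws, c)
        y = window_reverse(wins, ws, h, w, c)
        if shift:
            y = F.roll2d(y, (shift, shift))
        return y


class SwinStage(nn.Module):
    """Patch partition + linear embedding + stacked windowed attention.

    The patch size is 1 (a pure reshape), so the stage preserves H x W; the
    linear embedding is a 1x1 convolution + batch norm projecting the input
    onto ``cfg.embed_dim`` channels.  Blocks alternate plain and shifted
    windows (shift = win_size // 2), each carrying a per-head relative
    position bias table of (2 win_size - 1)^2 entries.
    """

    def __init__(self, c_in: int, cfg: SwinStageConfig):
        super().__init__()
        self.cfg = cfg
        self.embed = nn.Conv2d(c_in, cfg.embed_dim, 1, bias=False)
        self.embed_bn = nn.BatchNorm2d(cfg.embed_dim)
        blocks = []
        for i in range(cfg.depth):
            shift = 0 if i % 2 == 0 else cfg.win_size // 2
            blocks.append(WindowAttentionBlock(cfg.embed_dim, cfg.n_heads,
                                               cfg.win_size, shift))
        self.blocks = nn.ModuleList(blocks)

    def forward(self, x: Tensor) -> Tensor:
        y = self.embed_bn(self.embed(x))
        for blk in self.blocks:
            y = blk(y)
        return y
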