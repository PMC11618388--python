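"""Layer-level operations with hand-written backward rules.

Convolution is implemented as an explicit patch-gather (im2col) followed by
one BLAS matmul; the input gradient is accumulated tap-by-tap into a strided
view of the padded gradient, which keeps the backward pass vectorised.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "sigmoid", "silu", "relu", "tanh", "gelu", "atan", "bce_with_logits",
    "exp", "log", "sqrt", "softmax", "clamp_min",
    "concat", "conv2d", "batch_norm2d", "layer_norm", "maxpool2d",
    "avgpool2d", "upsample_nearest2x", "pad2d", "take", "roll2d", "linear",
    "reset_flop_counter", "enable_flop_counter", "flop_counter_value",
]

# multiply-accumulate counter for the profiling convention used by
# count_flops (convolutions and linear layers only)
_FLOPS = {"enabled": False, "macs": 0}


def reset_flop_counter():
    _FLOPS["macs"] = 0


def enable_flop_counter(on: bool):
    _FLOPS["enabled"] = bool(on)


def flop_counter_value() -> int:
    return _FLOPS["macs"]


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def _sigm(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def sigmoid(t: Tensor) -> Tensor:
    y = _sigm(t.data)

    def bw(g):
        t._accum(g * y * (1.0 - y))

    return Tensor._make(y, (t,), bw)


def silu(t: Tensor) -> Tensor:
    s = _sigm(t.data)
    y = t.data * s

    def bw(g):
        t._accum(g * (s * (1.0 + t.data * (1.0 - s))))

    return Tensor._make(y, (t,), bw)


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def bw(g):
        t._accum(g * mask)

    return Tensor._make(t.data * mask, (t,), bw)


def atan(t: Tensor) -> Tensor:
    def bw(g):
        t._accum(g / (1.0 + t.data * t.data))

    return Tensor._make(np.arctan(t.data), (t,), bw)


def bce_with_logits(x: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits against a constant target."""
    z = x.data
    # stable: max(z,0) - z*t + log(1 + exp(-|z|))
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def bw(g):
        s = _sigm(z)
        x._accum(g * (s - target) / n)

    return Tensor._make(np.float32(loss.mean()), (x,), bw)


def tanh(t: Tensor) -> Tensor:
    y = np.tanh(t.data)

    def bw(g):
        t._accum(g * (1.0 - y * y))

    return Tensor._make(y, (t,), bw)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(t: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    x = t.data
    inner = _GELU_C * (x + 0.044715 * x ** 3)
    th = np.tanh(inner)
    y = 0.5 * x * (1.0 + th)

    def bw(g):
        dth = (1.0 - th * th) * _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
        t._accum(g * (0.5 * (1.0 + th) + 0.5 * x * dth))

    return Tensor._make(y, (t,), bw)


def exp(t: Tensor) -> Tensor:
    y = np.exp(t.data)

    def bw(g):
        t._accum(g * y)

    return Tensor._make(y, (t,), bw)


def log(t: Tensor) -> Tensor:
    def bw(g):
        t._accum(g / t.data)

    return Tensor._make(np.log(t.data), (t,), bw)


def sqrt(t: Tensor) -> Tensor:
    y = np.sqrt(t.data)

    def bw(g):
        t._accum(g * 0.5 / np.maximum(y, 1e-12))

    return Tensor._make(y, (t,), bw)


def clamp_min(t: Tensor, lo: float) -> Tensor:
    mask = t.data > lo

    def bw(g):
        t._accum(g * mask)

    return Tensor._make(np.maximum(t.data, lo), (t,), bw)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        t._accum(y * (g - dot))

    return Tensor._make(y, (t,), bw)


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(start, start + s)
                t._accum(g[tuple(idx)])
            start += s

    return Tensor._make(out_data, tuple(tensors), bw)


def pad2d(t: Tensor, pads, value: float = 0.0) -> Tensor:
    """Pad the last two axes by (top, bottom, left, right)."""
    pt, pb, pl, pr = pads
    if pt == pb == pl == pr == 0:
        return t
    width = [(0, 0)] * (t.ndim - 2) + [(pt, pb), (pl, pr)]
    out_data = np.pad(t.data, width, constant_values=value)
    H, W = t.shape[-2], t.shape[-1]

    def bw(g):
        t._accum(g[..., pt:pt + H, pl:pl + W])

    return Tensor._make(out_data, (t,), bw)


def take(t: Tensor, flat_idx: np.ndarray) -> Tensor:
    """Gather from the flattened tensor; scatter-add on backward."""
    out_data = t.data.reshape(-1)[flat_idx]
    shape = t.shape

    def bw(g):
        full = np.zeros(t.size, dtype=g.dtype)
        np.add.at(full, flat_idx.reshape(-1), g.reshape(-1))
        t._accum(full.reshape(shape))

    return Tensor._make(out_data, (t,), bw)


def roll2d(t: Tensor, shifts) -> Tensor:
    sh, sw = shifts
    out_data = np.roll(t.data, (sh, sw), axis=(-2, -1))

    def bw(g):
        t._accum(np.roll(g, (-sh, -sw), axis=(-2, -1)))

    return Tensor._make(out_data, (t,), bw)


def linear(x: Tensor, w: Tensor, b=None) -> Tensor:
    """x @ w.T + b with w of shape (out, in)."""
    if _FLOPS["enabled"]:
        batch = 1
        for s in x.shape[:-1]:
            batch *= s
        _FLOPS["macs"] += batch * w.shape[0] * w.shape[1]
    y = x @ w.transpose(1, 0)
    if b is not None:
        y = y + b
    return y


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

_IDX_CACHE: dict = {}


def _conv_indices(H, W, kh, kw, sh, sw, dh, dw):
    key = (H, W, kh, kw, sh, sw, dh, dw)
    got = _IDX_CACHE.get(key)
    if got is None:
        Ho = (H - (kh - 1) * dh - 1) // sh + 1
        Wo = (W - (kw - 1) * dw - 1) // sw + 1
        i = (sh * np.arange(Ho))[:, None, None, None] + (dh * np.arange(kh))[None, None, :, None]
        j = (sw * np.arange(Wo))[None, :, None, None] + (dw * np.arange(kw))[None, None, None, :]
        i = np.broadcast_to(i, (Ho, Wo, kh, kw))
        j = np.broadcast_to(j, (Ho, Wo, kh, kw))
        got = (Ho, Wo, np.ascontiguousarray(i), np.ascontiguousarray(j))
        _IDX_CACHE[key] = got
    return got


def conv2d(x: Tensor, w: Tensor, b=None, stride=1, padding=0, dilation=1) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (Cout, Cin, kh, kw)."""
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    dh, dw = (dilation, dilation) if isinstance(dilation, int) else dilation
    N, C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    assert Cin == C, f"conv2d channel mismatch: {Cin} vs {C}"

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho, Wo, I, J = _conv_indices(Hp, Wp, kh, kw, sh, sw, dh, dw)
    if _FLOPS["enabled"]:
        _FLOPS["macs"] += N * Cout * Ho * Wo * Cin * kh * kw

    if kh == kw == 1 and sh == sw == 1:
        # fast path: 1x1 conv is a matmul over pixels
        cols = xp.reshape(N, C, Hp * Wp)
        y = np.matmul(w.data.reshape(Cout, C), cols).reshape(N, Cout, Ho, Wo)
        patches = None
    else:
        patches = xp[:, :, I, J]                     # (N, C, Ho, Wo, kh, kw)
        cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
        y = (cols @ w.data.reshape(Cout, -1).T).reshape(N, Ho, Wo, Cout)
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
    if b is not None:
        y = y + b.data.reshape(1, Cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        # g: (N, Cout, Ho, Wo)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gmat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Cout)
        if w.requires_grad:
            if patches is None:
                cols_t = xp.reshape(N, C, Hp * Wp).transpose(0, 2, 1).reshape(-1, C)
                gw = gmat.T @ cols_t
                w._accum(gw.reshape(w.shape))
            else:
                cols_l = patches.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
                gw = gmat.T @ cols_l
                w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gx_p = np.zeros((N, C, Hp, Wp), dtype=g.dtype)
            if kh == kw == 1 and sh == sw == 1:
                gx_p += np.matmul(w.data.reshape(Cout, C).T,
                                  g.reshape(N, Cout, Ho * Wo)).reshape(N, C, Hp, Wp)
            else:
                # accumulate one kernel tap at a time through strided views
                for a in range(kh):
                    for bb in range(kw):
                        contrib = np.einsum("nohw,oc->nchw", g, w.data[:, :, a, bb],
                                            optimize=True)
                        gx_p[:, :,
                             a * dh:a * dh + sh * Ho:sh,
                             bb * dw:bb * dw + sw * Wo:sw] += contrib
            if ph or pw:
                gx_p = gx_p[:, :, ph:ph + H, pw:pw + W]
            x._accum(gx_p)

    return Tensor._make(y, parents, bw)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                 running_var, training: bool, momentum: float = 0.03,
                 eps: float = 1e-3) -> Tensor:
    N, C, H, W = x.shape
    m = N * H * W
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
    y = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def bw(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data.reshape(1, C, 1, 1) * inv.reshape(1, C, 1, 1)
            if training:
                gm = g.mean(axis=(0, 2, 3), keepdims=True)
                gxh = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accum(gi * (g - gm - xhat * gxh))
            else:
                x._accum(gi * g)

    return Tensor._make(y, (x, gamma, beta), bw)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = xhat * weight.data + bias.data
    D = x.shape[-1]

    def bw(g):
        red = tuple(range(g.ndim - 1))
        if bias.requires_grad:
            bias._accum(g.sum(axis=red))
        if weight.requires_grad:
            weight._accum((g * xhat).sum(axis=red))
        if x.requires_grad:
            gh = g * weight.data
            gm = gh.mean(axis=-1, keepdims=True)
            gxh = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (gh - gm - xhat * gxh))

    return Tensor._make(y, (x, weight, bias), bw)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def maxpool2d(x: Tensor, k: int, stride: int = None, padding: int = 0) -> Tensor:
    s = stride or k
    N, C, H, W = x.shape
    xp = (np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                 constant_values=-np.inf) if padding else x.data)
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho, Wo, I, J = _conv_indices(Hp, Wp, k, k, s, s, 1, 1)
    win = xp[:, :, I, J].reshape(N, C, Ho, Wo, k * k)
    arg = win.argmax(axis=-1)
    y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gx_p = np.zeros((N, C, Hp, Wp), dtype=g.dtype)
        ai, aj = np.unravel_index(arg, (k, k))
        rows = (I[..., 0, 0][None, None] + ai)
        cols = (J[..., 0, 0][None, None] + aj)
        n_idx = np.arange(N)[:, None, None, None]
        c_idx = np.arange(C)[None, :, None, None]
        np.add.at(gx_p, (n_idx, c_idx, rows, cols), g)
        if padding:
            gx_p = gx_p[:, :, padding:padding + H, padding:padding + W]
        x._accum(gx_p)

    return Tensor._make(np.ascontiguousarray(y), (x,), bw)


def avgpool2d(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    N, C, H, W = x.shape
    xp = (np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
          if padding else x.data)
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho, Wo, I, J = _conv_indices(Hp, Wp, k, k, stride, stride, 1, 1)
    y = xp[:, :, I, J].mean(axis=(-1, -2))

    def bw(g):
        gx_p = np.zeros((N, C, Hp, Wp), dtype=g.dtype)
        gk = np.broadcast_to((g / (k * k))[..., None, None], g.shape + (k, k))
        n_idx = np.arange(N)[:, None, None, None, None, None]
        c_idx = np.arange(C)[None, :, None, None, None, None]
        np.add.at(gx_p, (n_idx, c_idx, I[None, None], J[None, None]), gk)
        if padding:
            gx_p = gx_p[:, :, padding:padding + H, padding:padding + W]
        x._accum(gx_p)

    return Tensor._make(np.ascontiguousarray(y), (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        N, C, H2, W2 = g.shape
        x._accum(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(y, (x,), bw)
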