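"""Differentiable array operations (NCHW layout) used by the models.

Convolutions are stride-1 with "same" zero padding for 3x3 kernels and no
padding for 1x1 kernels; downsampling is a separate 2x2 max-pool.  Gradients
of every operation here are checked against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .autograd import Tensor, needs_grad

__all__ = [
    "conv2d",
    "relu",
    "sigmoid",
    "maxpool2x2",
    "upsample_nearest2d",
    "upsample_bilinear2d",
    "concat_channels",
    "add",
    "batchnorm2d",
    "soft_dice_loss",
    "bce_loss",
]


# ---------------------------------------------------------------------------
# convolution


def _windows(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Sliding kxk windows of an NCHW array -> (N, C, H, W, k, k) view."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))


def _conv_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    k = w.shape[-1]
    if k == 1:
        # 1x1 convolution is a channel-mixing matmul; skip im2col entirely.
        n, c, h, wd = x.shape
        y = np.tensordot(w[:, :, 0, 0], x, axes=([1], [1]))  # O,N,H,W
        return np.ascontiguousarray(y.transpose(1, 0, 2, 3))
    win = _windows(x, k, pad)
    y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # N,H,W,O
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2))


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor], pad: int) -> Tensor:
    """2-D cross-correlation, stride 1.  weight: (O, C, k, k)."""
    k = weight.data.shape[-1]
    y = _conv_raw(x.data, weight.data, pad)
    if bias is not None:
        y += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    if not needs_grad(parents):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        if bias is not None:
            bias.accumulate(gy.sum(axis=(0, 2, 3)))
        if k == 1:
            gw = np.tensordot(gy, x.data, axes=([0, 2, 3], [0, 2, 3]))
            weight.accumulate(gw[:, :, None, None])
            gx = np.tensordot(weight.data[:, :, 0, 0].T, gy, axes=([1], [1]))
            x.accumulate(np.ascontiguousarray(gx.transpose(1, 0, 2, 3)))
        else:
            win = _windows(x.data, k, pad)
            gw = np.tensordot(gy, win, axes=([0, 2, 3], [0, 2, 3]))
            weight.accumulate(gw)
            # input gradient: full correlation with the flipped, transposed kernel
            w_rot = np.ascontiguousarray(
                weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            )
            x.accumulate(_conv_raw(gy, w_rot, k - 1 - pad))

    return Tensor(y, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# activations


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    if not needs_grad((x,)):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        x.accumulate(gy * (x.data > 0))

    return Tensor(y, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    d = x.data
    y = np.where(d >= 0, 1.0 / (1.0 + np.exp(-d)), np.exp(d) / (1.0 + np.exp(d)))
    y = y.astype(np.float32)
    if not needs_grad((x,)):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        x.accumulate(gy * y * (1.0 - y))

    return Tensor(y, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# resampling


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    xr = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    if not needs_grad((x,)):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        g = np.zeros_like(xr)
        np.put_along_axis(g, idx[..., None], gy[..., None], axis=-1)
        gx = (
            g.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x.accumulate(gx)

    return Tensor(y, parents=(x,), backward=backward)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    y = x.data.repeat(scale, axis=2).repeat(scale, axis=3)
    if not needs_grad((x,)):
        return Tensor(y)
    n, c, h, w = x.data.shape

    def backward(gy: np.ndarray) -> None:
        gx = gy.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
        x.accumulate(gx)

    return Tensor(y, parents=(x,), backward=backward)


def _linear_resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense (n_out, n_in) bilinear interpolation matrix, half-pixel centers."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def upsample_bilinear2d(x: Tensor, size: Tuple[int, int]) -> Tensor:
    """Bilinear resize to ``size`` (align_corners=False convention)."""
    n, c, h, w = x.data.shape
    ho, wo = size
    rm = _linear_resize_matrix(ho, h)
    cm = _linear_resize_matrix(wo, w)
    y = np.matmul(np.matmul(rm, x.data), cm.T)
    if not needs_grad((x,)):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        x.accumulate(np.matmul(np.matmul(rm.T, gy), cm))

    return Tensor(y, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# structural ops


def concat_channels(xs: Sequence[Tensor]) -> Tensor:
    y = np.concatenate([t.data for t in xs], axis=1)
    parents = tuple(xs)
    if not needs_grad(parents):
        return Tensor(y)
    sizes = [t.data.shape[1] for t in xs]
    edges = np.cumsum([0] + sizes)

    def backward(gy: np.ndarray) -> None:
        for t, a, b in zip(xs, edges[:-1], edges[1:]):
            t.accumulate(gy[:, a:b])

    return Tensor(y, parents=parents, backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data
    if not needs_grad((a, b)):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        a.accumulate(gy)
        b.accumulate(gy)

    return Tensor(y, parents=(a, b), backward=backward)


# ---------------------------------------------------------------------------
# batch normalisation


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    parents = (x, gamma, beta)
    if not needs_grad(parents):
        return Tensor(y)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(gy: np.ndarray) -> None:
        gamma.accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        beta.accumulate(gy.sum(axis=(0, 2, 3)))
        gb = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if training:
            s1 = gy.sum(axis=(0, 2, 3))[None, :, None, None]
            s2 = (gy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            x.accumulate(gb / m * (m * gy - s1 - xhat * s2))
        else:
            x.accumulate(gb * gy)

    return Tensor(y, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# losses


def soft_dice_loss(
    pred: Tensor,
    target: np.ndarray,
    xi: float = 100.0,
    per_image: bool = False,
) -> Tensor:
    """Smoothed soft Dice loss 1 - (2|A.B| + xi) / (|A| + |B| + xi).

    ``pred`` holds probabilities in [0, 1]; ``target`` is a binary array of
    the same shape.  The intersection is the sum of elementwise products and
    |A| the sum of predicted probabilities (the continuous relaxation of the
    set formulation).  With ``per_image`` the loss is averaged over per-image
    Dice terms instead of pooling every pixel of the batch into one term.
    """
    if xi < 0:
        raise ValueError(f"smoothing parameter must be >= 0, got {xi}")
    g = np.asarray(target, dtype=np.float32)
    if g.shape != pred.data.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {g.shape}")
    p = pred.data
    if per_image:
        axes = tuple(range(1, p.ndim))
        inter = (p * g).sum(axis=axes)
        num = 2.0 * inter + xi
        den = p.sum(axis=axes) + g.sum(axis=axes) + xi
        loss = float(np.mean(1.0 - num / den))
        nb = p.shape[0]

        def backward(gy: np.ndarray) -> None:
            shape = (nb,) + (1,) * (p.ndim - 1)
            gp = (num.reshape(shape) / den.reshape(shape) ** 2) - 2.0 * g / den.reshape(shape)
            pred.accumulate(float(gy) * gp / nb)

    else:
        inter = float((p * g).sum())
        num = 2.0 * inter + xi
        den = float(p.sum()) + float(g.sum()) + xi
        loss = 1.0 - num / den

        def backward(gy: np.ndarray) -> None:
            pred.accumulate(float(gy) * (num / den**2 - 2.0 * g / den))

    if not needs_grad((pred,)):
        return Tensor(loss)
    return Tensor(loss, parents=(pred,), backward=backward)


def bce_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy on probabilities (optional compound loss)."""
    g = np.asarray(target, dtype=np.float32)
    p = np.clip(pred.data, eps, 1.0 - eps)
    loss = float(-(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).mean())
    if not needs_grad((pred,)):
        return Tensor(loss)

    def backward(gy: np.ndarray) -> None:
        gp = (p - g) / (p * (1.0 - p)) / p.size
        pred.accumulate(float(gy) * gp)

    return Tensor(loss, parents=(pred,), backward=backward)
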