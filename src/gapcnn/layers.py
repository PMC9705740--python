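"""From-scratch differentiable layer primitives.

All image tensors use a ``(N, H, W, C)`` layout (batch, height, width,
channels), 0-based indexing, float64 arithmetic.  Every ``*_forward``
returns ``(output, cache)`` and the matching ``*_backward`` consumes the
upstream gradient plus that cache and returns exact analytic gradients of a
scalar loss; the analytic backward of each layer is validated against
central finite differences in the test-suite.

Convolution is cross-correlation (no kernel flip), implemented via an
im2col lowering so the inner loop is a single BLAS matmul.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv_forward",
    "conv_backward",
    "maxpool_forward",
    "maxpool_backward",
    "lrn_forward",
    "lrn_backward",
    "dense_forward",
    "dense_backward",
    "gap_forward",
    "gap_backward",
    "dropout_apply",
    "softmax_xent",
    "pad_amounts",
]


def _as_tensor4(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 4:
        raise ValueError(f"{name} must be 4-D (N,H,W,C), got shape {x.shape}")
    return x


def pad_amounts(size: int, k: int, stride: int, padding) -> tuple[int, int]:
    """(before, after) padding along one spatial axis.

    ``padding`` is ``"same"`` (output ceil(size/stride)), ``"valid"`` or an
    explicit non-negative int applied symmetrically.
    """
    if padding == "same":
        out = -(-size // stride)  # ceil
        total = max((out - 1) * stride + k - size, 0)
        before = total // 2
        return before, total - before
    if padding == "valid":
        return 0, 0
    p = int(padding)
    if p < 0:
        raise ValueError(f"explicit padding must be >= 0, got {p}")
    return p, p


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # xp: padded (N, Hp, Wp, C) -> (N, Ho, Wo, kh*kw*C)
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N, Ho', Wo', C, kh, kw)
    win = win[:, ::stride, ::stride]
    win = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))  # (..., kh, kw, C)
    n, ho, wo = win.shape[:3]
    return win.reshape(n, ho, wo, kh * kw * xp.shape[3])


def conv_forward(x, weights, bias, stride: int = 1, padding="same"):
    """2-D cross-correlation.

    ``weights`` has shape ``(kh, kw, C_in, C_out)``, ``bias`` shape
    ``(C_out,)``.  Returns ``(out, cache)`` with ``out`` of shape
    ``(N, Ho, Wo, C_out)``.
    """
    x = _as_tensor4(x)
    w = np.asarray(weights, dtype=float)
    b = np.asarray(bias, dtype=float)
    if w.ndim != 4:
        raise ValueError(f"weights must be 4-D (kh,kw,Cin,Cout), got {w.shape}")
    kh, kw, cin, cout = w.shape
    if x.shape[3] != cin:
        raise ValueError(
            f"channel mismatch: input shape {x.shape} vs weights shape {w.shape}"
        )
    ph = pad_amounts(x.shape[1], kh, stride, padding)
    pw = pad_amounts(x.shape[2], kw, stride, padding)
    xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
    if xp.shape[1] < kh or xp.shape[2] < kw:
        raise ValueError(
            f"kernel ({kh},{kw}) larger than padded input {xp.shape[1:3]}"
        )
    cols = _im2col(xp, kh, kw, stride)
    out = cols @ w.reshape(kh * kw * cin, cout) + b
    cache = (cols, w, x.shape, (ph, pw), stride)
    return out, cache


def conv_backward(dout, cache):
    """Gradients of conv_forward: returns ``(dx, dw, db)``."""
    cols, w, x_shape, (ph, pw), stride = cache
    kh, kw, cin, cout = w.shape
    dout = np.asarray(dout, dtype=float)
    n, ho, wo = dout.shape[:3]
    db = dout.sum(axis=(0, 1, 2))
    dw = np.tensordot(cols, dout, axes=([0, 1, 2], [0, 1, 2])).reshape(w.shape)
    dcols = (dout @ w.reshape(kh * kw * cin, cout).T).reshape(n, ho, wo, kh, kw, cin)
    hp = x_shape[1] + ph[0] + ph[1]
    wp = x_shape[2] + pw[0] + pw[1]
    dxp = np.zeros((n, hp, wp, cin))
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + stride * ho : stride, j : j + stride * wo : stride, :] += dcols[
                :, :, :, i, j, :
            ]
    dx = dxp[:, ph[0] : hp - ph[1], pw[0] : wp - pw[1], :]
    return dx, dw, db


def maxpool_forward(x, k: int, stride: int, padding="same"):
    """Window maximum over ``k x k`` windows; ties go to the first
    (row-major) position.  Padded positions hold ``-inf`` and never win."""
    x = _as_tensor4(x)
    ph = pad_amounts(x.shape[1], k, stride, padding)
    pw = pad_amounts(x.shape[2], k, stride, padding)
    xp = np.pad(x, ((0, 0), ph, pw, (0, 0)), constant_values=-np.inf)
    if xp.shape[1] < k or xp.shape[2] < k:
        raise ValueError(f"pool window {k} larger than padded input {xp.shape[1:3]}")
    win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    # (N, Ho, Wo, C, k, k) -> flatten window
    n, ho, wo, c = win.shape[:4]
    flat = win.reshape(n, ho, wo, c, k * k)
    arg = flat.argmax(axis=-1)  # first max in row-major window order
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    cache = (arg, x.shape, (ph, pw), k, stride)
    return out, cache


def maxpool_backward(dout, cache):
    arg, x_shape, (ph, pw), k, stride = cache
    dout = np.asarray(dout, dtype=float)
    n, ho, wo, c = dout.shape
    hp = x_shape[1] + ph[0] + ph[1]
    wp = x_shape[2] + pw[0] + pw[1]
    dxp = np.zeros((n, hp, wp, c))
    ni, hoi, woi, ci = np.indices((n, ho, wo, c), sparse=False)
    rows = hoi * stride + arg // k
    cols = woi * stride + arg % k
    np.add.at(dxp, (ni, rows, cols, ci), dout)
    return dxp[:, ph[0] : hp - ph[1], pw[0] : wp - pw[1], :]


def _channel_window_sum(t: np.ndarray, radius: int) -> np.ndarray:
    # sum over channels c-radius .. c+radius, zero outside
    c = t.shape[-1]
    out = t.copy()
    for d in range(1, radius + 1):
        out[..., d:] += t[..., : c - d]
        out[..., : c - d] += t[..., d:]
    return out


def lrn_forward(x, depth_radius: int = 2, k0: float = 2.0, a: float = 1e-4, b: float = 0.75):
    """Local response normalization across channels.

    ``y_c = x_c / (k0 + a * sum_{|j-c|<=r} x_j^2)^b`` — brightness-style
    cross-channel competition.
    """
    x = _as_tensor4(x)
    if k0 <= 0:
        raise ValueError(f"k0 must be positive, got {k0}")
    ssq = _channel_window_sum(x * x, depth_radius)
    denom = k0 + a * ssq
    out = x * denom ** (-b)
    return out, (x, denom, depth_radius, a, b)


def lrn_backward(dout, cache):
    x, denom, radius, a, b = cache
    dout = np.asarray(dout, dtype=float)
    t = dout * x * denom ** (-b - 1.0)
    return dout * denom ** (-b) - 2.0 * a * b * x * _channel_window_sum(t, radius)


def dense_forward(x, weights, bias):
    """Affine layer ``x @ W + b``.  4-D inputs are flattened per sample."""
    x = np.asarray(x, dtype=float)
    orig_shape = x.shape
    if x.ndim > 2:
        x = x.reshape(x.shape[0], -1)
    w = np.asarray(weights, dtype=float)
    b = np.asarray(bias, dtype=float)
    if x.shape[1] != w.shape[0]:
        raise ValueError(f"shape mismatch: input {orig_shape} vs weights {w.shape}")
    return x @ w + b, (x, w, orig_shape)


def dense_backward(dout, cache):
    x, w, orig_shape = cache
    dout = np.asarray(dout, dtype=float)
    dw = x.T @ dout
    db = dout.sum(axis=0)
    dx = (dout @ w.T).reshape(orig_shape)
    return dx, dw, db


def gap_forward(x):
    """Global average pooling: ``(N,H,W,C) -> (N,C)`` channel means."""
    x = _as_tensor4(x)
    return x.mean(axis=(1, 2)), x.shape


def gap_backward(dout, x_shape):
    n, h, w, c = x_shape
    dout = np.asarray(dout, dtype=float)
    return np.broadcast_to(dout[:, None, None, :] / (h * w), x_shape).copy()


def dropout_apply(x, rate: float, train_flag: bool, rng_seed=0):
    """Inverted dropout.

    Training: zero each element with probability ``rate`` and scale
    survivors by ``1/(1-rate)`` so expectations match inference, where the
    layer is the identity.  ``rng_seed`` may be an int seed or a
    ``numpy.random.Generator``.  Returns ``(output, mask)`` with the mask
    already including the ``1/(1-rate)`` scale.
    """
    x = np.asarray(x, dtype=float)
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if not train_flag or rate == 0.0:
        return x, np.ones_like(x)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


def softmax_xent(logits, labels):
    """Softmax cross-entropy head.

    Returns ``(mean_loss, probs, dlogits)`` where ``dlogits`` is the
    gradient of the mean loss, ``(probs - onehot) / N``.  Probability rows
    sum to 1 to machine precision.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels)
    if logits.ndim != 2:
        raise ValueError(f"logits must be 2-D (N, classes), got {logits.shape}")
    n, k = logits.shape
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} != ({n},)")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(
            f"labels must lie in [0, {k}), got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    log_probs = z - np.log(ez.sum(axis=1, keepdims=True))
    loss = -log_probs[np.arange(n), labels].mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, probs, dlogits
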