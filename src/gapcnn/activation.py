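"""Normalized Non-linear activation Unit (NNLU) and baseline activations.

The NNLU is a Gaussian-density-shaped activation

    mu_a(x) = exp(-x^2 / (4 a)) / (2 sqrt(a pi)),   a > 0,

i.e. a normal density with variance ``2 a``.  The scale ``a`` (written
``alpha`` throughout) controls both the peak height ``1 / (2 sqrt(a pi))``
and the width of the bump.  The function is strictly positive, even, and
integrates to one; its first derivative is odd and its second derivative
changes sign at ``x = +-sqrt(2 a)``.

Backpropagation uses only :func:`nnlu_grad`; :func:`nnlu_hess` is exposed as
a diagnostic (curvature / inflection analysis).  ReLU and the logistic
sigmoid are provided as comparison baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NNLUParams",
    "nnlu_value",
    "nnlu_grad",
    "nnlu_hess",
    "activation_family",
    "relu",
    "relu_grad",
    "sigmoid",
    "sigmoid_grad",
    "get_activation",
]


@dataclass(frozen=True)
class NNLUParams:
    """Parameters of the NNLU activation.

    Parameters
    ----------
    alpha : float
        Positive dimensionless activation scale. Default 0.333.
    """

    alpha: float = 0.333

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha!r}")


def _check_finite(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x))
        raise ValueError(f"non-finite input at index {tuple(int(i) for i in bad[0])}")
    return x


def nnlu_value(x: np.ndarray, params: NNLUParams = NNLUParams()) -> np.ndarray:
    """Elementwise NNLU value ``exp(-x^2/(4 a)) / (2 sqrt(a pi))``.

    Strictly positive for finite ``x``; maximum ``1/(2 sqrt(a pi))`` at 0.
    Large ``|x|`` underflows gracefully to 0.0 (never NaN/Inf).
    """
    x = _check_finite(x)
    a = params.alpha
    return np.exp(-(x * x) / (4.0 * a)) / (2.0 * np.sqrt(a * np.pi))


def nnlu_grad(x: np.ndarray, params: NNLUParams = NNLUParams()) -> np.ndarray:
    """First derivative ``-x exp(-x^2/(4a)) / (4 a sqrt(a pi))`` (odd)."""
    x = _check_finite(x)
    a = params.alpha
    return -x / (4.0 * a * np.sqrt(a * np.pi)) * np.exp(-(x * x) / (4.0 * a))


def nnlu_hess(x: np.ndarray, params: NNLUParams = NNLUParams()) -> np.ndarray:
    """Analytic second derivative ``(x^2 - 2a) exp(-x^2/(4a)) / (8 a^2 sqrt(a pi))``.

    Even; negative at the origin (interior maximum) and zero at
    ``x = +-sqrt(2 a)``.
    """
    x = _check_finite(x)
    a = params.alpha
    return (x * x - 2.0 * a) / (8.0 * a * a * np.sqrt(a * np.pi)) * np.exp(
        -(x * x) / (4.0 * a)
    )


def activation_family(alphas: list[float], grid: np.ndarray) -> pd.DataFrame:
    """Tabulate the NNLU family over a grid for each scale.

    Returns a long-format DataFrame with columns
    ``alpha, x, value, grad, hess`` — one row per (alpha, grid point),
    suitable for plotting the family of bumps for different scales.
    """
    alphas = list(alphas)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if len(alphas) == 0:
        raise ValueError("alphas must be non-empty")
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    rows = []
    for a in alphas:
        p = NNLUParams(alpha=float(a))
        rows.append(
            pd.DataFrame(
                {
                    "alpha": float(a),
                    "x": grid,
                    "value": nnlu_value(grid, p),
                    "grad": nnlu_grad(grid, p),
                    "hess": nnlu_hess(grid, p),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    # subgradient 0 at the kink
    return (np.asarray(x, dtype=float) > 0).astype(float)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # split by sign for overflow safety
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid_grad(x: np.ndarray) -> np.ndarray:
    s = sigmoid(x)
    return s * (1.0 - s)


def get_activation(name: str, alpha: float = 0.333):
    """Return ``(value_fn, grad_fn)`` for an activation by name.

    ``name`` is one of ``{"nnlu", "relu", "sigmoid"}``; ``alpha`` only
    applies to nnlu.
    """
    if name == "nnlu":
        p = NNLUParams(alpha=alpha)
        return (lambda x: nnlu_value(x, p)), (lambda x: nnlu_grad(x, p))
    if name == "relu":
        return relu, relu_grad
    if name == "sigmoid":
        return sigmoid, sigmoid_grad
    raise ValueError(f"unknown activation {name!r}")
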