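"""Parameter-update rules: SGD, Adam, AMSGrad.

All three operate on :class:`~gapcnn.network.ParamSet` /
:class:`~gapcnn.network.GradientSet` pairs.  Adam keeps bias-corrected
first/second moment estimates; AMSGrad additionally clamps the second
moment to its running maximum, making the effective step size
non-increasing in the presence of oscillating gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import GradientSet, ParamSet

__all__ = ["OptimizerState", "make_optimizer", "step"]

_RULES = ("sgd", "adam", "amsgrad")


@dataclass
class OptimizerState:
    rule: str = "adam"
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    vhat: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}, got {self.rule!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1, beta2 must lie in [0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    def copy(self) -> "OptimizerState":
        return OptimizerState(
            rule=self.rule,
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            eps=self.eps,
            t=self.t,
            m={k: v.copy() for k, v in self.m.items()},
            v={k: v.copy() for k, v in self.v.items()},
            vhat={k: v.copy() for k, v in self.vhat.items()},
        )


def make_optimizer(rule: str = "adam", learning_rate: float = 1e-3, **kw) -> OptimizerState:
    return OptimizerState(rule=rule, learning_rate=learning_rate, **kw)


def step(state: OptimizerState, params: ParamSet, grads: GradientSet) -> ParamSet:
    """One in-place-free update; returns new parameters, mutates ``state``.

    sgd:      w <- w - lr * g
    adam:     w <- w - lr * m_hat / (sqrt(v_hat) + eps)
    amsgrad:  adam with v_hat <- max(v_hat_prev, v_hat)  (elementwise)
    """
    params.check_congruent(grads)
    state.t += 1
    out = ParamSet()
    if state.rule == "sgd":
        for k in params:
            out[k] = params[k] - state.learning_rate * grads[k]
        return out
    b1, b2 = state.beta1, state.beta2
    bc1 = 1.0 - b1 ** state.t
    bc2 = 1.0 - b2 ** state.t
    for k in params:
        g = grads[k]
        m = state.m.get(k, np.zeros_like(g))
        v = state.v.get(k, np.zeros_like(g))
        m = b1 * m + (1.0 - b1) * g
        v = b2 * v + (1.0 - b2) * g * g
        state.m[k], state.v[k] = m, v
        mhat = m / bc1
        vhat = v / bc2
        if state.rule == "amsgrad":
            vprev = state.vhat.get(k, np.zeros_like(g))
            vhat = np.maximum(vprev, vhat)
            state.vhat[k] = vhat
        out[k] = params[k] - state.learning_rate * mhat / (np.sqrt(vhat) + state.eps)
    return out
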