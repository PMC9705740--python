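"""Analytic computation/communication cost model for parameter-server
training.

The model prices one training round of ``k`` workers synchronising ``P``
parameters through ``N`` processors / parameter servers over a binary
reduction tree.  Big-O expressions are evaluated as concrete formulas with
unit constants and base-2 logarithms, so outputs are *model units*, not
seconds:

* rounds:            ``ceil(log2 k)``
* computation time:  ``P/N + ceil(log2 k) + P * log2(1/eps)``
  (aggregation over N processors, plus the SGD iteration count to reach
  target error ``eps``)
* communication cost (truncated geometric sums over the tree rounds):
  ``L * sum_{i=1..r} k/2^i  +  (k P / B) * sum_{i=1..r} 1/2^i``
* multi-server totals: cost ``N k + P k``, time ``k / N``.

``comparison_report`` evaluates the same quantities for a baseline
all-to-all scheme whose computation time carries an extra ``log2 k``
factor on the SGD term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CostParams",
    "communication_rounds",
    "computation_time",
    "communication_cost",
    "communication_time_total",
    "comparison_report",
]


@dataclass(frozen=True)
class CostParams:
    """P parameters, k workers, N processors/servers, target error eps,
    per-round latency L (time units), bandwidth B (parameters per time
    unit), dataset size D."""

    P: float
    k: int = 1
    N: int = 1
    eps: float = 0.01
    L: float = 1.0
    B: float = 1.0
    D: float = 1.0

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError("P must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0.0 < self.eps < 1.0):
            raise ValueError("eps must lie in (0, 1)")
        if self.L <= 0 or self.B <= 0 or self.D <= 0:
            raise ValueError("L, B, D must be > 0")


def communication_rounds(k: int) -> int:
    """Depth of a binary reduction tree over ``k`` leaves: ``ceil(log2 k)``."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return math.ceil(math.log2(k)) if k > 1 else 0


def computation_time(p: CostParams) -> float:
    """``P/N + ceil(log2 k) + P log2(1/eps)`` (aggregation + SGD terms)."""
    return p.P / p.N + communication_rounds(p.k) + p.P * math.log2(1.0 / p.eps)


def communication_cost(p: CostParams):
    """Exact truncated-geometric communication cost of the reduction tree.

    Returns ``(exact, big_o_terms)`` where ``big_o_terms = (L*k, k*P/B)``
    are the asymptotic envelopes the exact sum approaches from below.
    """
    r = communication_rounds(p.k)
    latency_sum = sum(p.k / 2**i for i in range(1, r + 1))
    transfer_sum = sum(1.0 / 2**i for i in range(1, r + 1))
    exact = p.L * latency_sum + (p.k * p.P / p.B) * transfer_sum
    return exact, (p.L * p.k, p.k * p.P / p.B)


def communication_time_total(p: CostParams):
    """Multi-server totals: returns ``(servers_cost, time)`` with
    ``servers_cost = N*k + P*k`` and ``time = k/N``."""
    return (p.N * p.k + p.P * p.k, p.k / p.N)


def comparison_report(p: CostParams) -> pd.DataFrame:
    """Three-row table comparing this scheme with a baseline all-to-all
    parameter exchange, all entries evaluated as concrete unit-constant
    formulas.

    Baseline formulas: computation ``P log2(k) log2(1/eps) + P log2(1/eps)``,
    communication cost ``P k log2(1/eps)``, communication time
    ``P log2(1/eps) / log2(k)`` (undefined at k = 1, reported as NaN with a
    note).
    """
    log_eps = math.log2(1.0 / p.eps)
    proposed_comp = computation_time(p)
    servers_cost, time = communication_time_total(p)
    existing_comp = p.P * math.log2(max(p.k, 1)) * log_eps + p.P * log_eps
    existing_cost = p.P * p.k * log_eps
    if p.k == 1:
        existing_time = math.nan
        note = "baseline communication time undefined at k=1 (division by log2 1)"
    else:
        existing_time = p.P * log_eps / math.log2(p.k)
        note = ""
    df = pd.DataFrame(
        {
            "quantity": ["Computation time", "Communication cost", "Communication time"],
            "proposed": [proposed_comp, servers_cost, time],
            "existing": [existing_comp, existing_cost, existing_time],
            "note": ["", "", note],
        }
    )
    df.attrs["params"] = p
    # N=D/K appears only as a derived footnote, never in the formulas
    df.attrs["footnote"] = (
        f"model units (unit big-O constants, base-2 logs); derived N_eff = D/k = {p.D / p.k:g}"
    )
    return df
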