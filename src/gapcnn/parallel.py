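"""Simulated hybrid data/model parallelism with exact serial equivalence.

Data parallelism replicates the network, shards the batch across ``k``
virtual workers, and combines per-shard gradients with weights
``m_i / n`` (shard size over batch size).  Because the loss is a mean over
samples, this weighted combination equals the full-batch gradient
*identically*:

    dLoss/dw = (1/n) sum_i dg_i/dw = sum_k (m_k/n) * dp_k/dw

reducing to the plain ``(1/k)``-average when all shards are equal.

Model parallelism partitions a dense layer's *output units* into ``k``
contiguous column blocks; each worker computes its block matmul and the
blocks are concatenated, which is algebraically the unpartitioned product.

Hybrid parallelism applies data parallelism to the conv/pool/GAP stages
(micro-batches of ``m`` samples), gathers the resulting activations, and
runs the dense stages model-parallel on fc batches of ``n_fc`` samples.

Workers are simulated by a sequential loop — the contracts here are about
the *algebra* of partitioned training, not wall-clock speed; every step
function is required (and tested) to match serial execution to floating-
point accumulation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import layers as L
from .network import (
    GradientSet,
    NetworkSpec,
    ParamSet,
    backward,
    first_dense_index,
    forward,
    run_layers,
    run_layers_backward,
    weighted_combination,
)
from .optim import OptimizerState, step as opt_step

__all__ = [
    "ShardPlan",
    "FcPartition",
    "HybridConfig",
    "make_shard_plan",
    "aggregate_gradients",
    "serial_step",
    "data_parallel_step",
    "partition_fc",
    "model_parallel_dense",
    "model_parallel_dense_backward",
    "model_parallel_step",
    "hybrid_step",
]


@dataclass(frozen=True)
class ShardPlan:
    """Assignment of ``n`` sample indices to ``k`` workers."""

    k: int
    n: int
    shard_indices: tuple  # tuple of index arrays

    @property
    def shard_sizes(self) -> tuple[int, ...]:
        return tuple(len(ix) for ix in self.shard_indices)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if sum(self.shard_sizes) != self.n:
            raise ValueError("shard sizes must sum to n")
        all_ix = np.concatenate([np.asarray(ix) for ix in self.shard_indices])
        if len(np.unique(all_ix)) != self.n:
            raise ValueError("every sample index must appear in exactly one shard")


def make_shard_plan(n: int, k: int, seed: int | None = None) -> ShardPlan:
    """Near-equal contiguous shards of a permutation of ``0..n-1``.

    Sizes differ by at most one (the remainder is spread over the first
    shards).  ``k == 1`` always yields the identity permutation.
    """
    if k < 1:
        raise ValueError(f"worker count must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"more workers ({k}) than samples ({n})")
    if k == 1:
        perm = np.arange(n)
    elif seed is None:
        perm = np.arange(n)
    else:
        perm = np.random.default_rng(seed).permutation(n)
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    out, pos = [], 0
    for s in sizes:
        out.append(perm[pos : pos + s])
        pos += s
    return ShardPlan(k=k, n=n, shard_indices=tuple(out))


def aggregate_gradients(shard_grads: list[GradientSet], shard_sizes: list[int]) -> GradientSet:
    """Weighted combination ``sum_i (m_i / n) g_i`` of per-shard gradients.

    With equal shards this is the plain mean ``(1/k) sum_i g_i``.
    """
    if len(shard_grads) != len(shard_sizes):
        raise ValueError(
            f"{len(shard_grads)} gradient sets vs {len(shard_sizes)} shard sizes"
        )
    if any(s <= 0 for s in shard_sizes):
        raise ValueError("shard sizes must be positive")
    n = float(sum(shard_sizes))
    return weighted_combination(shard_grads, [m / n for m in shard_sizes])


def serial_step(
    spec: NetworkSpec,
    params: ParamSet,
    x: np.ndarray,
    labels: np.ndarray,
    optimizer: OptimizerState,
    root_seed: int = 0,
):
    """Ordinary single-worker training step (the oracle all parallel modes
    are contracted against)."""
    loss, _, cache = forward(spec, params, x, labels, "train", root_seed)
    grads = backward(cache)
    return opt_step(optimizer, params, grads), loss


def data_parallel_step(
    spec: NetworkSpec,
    params: ParamSet,
    x: np.ndarray,
    labels: np.ndarray,
    plan: ShardPlan,
    optimizer: OptimizerState,
    root_seed: int = 0,
):
    """Sharded forward/backward + weighted aggregation + one update.

    Each virtual worker sees its shard with *global* sample indices, so
    dropout masks match serial execution exactly.
    """
    if plan.n != x.shape[0]:
        raise ValueError(f"plan covers {plan.n} samples but batch has {x.shape[0]}")
    shard_grads, losses = [], []
    for ix in plan.shard_indices:
        loss, _, cache = forward(
            spec, params, x[ix], labels[ix], "train", root_seed, sample_indices=ix
        )
        shard_grads.append(backward(cache))
        losses.append(loss)
    agg = aggregate_gradients(shard_grads, list(plan.shard_sizes))
    loss = float(np.dot(losses, np.asarray(plan.shard_sizes) / plan.n))
    return opt_step(optimizer, params, agg), loss


# -- model parallelism ----------------------------------------------------

@dataclass(frozen=True)
class FcPartition:
    """Half-open output-unit column ranges, one per worker."""

    k: int
    ranges: tuple  # tuple of (start, stop)

    def __post_init__(self) -> None:
        stops = 0
        for a, b in self.ranges:
            if a != stops or b < a:
                raise ValueError("ranges must be contiguous, disjoint and ordered")
            stops = b


def partition_fc(units: int, k: int) -> FcPartition:
    """Split ``units`` output neurons into ``k`` near-equal column blocks."""
    if k < 1:
        raise ValueError(f"worker count must be >= 1, got {k}")
    if k > units:
        raise ValueError(f"more workers ({k}) than output units ({units})")
    base, rem = divmod(units, k)
    ranges, pos = [], 0
    for i in range(k):
        s = base + (1 if i < rem else 0)
        ranges.append((pos, pos + s))
        pos += s
    return FcPartition(k=k, ranges=tuple(ranges))


def model_parallel_dense(x, weights, bias, partition: FcPartition):
    """Column-blocked dense forward: each worker computes
    ``x @ W[:, a:b] + b[a:b]``; concatenation equals the full matmul."""
    x = np.asarray(x, dtype=float)
    if x.ndim > 2:
        x = x.reshape(x.shape[0], -1)
    w = np.asarray(weights, dtype=float)
    b = np.asarray(bias, dtype=float)
    if partition.ranges[-1][1] != w.shape[1]:
        raise ValueError(
            f"partition covers {partition.ranges[-1][1]} units, weights have {w.shape[1]}"
        )
    blocks = [x @ w[:, a:bb] + b[a:bb] for a, bb in partition.ranges]
    out = np.concatenate(blocks, axis=1)
    return out, (x, w, partition)


def model_parallel_dense_backward(dout, cache):
    """Per-block weight/bias gradients concatenated; input gradients summed
    across workers (each holds a partial product)."""
    x, w, partition = cache
    dout = np.asarray(dout, dtype=float)
    dw_blocks, db_blocks = [], []
    dx = np.zeros_like(x)
    for a, b in partition.ranges:
        up = dout[:, a:b]
        dw_blocks.append(x.T @ up)
        db_blocks.append(up.sum(axis=0))
        dx += up @ w[:, a:b].T
    return dx, np.concatenate(dw_blocks, axis=1), np.concatenate(db_blocks)


# -- hybrid orchestration -------------------------------------------------

@dataclass(frozen=True)
class HybridConfig:
    """(k, m, n_fc): worker count, conv-stage micro-batch size, fc-stage
    batch size.  Conv micro-batch activations are buffered until ``n_fc``
    samples exist for the dense stages."""

    k: int = 1
    conv_batch: int = 8
    fc_batch: int = 8

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.conv_batch < 1 or self.fc_batch < 1:
            raise ValueError("batch sizes must be >= 1")


def _dense_part_forward(spec, params, h, labels_part, cfg, start, root_seed, sample_indices):
    """Model-parallel walk of layers[start:] on a flat activation batch."""
    caches = []
    x = h
    for li in range(start, len(spec.layers)):
        lay = spec.layers[li]
        if lay.kind == "dense":
            part = partition_fc(lay.filters, min(cfg.k, lay.filters))
            x, cache = model_parallel_dense(
                x, params[f"{lay.name}/w"], params[f"{lay.name}/b"], part
            )
            caches.append((li, "mp_dense", cache))
        elif lay.kind in ("activation", "dropout", "softmax", "norm", "gap", "maxpool"):
            x, sub = run_layers(
                spec, params, x, li, li + 1, "train", root_seed, sample_indices
            )
            caches.extend(sub)
        else:  # pragma: no cover
            raise AssertionError(f"unexpected layer {lay.kind} after the fc boundary")
    loss, probs, dlogits = L.softmax_xent(x, labels_part)
    return loss, probs, dlogits, caches


def _dense_part_backward(spec, caches, dout):
    grads = GradientSet()
    dx = dout
    for li, kind, cache in reversed(caches):
        lay = spec.layers[li]
        if kind == "mp_dense":
            dx, dw, db = model_parallel_dense_backward(dx, cache)
            grads[f"{lay.name}/w"] = dw
            grads[f"{lay.name}/b"] = db
        else:
            dx, sub = run_layers_backward(spec, [(li, kind, cache)], dx)
            grads.update(sub)
    return dx, grads


def model_parallel_step(
    spec: NetworkSpec,
    params: ParamSet,
    x: np.ndarray,
    labels: np.ndarray,
    k: int,
    optimizer: OptimizerState,
    root_seed: int = 0,
):
    """Full-batch step with every dense layer partitioned over ``k``
    workers; conv stages run unsharded."""
    cfg = HybridConfig(k=k, conv_batch=x.shape[0], fc_batch=x.shape[0])
    return hybrid_step(spec, params, x, labels, cfg, optimizer, root_seed)


def hybrid_step(
    spec: NetworkSpec,
    params: ParamSet,
    x: np.ndarray,
    labels: np.ndarray,
    config: HybridConfig,
    optimizer: OptimizerState,
    root_seed: int = 0,
):
    """One hybrid-parallel update, numerically equivalent to serial.

    Conv/pool/GAP stages run data-parallel over micro-batches of
    ``conv_batch`` samples; their output activations accumulate in a buffer
    and the dense stages consume it in model-parallel fc batches of
    ``fc_batch`` samples.  Gradients flow back through the buffer to the
    retained conv caches; all contributions are weighted by sample share so
    the total equals the full-batch gradient of the mean loss.
    """
    n = x.shape[0]
    boundary = first_dense_index(spec)
    m, nfc = config.conv_batch, config.fc_batch

    # conv stage: data-parallel micro-batches (sequential virtual workers)
    micro = []  # (index array, activations, caches)
    for a in range(0, n, m):
        ix = np.arange(a, min(a + m, n))
        h, caches = run_layers(
            spec, params, x[ix], 0, boundary, "train", root_seed, sample_indices=ix
        )
        micro.append((ix, h, caches))
    gathered = np.concatenate([h for _, h, _ in micro], axis=0)

    # dense stage: model-parallel fc batches over the gathered buffer
    total_loss = 0.0
    d_gathered = np.zeros_like(gathered)
    dense_grads: list[GradientSet] = []
    dense_weights: list[float] = []
    for a in range(0, n, nfc):
        ix = np.arange(a, min(a + nfc, n))
        loss, _, dlogits, caches = _dense_part_forward(
            spec, params, gathered[ix], labels[ix], config, boundary, root_seed, ix
        )
        share = len(ix) / n
        total_loss += share * loss
        # rescale the per-fc-batch mean-loss gradient to the global mean
        dh, grads = _dense_part_backward(spec, caches, dlogits * share)
        d_gathered[ix] = dh
        dense_grads.append(grads)
        dense_weights.append(1.0)

    # conv backward per micro-batch, weighted aggregation
    conv_grads: list[GradientSet] = []
    pos = 0
    for ix, h, caches in micro:
        dh = d_gathered[pos : pos + len(ix)]
        pos += len(ix)
        _, grads = run_layers_backward(spec, caches, dh)
        conv_grads.append(grads)

    grads = GradientSet()
    for gset in dense_grads + conv_grads:
        for key, val in gset.items():
            grads[key] = grads.get(key, 0.0) + val
    return opt_step(optimizer, params, grads), float(total_loss)
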