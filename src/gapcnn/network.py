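"""Declarative network specification, shape inference and composition.

A :class:`NetworkSpec` is an ordered stack of :class:`LayerSpec` entries
(conv, maxpool, norm, dense, gap, dropout, activation, softmax) plus an
input shape and class count.  It drives three things:

* :func:`infer_shapes` — a deterministic static shape walk (the "output
  calculation" column of an architecture table);
* :func:`init_params` — Xavier-uniform weights, constant-0.1 biases;
* :func:`forward` / :func:`backward` — the full differentiable pass,
  composed from the primitives in :mod:`gapcnn.layers`.

``forward`` can also run a *sub-range* of layers (``run_layers``), which is
what the hybrid-parallel orchestrator uses to split the stack at the
conv-to-dense boundary.

Dropout masks are a pure function of ``(root_seed, layer_index, global
sample index)`` via counter-based Philox streams, so re-sharding a batch
across simulated workers can never change the effective mask.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import layers as L
from .activation import get_activation

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "ParamSet",
    "GradientSet",
    "weighted_combination",
    "infer_shapes",
    "init_params",
    "param_count",
    "forward",
    "backward",
    "run_layers",
    "run_layers_backward",
    "first_dense_index",
    "table1_spec",
    "tiny_spec",
    "save_checkpoint",
    "load_checkpoint",
]

_KINDS = {"conv", "maxpool", "norm", "dense", "gap", "dropout", "activation", "softmax"}


@dataclass
class LayerSpec:
    kind: str
    name: str = ""
    kernel_h: int = 1
    kernel_w: int = 1
    filters: int = 1
    stride: int = 1
    padding: object = "same"  # "same" | "valid" | int
    rate: float = 0.5  # dropout only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.stride < 1:
            raise ValueError(f"{self.kind}: stride must be >= 1, got {self.stride}")
        if self.kernel_h < 1 or self.kernel_w < 1:
            raise ValueError(f"{self.kind}: kernel dims must be >= 1")
        if self.kind == "dropout" and not (0.0 <= self.rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {self.rate}")
        if self.kind in ("conv", "dense") and self.filters < 1:
            raise ValueError(f"{self.kind}: filters must be >= 1, got {self.filters}")


@dataclass
class NetworkSpec:
    layers: list[LayerSpec]
    input_shape: tuple[int, int, int]
    class_count: int = 3
    activation: str = "nnlu"
    alpha: float = 0.333
    lrn_radius: int = 2
    lrn_k0: float = 2.0
    lrn_a: float = 1e-4
    lrn_b: float = 0.75

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(v) for v in self.input_shape)
        if len(self.input_shape) != 3 or min(self.input_shape) < 1:
            raise ValueError(f"input_shape must be (H, W, C) >= 1, got {self.input_shape}")
        if self.class_count < 2:
            raise ValueError("class_count must be >= 2")
        counters: dict[str, int] = {}
        taken = {lay.name for lay in self.layers if lay.name}
        for lay in self.layers:
            if not lay.name:
                counters[lay.kind] = counters.get(lay.kind, 0) + 1
                name = f"{lay.kind}{counters[lay.kind]}"
                while name in taken:
                    counters[lay.kind] += 1
                    name = f"{lay.kind}{counters[lay.kind]}"
                lay.name = name
                taken.add(name)
        names = [lay.name for lay in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {sorted(names)}")
        kinds = [l.kind for l in self.layers]
        if kinds.count("softmax") != 1 or kinds[-1] != "softmax":
            raise ValueError("spec must end with exactly one softmax layer")
        if "gap" in kinds:
            dense_after_gap = [
                i for i, k in enumerate(kinds) if k == "dense" and i > kinds.index("gap")
            ]
            if not dense_after_gap:
                raise ValueError("GAP must precede the final dense layer")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        layers_ = [LayerSpec(**ld) for ld in d["layers"]]
        kw = {k: v for k, v in d.items() if k != "layers"}
        return cls(layers=layers_, **kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def spec_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class ArrayMap(dict):
    """Named collection of arrays (parameters or their gradients).

    Supports the linear algebra needed by gradient aggregation: scalar
    scaling and elementwise addition over congruent key sets.
    """

    def check_congruent(self, other: "ArrayMap") -> None:
        if set(self) != set(other):
            raise ValueError(
                f"key mismatch: {sorted(set(self) ^ set(other))}"
            )
        for k in self:
            if self[k].shape != other[k].shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: {self[k].shape} vs {other[k].shape}"
                )

    def scaled(self, c: float) -> "ArrayMap":
        return type(self)({k: c * v for k, v in self.items()})

    def __add__(self, other: "ArrayMap") -> "ArrayMap":
        self.check_congruent(other)
        return type(self)({k: self[k] + other[k] for k in self})

    def copy(self) -> "ArrayMap":
        return type(self)({k: v.copy() for k, v in self.items()})

    def max_abs(self) -> float:
        return max((np.abs(v).max() for v in self.values()), default=0.0)


class ParamSet(ArrayMap):
    pass


class GradientSet(ArrayMap):
    pass


def weighted_combination(grads: list[GradientSet], weights: list[float]) -> GradientSet:
    """``sum_i w_i * g_i`` over congruent gradient sets."""
    if len(grads) != len(weights):
        raise ValueError(f"{len(grads)} gradient sets but {len(weights)} weights")
    if not grads:
        raise ValueError("empty gradient list")
    out = grads[0].scaled(weights[0])
    for g, w in zip(grads[1:], weights[1:]):
        out = out + g.scaled(w)
    return GradientSet(out)


# -- shape inference ------------------------------------------------------

def _conv_out(size: int, k: int, stride: int, padding) -> int:
    before, after = L.pad_amounts(size, k, stride, padding)
    return (size + before + after - k) // stride + 1


def infer_shapes(spec: NetworkSpec) -> list[tuple[str, tuple]]:
    """Static output shape per layer, in order (shapes exclude the batch dim)."""
    h, w, c = spec.input_shape
    shape: tuple = (h, w, c)
    out = []
    for lay in spec.layers:
        if lay.kind == "conv":
            if len(shape) != 3:
                raise ValueError(f"{lay.name}: conv needs a 3-D input, got {shape}")
            h2 = _conv_out(shape[0], lay.kernel_h, lay.stride, lay.padding)
            w2 = _conv_out(shape[1], lay.kernel_w, lay.stride, lay.padding)
            if h2 < 1 or w2 < 1:
                raise ValueError(f"{lay.name}: non-positive output dims ({h2},{w2})")
            shape = (h2, w2, lay.filters)
        elif lay.kind == "maxpool":
            if len(shape) != 3:
                raise ValueError(f"{lay.name}: pool needs a 3-D input, got {shape}")
            h2 = _conv_out(shape[0], lay.kernel_h, lay.stride, lay.padding)
            w2 = _conv_out(shape[1], lay.kernel_w, lay.stride, lay.padding)
            if h2 < 1 or w2 < 1:
                raise ValueError(f"{lay.name}: non-positive output dims ({h2},{w2})")
            shape = (h2, w2, shape[2])
        elif lay.kind == "gap":
            if len(shape) != 3:
                raise ValueError(f"{lay.name}: GAP needs a 3-D input, got {shape}")
            shape = (shape[2],)
        elif lay.kind == "dense":
            shape = (lay.filters,)
        elif lay.kind in ("norm", "dropout", "activation", "softmax"):
            pass
        out.append((lay.name, shape))
    return out


# -- parameters -----------------------------------------------------------

def init_params(spec: NetworkSpec, seed: int = 0, bias_value: float = 0.1) -> ParamSet:
    """Xavier-uniform weights (limit ``sqrt(6/(fan_in+fan_out))``), constant
    biases."""
    rng = np.random.default_rng(seed)
    params = ParamSet()
    h, w, c = spec.input_shape
    shape: tuple = (h, w, c)
    for lay in spec.layers:
        if lay.kind == "conv":
            cin = shape[2]
            fan_in = lay.kernel_h * lay.kernel_w * cin
            fan_out = lay.kernel_h * lay.kernel_w * lay.filters
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            params[f"{lay.name}/w"] = rng.uniform(
                -lim, lim, (lay.kernel_h, lay.kernel_w, cin, lay.filters)
            )
            params[f"{lay.name}/b"] = np.full(lay.filters, bias_value)
        elif lay.kind == "dense":
            d = int(np.prod(shape))
            lim = np.sqrt(6.0 / (d + lay.filters))
            params[f"{lay.name}/w"] = rng.uniform(-lim, lim, (d, lay.filters))
            params[f"{lay.name}/b"] = np.full(lay.filters, bias_value)
        # advance the static shape
        for name, s in infer_shapes(spec):
            if name == lay.name:
                shape = s
                break
    return params


def param_count(params: ParamSet) -> int:
    return int(sum(v.size for v in params.values()))


# -- forward / backward ---------------------------------------------------

def _dropout_mask(shape, rate, root_seed, layer_idx, sample_indices):
    """Per-sample masks from counter-based streams keyed by
    (root_seed, layer index, global sample index)."""
    n = shape[0]
    mask = np.empty(shape)
    for i in range(n):
        key = (
            int(root_seed) & 0xFFFFFFFFFFFFFFFF,
            (int(layer_idx) << 32) | (int(sample_indices[i]) & 0xFFFFFFFF),
        )
        rng = np.random.Generator(np.random.Philox(key=key))
        mask[i] = (rng.random(shape[1:]) >= rate) / (1.0 - rate)
    return mask


def run_layers(
    spec: NetworkSpec,
    params: ParamSet,
    x: np.ndarray,
    start: int = 0,
    stop: int | None = None,
    mode: str = "train",
    root_seed: int = 0,
    sample_indices=None,
):
    """Run layers ``spec.layers[start:stop]`` (softmax excluded if terminal).

    Returns ``(out, caches)``; ``caches`` is consumed by
    :func:`run_layers_backward`.
    """
    if stop is None:
        stop = len(spec.layers)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if sample_indices is None:
        sample_indices = np.arange(n)
    val_fn, grad_fn = get_activation(spec.activation, spec.alpha)
    caches = []
    for li in range(start, stop):
        lay = spec.layers[li]
        if lay.kind == "conv":
            x, cache = L.conv_forward(
                x, params[f"{lay.name}/w"], params[f"{lay.name}/b"], lay.stride, lay.padding
            )
            caches.append((li, "conv", cache))
        elif lay.kind == "maxpool":
            x, cache = L.maxpool_forward(x, lay.kernel_h, lay.stride, lay.padding)
            caches.append((li, "maxpool", cache))
        elif lay.kind == "norm":
            x, cache = L.lrn_forward(x, spec.lrn_radius, spec.lrn_k0, spec.lrn_a, spec.lrn_b)
            caches.append((li, "norm", cache))
        elif lay.kind == "dense":
            x, cache = L.dense_forward(x, params[f"{lay.name}/w"], params[f"{lay.name}/b"])
            caches.append((li, "dense", cache))
        elif lay.kind == "gap":
            x, cache = L.gap_forward(x)
            caches.append((li, "gap", cache))
        elif lay.kind == "activation":
            caches.append((li, "activation", (x.copy(), grad_fn)))
            x = val_fn(x)
        elif lay.kind == "dropout":
            if mode == "train" and lay.rate > 0.0:
                mask = _dropout_mask(x.shape, lay.rate, root_seed, li, sample_indices)
            else:
                mask = np.ones_like(x)
            x = x * mask
            caches.append((li, "dropout", mask))
        elif lay.kind == "softmax":
            caches.append((li, "softmax", None))  # handled by the loss head
        else:  # pragma: no cover
            raise AssertionError(lay.kind)
    return x, caches


def run_layers_backward(spec: NetworkSpec, caches, dout: np.ndarray):
    """Chain-rule walk back through cached layers.

    Returns ``(dx, grads)`` — gradient w.r.t. the sub-stack input and a
    :class:`GradientSet` for the parameters of the layers traversed.
    """
    grads = GradientSet()
    dx = np.asarray(dout, dtype=float)
    for li, kind, cache in reversed(caches):
        lay = spec.layers[li]
        if kind == "conv":
            dx, dw, db = L.conv_backward(dx, cache)
            grads[f"{lay.name}/w"] = dw
            grads[f"{lay.name}/b"] = db
        elif kind == "maxpool":
            dx = L.maxpool_backward(dx, cache)
        elif kind == "norm":
            dx = L.lrn_backward(dx, cache)
        elif kind == "dense":
            dx, dw, db = L.dense_backward(dx, cache)
            grads[f"{lay.name}/w"] = dw
            grads[f"{lay.name}/b"] = db
        elif kind == "gap":
            dx = L.gap_backward(dx, cache)
        elif kind == "activation":
            x_pre, grad_fn = cache
            dx = dx * grad_fn(x_pre)
        elif kind == "dropout":
            dx = dx * cache
        elif kind == "softmax":
            pass
    return dx, grads


def forward(
    spec: NetworkSpec,
    params: ParamSet,
    x: np.ndarray,
    labels: np.ndarray,
    mode: str = "train",
    root_seed: int = 0,
    sample_indices=None,
):
    """Full forward pass with the softmax cross-entropy head.

    Returns ``(loss, probs, cache)``; pass ``cache`` to :func:`backward`
    for the parameter gradients of the mean loss.
    """
    logits, caches = run_layers(
        spec, params, x, 0, len(spec.layers), mode, root_seed, sample_indices
    )
    loss, probs, dlogits = L.softmax_xent(logits, labels)
    return loss, probs, (spec, caches, dlogits)


def backward(cache) -> GradientSet:
    spec, caches, dlogits = cache
    _, grads = run_layers_backward(spec, caches, dlogits)
    return grads


def first_dense_index(spec: NetworkSpec) -> int:
    """Index of the first dense layer — the conv/dense boundary used by the
    hybrid-parallel orchestrator."""
    for i, lay in enumerate(spec.layers):
        if lay.kind == "dense":
            return i
    raise ValueError("spec has no dense layer")


# -- canonical architectures ----------------------------------------------

def table1_spec(width_divisor: int = 1, input_size: int = 224, channels: int = 3) -> NetworkSpec:
    """The published GAPCNN layer stack (AlexNet-style).

    One 11x11, one 5x5, two 3x3 and two 6x6 conv layers interleaved with
    3x3/2x2 stride-2 max pools and two cross-channel normalization layers,
    a GAP head, a 4096-unit dense layer with dropout and a 3-way softmax.
    ``width_divisor`` scales every channel width down for desk-scale runs;
    at 1 the stack reproduces the published output-shape table.
    """
    d = width_divisor

    def f(n: int) -> int:
        return max(n // d, 1)

    act = LayerSpec  # alias for brevity
    layers_ = [
        act("conv", name="conv1", kernel_h=11, kernel_w=11, filters=f(64), stride=1),
        act("activation", name="act1"),
        act("maxpool", name="pool1", kernel_h=3, kernel_w=3, stride=2),
        act("norm", name="norm1"),
        act("conv", name="conv2", kernel_h=5, kernel_w=5, filters=f(256), stride=1),
        act("activation", name="act2"),
        act("maxpool", name="pool2", kernel_h=3, kernel_w=3, stride=2),
        act("norm", name="norm2"),
        act("conv", name="conv3", kernel_h=3, kernel_w=3, filters=f(256), stride=1),
        act("activation", name="act3"),
        act("conv", name="conv4", kernel_h=3, kernel_w=3, filters=f(256), stride=1),
        act("activation", name="act4"),
        act("conv", name="conv5", kernel_h=6, kernel_w=6, filters=f(4096), stride=1),
        act("activation", name="act5"),
        act("maxpool", name="pool3", kernel_h=2, kernel_w=2, stride=2),
        act("conv", name="conv6", kernel_h=6, kernel_w=6, filters=f(4096), stride=1),
        act("activation", name="act6"),
        act("maxpool", name="pool4", kernel_h=2, kernel_w=2, stride=2),
        act("gap", name="gap"),
        act("dense", name="fc1", filters=f(4096)),
        act("activation", name="act7"),
        act("dropout", name="drop1", rate=0.5),
        act("dense", name="fc2", filters=3),
        act("softmax", name="softmax"),
    ]
    return NetworkSpec(
        layers=layers_, input_shape=(input_size, input_size, channels), class_count=3
    )


def tiny_spec(
    input_size: int = 32,
    channels: int = 1,
    class_count: int = 3,
    activation: str = "nnlu",
    alpha: float = 0.333,
    dropout_rate: float = 0.0,
    widths: tuple[int, int] = (8, 16),
) -> NetworkSpec:
    """A two-block GAP network small enough to train in seconds on a CPU."""
    layers_ = [
        LayerSpec("conv", kernel_h=3, kernel_w=3, filters=widths[0], stride=1),
        LayerSpec("activation"),
        LayerSpec("maxpool", kernel_h=2, kernel_w=2, stride=2),
        LayerSpec("conv", kernel_h=3, kernel_w=3, filters=widths[1], stride=1),
        LayerSpec("activation"),
        LayerSpec("maxpool", kernel_h=2, kernel_w=2, stride=2),
        LayerSpec("gap"),
        LayerSpec("dense", filters=32),
        LayerSpec("activation"),
    ]
    if dropout_rate > 0:
        layers_.append(LayerSpec("dropout", rate=dropout_rate))
    layers_ += [LayerSpec("dense", filters=class_count), LayerSpec("softmax")]
    return NetworkSpec(
        layers=layers_,
        input_shape=(input_size, input_size, channels),
        class_count=class_count,
        activation=activation,
        alpha=alpha,
    )


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(path, spec: NetworkSpec, params: ParamSet, seed: int = 0, epoch: int = 0):
    """Write ``<path>.npz`` (named arrays) plus ``<path>.json`` (manifest
    with the spec, its hash, the seed and the epoch)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **params)
    manifest = {
        "spec": spec.to_dict(),
        "spec_hash": spec.spec_hash(),
        "seed": int(seed),
        "epoch": int(epoch),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns ``(spec, params, manifest)``."""
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec.from_dict(manifest["spec"])
    with np.load(path.with_suffix(".npz")) as z:
        params = ParamSet({k: z[k] for k in z.files})
    return spec, params, manifest
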