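"""Training/evaluation orchestration as model + results objects.

:class:`GAPCNN` binds a network specification to a dataset (typically the
synthetic phantom set); :meth:`GAPCNN.fit` runs the epoch loop under any
parallel mode (serial, data, model, hybrid) and returns a
:class:`TrainingResults` carrying the fitted parameters, the per-epoch
history, ``evaluate``/``predict``/``summary`` and checkpointing.  The
functional entry points :func:`train`, :func:`evaluate` and :func:`sweep`
are thin wrappers over these objects.

All randomness (weight init, batch order, dropout) derives from a single
integer seed, and batch order / dropout streams are independent of the
parallel mode, so hybrid training is numerically equivalent to serial.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import network as N
from . import parallel as P
from .optim import OptimizerState, make_optimizer
from .synth_data import PhantomConfig, make_dataset

__all__ = ["TrainConfig", "GAPCNN", "TrainingResults", "train", "evaluate_arrays", "sweep"]

HISTORY_COLUMNS = ["epoch", "train_loss", "train_acc", "val_loss", "val_acc", "seconds"]


@dataclass
class TrainConfig:
    """Declarative training run; maps 1:1 onto the YAML config surface."""

    network: str = "tiny"  # "tiny", "table1", or a path to a spec YAML
    data: PhantomConfig = field(default_factory=lambda: PhantomConfig(image_size=32, scale=0.003))
    epochs: int = 3
    batch_size: int = 32
    mode: str = "serial"  # serial | data | model | hybrid
    k: int = 1
    conv_batch: int = 8
    fc_batch: int = 8
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    opt_eps: float = 1e-8
    dropout: float = 0.0
    activation: str = "nnlu"
    alpha: float = 0.333
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mode not in ("serial", "data", "model", "hybrid"):
            raise ValueError(f"unknown parallel mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        data = raw.pop("data", {})
        par = raw.pop("parallel", {})
        opt = raw.pop("optimizer", {})
        kw = dict(raw)
        if data:
            kw["data"] = PhantomConfig(**data)
        kw.update(
            {
                k2: v
                for k2, v in {
                    "mode": par.get("mode"),
                    "k": par.get("k"),
                    "conv_batch": par.get("conv_batch"),
                    "fc_batch": par.get("fc_batch"),
                    "optimizer": opt.get("rule"),
                    "learning_rate": opt.get("lr"),
                    "beta1": opt.get("beta1"),
                    "beta2": opt.get("beta2"),
                    "opt_eps": opt.get("eps"),
                }.items()
                if v is not None
            }
        )
        return cls(**kw)

    def build_spec(self) -> N.NetworkSpec:
        if self.network == "tiny":
            spec = N.tiny_spec(
                input_size=self.data.image_size,
                channels=self.data.channels,
                activation=self.activation,
                alpha=self.alpha,
                dropout_rate=self.dropout,
            )
        elif self.network == "table1":
            spec = N.table1_spec()
            spec.activation, spec.alpha = self.activation, self.alpha
        else:
            spec = N.NetworkSpec.from_yaml(self.network)
            spec.activation, spec.alpha = self.activation, self.alpha
        return spec

    def build_optimizer(self) -> OptimizerState:
        return make_optimizer(
            rule=self.optimizer,
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            eps=self.opt_eps,
        )


class GAPCNN:
    """A GAP-headed CNN bound to a training/validation dataset.

    Parameters
    ----------
    spec : NetworkSpec
        The layer stack (must end in softmax).
    images, labels : ndarray
        Training images ``(n, H, W, C)`` in [0, 1] and integer labels.
    val_images, val_labels : ndarray, optional
        Held-out set evaluated once per epoch.
    """

    def __init__(self, spec, images, labels, val_images=None, val_labels=None):
        self.spec = spec
        self.images = np.asarray(images, dtype=float)
        self.labels = np.asarray(labels)
        self.val_images = None if val_images is None else np.asarray(val_images, dtype=float)
        self.val_labels = None if val_labels is None else np.asarray(val_labels)
        if self.images.ndim != 4:
            raise ValueError("images must be (n, H, W, C)")
        if self.images.shape[1:] != tuple(spec.input_shape):
            raise ValueError(
                f"images {self.images.shape[1:]} do not match spec input {spec.input_shape}"
            )

    @classmethod
    def from_config(cls, config: TrainConfig) -> "GAPCNN":
        """Build the model from a declarative config over the phantom set
        (train split for fitting, val split for per-epoch metrics)."""
        spec = config.build_spec()
        imgs, labels, manifest = make_dataset(config.data)
        tr = manifest["split"] == "train"
        va = manifest["split"] == "val"
        model = cls(
            spec,
            imgs[tr.to_numpy()],
            labels[tr.to_numpy()],
            imgs[va.to_numpy()],
            labels[va.to_numpy()],
        )
        model.manifest = manifest
        model.all_images, model.all_labels = imgs, labels
        return model

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        epochs: int = 3,
        batch_size: int = 32,
        optimizer: OptimizerState | None = None,
        mode: str = "serial",
        k: int = 1,
        conv_batch: int = 8,
        fc_batch: int = 8,
        seed: int = 0,
        verbose: bool = False,
    ) -> "TrainingResults":
        opt = optimizer if optimizer is not None else make_optimizer()
        params = N.init_params(self.spec, seed=seed)
        n = self.images.shape[0]
        order_rng = np.random.default_rng((int(seed) & 0x7FFFFFFF, 17))
        records = []
        for epoch in range(1, epochs + 1):
            t0 = time.perf_counter()
            order = order_rng.permutation(n)
            batch_losses, batch_sizes = [], []
            for b, a in enumerate(range(0, n, batch_size)):
                ix = order[a : a + batch_size]
                x, y = _center(self.images[ix]), self.labels[ix]
                root_seed = ((int(seed) & 0xFFFF) << 14) + epoch * 131 + b
                if mode == "serial":
                    params, loss = P.serial_step(self.spec, params, x, y, opt, root_seed)
                elif mode == "data":
                    plan = P.make_shard_plan(len(ix), min(k, len(ix)))
                    params, loss = P.data_parallel_step(
                        self.spec, params, x, y, plan, opt, root_seed
                    )
                elif mode == "model":
                    params, loss = P.model_parallel_step(
                        self.spec, params, x, y, k, opt, root_seed
                    )
                elif mode == "hybrid":
                    cfg = P.HybridConfig(k=k, conv_batch=conv_batch, fc_batch=fc_batch)
                    params, loss = P.hybrid_step(self.spec, params, x, y, cfg, opt, root_seed)
                else:  # pragma: no cover
                    raise AssertionError(mode)
                if not np.isfinite(loss):
                    raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
                batch_losses.append(loss)
                batch_sizes.append(len(ix))
            train_loss = float(np.dot(batch_losses, batch_sizes) / n)
            train_acc = _accuracy(self.spec, params, self.images, self.labels)
            if self.val_images is not None and len(self.val_images):
                val_loss, val_acc = _loss_acc(self.spec, params, self.val_images, self.val_labels)
            else:
                val_loss, val_acc = np.nan, np.nan
            seconds = time.perf_counter() - t0
            records.append(
                dict(
                    epoch=epoch,
                    train_loss=train_loss,
                    train_acc=train_acc,
                    val_loss=val_loss,
                    val_acc=val_acc,
                    seconds=seconds,
                )
            )
            if verbose:
                import sys

                print(
                    f"epoch={epoch} phase=train loss={train_loss:.6f} acc={train_acc:.4f} "
                    f"val_loss={val_loss:.6f} val_acc={val_acc:.4f} lr={opt.learning_rate:g}",
                    file=sys.stderr,
                )
        history = pd.DataFrame.from_records(records, columns=HISTORY_COLUMNS)
        return TrainingResults(self, params, history, opt, seed=seed, mode=mode)


def _center(images: np.ndarray) -> np.ndarray:
    """Map [0, 1] pixel intensities to [-1, 0.99...]-ish zero-centered range.

    Centering keeps early-layer preactivations balanced around zero, which
    matters for both the Xavier init assumptions and the even-symmetric
    NNLU activation; applied identically at fit and predict time.
    """
    return 2.0 * images - 1.0


def _predict_probs(spec, params, images, batch: int = 64) -> np.ndarray:
    out = []
    images = _center(np.asarray(images, dtype=float))
    for a in range(0, images.shape[0], batch):
        x = images[a : a + batch]
        logits, _ = N.run_layers(spec, params, x, mode="eval")
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        out.append(ez / ez.sum(axis=1, keepdims=True))
    return np.concatenate(out, axis=0)


def _accuracy(spec, params, images, labels) -> float:
    probs = _predict_probs(spec, params, images)
    return float((probs.argmax(axis=1) == labels).mean())


def _loss_acc(spec, params, images, labels):
    probs = _predict_probs(spec, params, images)
    eps = 1e-300
    loss = float(-np.log(probs[np.arange(len(labels)), labels] + eps).mean())
    return loss, float((probs.argmax(axis=1) == labels).mean())


def evaluate_arrays(spec, params, images, labels) -> dict:
    """Accuracy, per-class precision/recall and the confusion matrix.

    Confusion rows are true classes (rows sum to per-class support);
    accuracy is trace/total.
    """
    images = np.asarray(images, dtype=float)
    if images.shape[1:] != tuple(spec.input_shape):
        raise ValueError(
            f"images {images.shape[1:]} do not match checkpoint input {spec.input_shape}"
        )
    probs = _predict_probs(spec, params, images)
    pred = probs.argmax(axis=1)
    kc = spec.class_count
    conf = np.zeros((kc, kc), dtype=int)
    np.add.at(conf, (labels, pred), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.diag(conf) / np.maximum(conf.sum(axis=0), 1)
        recall = np.diag(conf) / np.maximum(conf.sum(axis=1), 1)
    return {
        "accuracy": float(np.trace(conf) / max(conf.sum(), 1)),
        "precision": precision,
        "recall": recall,
        "confusion": conf,
    }


class TrainingResults:
    """Fitted parameters + per-epoch history for a :class:`GAPCNN` fit."""

    def __init__(self, model: GAPCNN, params, history: pd.DataFrame, optimizer, seed=0, mode="serial"):
        self.model = model
        self.spec = model.spec
        self.params = params
        self.history = history
        self.optimizer = optimizer
        self.seed = seed
        self.mode = mode

    def predict(self, images) -> np.ndarray:
        return _predict_probs(self.spec, self.params, np.asarray(images, dtype=float))

    def evaluate(self, images, labels) -> dict:
        return evaluate_arrays(self.spec, self.params, images, labels)

    def save(self, path) -> None:
        N.save_checkpoint(path, self.spec, self.params, seed=self.seed,
                          epoch=int(self.history["epoch"].iloc[-1]))

    def history_csv(self, path) -> None:
        self.history.to_csv(path, index=False)

    def summary(self) -> str:
        last = self.history.iloc[-1]
        lines = [
            "GAPCNN Training Results",
            "=" * 54,
            f"{'Layers:':<24}{len(self.spec.layers)}",
            f"{'Input shape:':<24}{self.spec.input_shape}",
            f"{'Activation:':<24}{self.spec.activation} (alpha={self.spec.alpha})",
            f"{'Parameters:':<24}{N.param_count(self.params):,}",
            f"{'Optimizer:':<24}{self.optimizer.rule} (lr={self.optimizer.learning_rate:g})",
            f"{'Parallel mode:':<24}{self.mode}",
            f"{'Epochs:':<24}{int(last['epoch'])}",
            "-" * 54,
            f"{'Final train loss:':<24}{last['train_loss']:.6f}",
            f"{'Final train accuracy:':<24}{last['train_acc']:.4f}",
            f"{'Final val loss:':<24}{last['val_loss']:.6f}",
            f"{'Final val accuracy:':<24}{last['val_acc']:.4f}",
            "=" * 54,
        ]
        return "\n".join(lines)


# -- functional surface ---------------------------------------------------

def train(config: TrainConfig, out_dir=None, verbose: bool = False) -> TrainingResults:
    """Run a full training job from a declarative config.

    Optionally writes ``history.csv`` and a checkpoint under ``out_dir``.
    """
    model = GAPCNN.from_config(config)
    res = model.fit(
        epochs=config.epochs,
        batch_size=config.batch_size,
        optimizer=config.build_optimizer(),
        mode=config.mode,
        k=config.k,
        conv_batch=config.conv_batch,
        fc_batch=config.fc_batch,
        seed=config.seed,
        verbose=verbose,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        res.history_csv(out / "history.csv")
        res.save(out / "model")
    return res


def sweep(config: TrainConfig, optimizers=("sgd", "adam", "amsgrad"),
          learning_rates=(1e-4, 2e-4, 5e-4), epoch_grid=(30, 50)) -> pd.DataFrame:
    """Grid sweep over optimizer rule, learning rate and epoch budget.

    The dataset and split are built once from the config seed, so every
    grid cell trains on identical data; one long-format row per cell.
    """
    base = GAPCNN.from_config(config)
    rows = []
    for rule in optimizers:
        for lr in learning_rates:
            for ep in epoch_grid:
                opt = make_optimizer(rule=rule, learning_rate=lr,
                                     beta1=config.beta1, beta2=config.beta2, eps=config.opt_eps)
                res = base.fit(
                    epochs=ep,
                    batch_size=config.batch_size,
                    optimizer=opt,
                    mode=config.mode,
                    k=config.k,
                    conv_batch=config.conv_batch,
                    fc_batch=config.fc_batch,
                    seed=config.seed,
                )
                last = res.history.iloc[-1]
                rows.append(
                    dict(
                        optimizer=rule,
                        learning_rate=lr,
                        epochs=ep,
                        train_loss=last["train_loss"],
                        train_acc=last["train_acc"],
                        val_loss=last["val_loss"],
                        val_acc=last["val_acc"],
                    )
                )
    return pd.DataFrame(rows)
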