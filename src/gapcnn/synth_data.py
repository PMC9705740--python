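"""Synthetic three-class brain-tumor phantom dataset.

Stands in for T1-weighted contrast-enhanced axial slices so the full
pipeline is testable without any download.  Each phantom is a grayscale
image in ``[0, 1]``: a bright skull-like ring around a darker brain disc,
plus one class-specific contrast-enhancing lesion:

* label 0 (meningioma-like): a bright disc attached peripherally, near the
  inner skull margin (meningiomas arise from the meninges);
* label 1 (glioma-like): an irregular multi-lobed intra-axial blob at
  mid-radius;
* label 2 (pituitary-like): a small midline blob just below center (sellar
  region).

Default class counts follow the 7,080 : 14,260 : 9,300
(meningioma : glioma : pituitary) study proportions, scalable by a factor
with round-half-up; at scale 1 the manifest totals 30,640 slices.

The phantoms make no claim to radiological realism — they exist to give
the classifier a learnable, class-separable geometry and to exercise the
augmentation operators (rotation, translation, brightness/contrast
jitter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "BASE_CLASS_COUNTS",
    "CLASS_NAMES",
    "make_phantom",
    "make_manifest",
    "make_dataset",
    "augment_rotate",
    "augment_translate",
    "augment_jitter",
    "default_augment_angles",
    "load_figshare_slice",
]

BASE_CLASS_COUNTS = (7080, 14260, 9300)  # meningioma, glioma, pituitary
CLASS_NAMES = ("meningioma", "glioma", "pituitary")
SPLIT_FRACTIONS = {"train": 0.70, "val": 0.15, "test": 0.15}
default_augment_angles = (-30.0, -20.0, -10.0, 10.0, 20.0, 30.0)


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 64
    scale: float = 1.0
    class_counts: tuple[int, int, int] | None = None  # overrides scale
    noise_sd: float = 0.0
    seed: int = 0
    channels: int = 1  # grayscale replicated to 3 when a spec wants RGB

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        counts = self.resolved_counts()
        if any(c < 0 for c in counts):
            raise ValueError("class counts must be >= 0")
        if sum(counts) == 0:
            raise ValueError("at least one class count must be nonzero")

    def resolved_counts(self) -> tuple[int, int, int]:
        if self.class_counts is not None:
            return tuple(int(c) for c in self.class_counts)
        # round-half-up scaling of the study proportions
        return tuple(int(math.floor(c * self.scale + 0.5)) for c in BASE_CLASS_COUNTS)


def _disc(xx, yy, cx, cy, r):
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def make_phantom(label: int, size: int = 64, noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """One grayscale phantom slice in ``[0, 1]``, deterministic per seed."""
    if label not in (0, 1, 2):
        raise ValueError(f"label must be in {{0, 1, 2}}, got {label!r}")
    rng = np.random.default_rng((int(seed) & 0x7FFFFFFF, label))
    ax = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(ax, ax, indexing="xy")
    rr = np.sqrt(xx * xx + yy * yy)
    img = np.zeros((size, size))
    img[rr <= 0.80] = 0.35  # brain parenchyma
    img[(rr >= 0.80) & (rr <= 0.92)] = 0.90  # skull ring
    if label == 0:
        # large homogeneously enhancing disc at the inner skull margin
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rad = rng.uniform(0.45, 0.52)
        lr = rng.uniform(0.19, 0.21)
        img[_disc(xx, yy, rad * np.cos(theta), rad * np.sin(theta), lr)] = 0.95
    elif label == 1:
        # irregular multi-lobed blob at mid-radius, rim-enhancing with a
        # darker heterogeneous core
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cx, cy = 0.28 * np.cos(theta), 0.28 * np.sin(theta)
        lobes = []
        for _ in range(4):
            ox, oy = rng.uniform(-0.08, 0.08, size=2)
            lr = rng.uniform(0.11, 0.13)
            lobes.append((cx + ox, cy + oy, lr))
        rim = np.zeros_like(img, dtype=bool)
        core = np.zeros_like(img, dtype=bool)
        for lx, ly, lr in lobes:
            rim |= _disc(xx, yy, lx, ly, lr)
            core |= _disc(xx, yy, lx, ly, 0.6 * lr)
        img[rim] = 0.90
        img[core] = 0.55 + 0.08 * np.sin(14.0 * xx[core] + 11.0 * yy[core])
    else:
        # small, moderately enhancing midline blob just below center
        cy = rng.uniform(0.02, 0.10)
        cx = rng.uniform(-0.03, 0.03)
        lr = rng.uniform(0.055, 0.075)
        img[_disc(xx, yy, cx, cy, lr)] = 0.80
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def _split_counts(m: int) -> dict[str, int]:
    # largest-remainder allocation of 70/15/15 within one class
    exact = {s: m * f for s, f in SPLIT_FRACTIONS.items()}
    base = {s: int(math.floor(v)) for s, v in exact.items()}
    short = m - sum(base.values())
    order = sorted(exact, key=lambda s: exact[s] - base[s], reverse=True)
    for s in order[:short]:
        base[s] += 1
    return base


def make_manifest(config: PhantomConfig) -> pd.DataFrame:
    """Per-image records (index, label, split, aug) — exact class counts,
    stratified 70/15/15 split, deterministic per seed."""
    counts = config.resolved_counts()
    rng = np.random.default_rng(config.seed)
    rows = []
    idx = 0
    for label, m in enumerate(counts):
        splits = _split_counts(m)
        assign = np.array(
            ["train"] * splits["train"] + ["val"] * splits["val"] + ["test"] * splits["test"]
        )
        rng.shuffle(assign)
        for j in range(m):
            rows.append(
                {
                    "index": idx,
                    "label": label,
                    "class_name": CLASS_NAMES[label],
                    "split": assign[j],
                    "aug": "none",
                    "seed": int(rng.integers(0, 2**31 - 1)),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def make_dataset(config: PhantomConfig):
    """Materialise the dataset: returns ``(images, labels, manifest)``.

    ``images`` has shape ``(n, H, W, channels)`` in ``[0, 1]``.  A pure
    function of the config — byte-identical on re-runs.
    """
    manifest = make_manifest(config)
    n = len(manifest)
    imgs = np.empty((n, config.image_size, config.image_size), dtype=float)
    for i, row in enumerate(manifest.itertuples()):
        imgs[i] = make_phantom(row.label, config.image_size, config.noise_sd, row.seed)
    imgs = imgs[..., None]
    if config.channels == 3:
        imgs = np.repeat(imgs, 3, axis=3)
    labels = manifest["label"].to_numpy()
    return imgs, labels, manifest


# -- augmentation operators -----------------------------------------------

def augment_rotate(image: np.ndarray, angle_degrees: float) -> np.ndarray:
    """Rotation about the center, bilinear interpolation, zero fill."""
    if not np.isfinite(angle_degrees):
        raise ValueError("angle must be finite")
    return np.clip(
        ndimage.rotate(image, angle_degrees, reshape=False, order=1, mode="constant", cval=0.0),
        0.0,
        1.0,
    )


def augment_translate(image: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer-pixel shift (dx columns, dy rows), zero fill."""
    h, w = image.shape[:2]
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"shift ({dx},{dy}) must be smaller than image size ({h},{w})")
    out = np.zeros_like(image)
    src_r = slice(max(0, -dy), min(h, h - dy))
    dst_r = slice(max(0, dy), min(h, h + dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = image[src_r, src_c]
    return out


def augment_jitter(
    image: np.ndarray,
    brightness_delta: float | None = None,
    contrast_factor: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Brightness/contrast jitter, clipped to [0, 1].

    If a parameter is ``None`` it is sampled (brightness U(-0.1, 0.1),
    contrast U(0.8, 1.2)) from ``seed``.
    """
    rng = np.random.default_rng(seed)
    if brightness_delta is None:
        brightness_delta = rng.uniform(-0.1, 0.1)
    if contrast_factor is None:
        contrast_factor = rng.uniform(0.8, 1.2)
    if not (np.isfinite(brightness_delta) and np.isfinite(contrast_factor)):
        raise ValueError("jitter parameters must be finite")
    mean = image.mean()
    return np.clip((image - mean) * contrast_factor + mean + brightness_delta, 0.0, 1.0)


# -- optional real-data loader --------------------------------------------

def load_figshare_slice(path):
    """Read one slice of the figshare brain-tumor archive (HDF5 per-slice
    files with ``cjdata/image``, ``cjdata/label``, ``cjdata/PID``).

    Read-only convenience for users who have downloaded the archive; no
    package functionality depends on it.  Returns ``(image, label, pid)``
    with the image min-max scaled to [0, 1] and the label shifted to
    0-based {meningioma, glioma, pituitary}.
    """
    import h5py

    with h5py.File(path, "r") as f:
        grp = f["cjdata"]
        img = np.asarray(grp["image"], dtype=float)
        label = int(np.asarray(grp["label"]).ravel()[0]) - 1
        pid = bytes(np.asarray(grp["PID"], dtype=np.uint8).ravel()).decode(
            "ascii", errors="replace"
        )
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return img, label, pid
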