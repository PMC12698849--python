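"""Labeled image sets: synthetic generation, folder I/O, preprocessing, partitioning.

The synthetic generator emulates the structure of a four-class brain-MRI tumor
dataset: grayscale images of a noisy "brain" disc where class 0 carries no
lesion and classes >= 1 carry an elliptical bright lesion whose position, size
and intensity distributions are class-specific. The classes are separable
enough for a small CNN to exceed 90% held-out accuracy, which is what makes
the downstream privacy experiments meaningful without any external download.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

DEFAULT_CLASS_NAMES = ("no_tumour", "glioma", "meningioma", "pituitary")


@dataclass
class LabeledImageSet:
    """Grayscale images with integer class labels.

    ``images`` has shape (n, H, W); ``labels`` values lie in {0..C-1};
    ``value_range`` records the nominal pixel range (raw images (0, 255),
    preprocessed images (-1, 1)).
    """

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3:
            raise ValueError(f"images must be (n, H, W), got {self.images.shape}")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels differ in length")
        c = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= c):
            raise ValueError(f"labels outside {{0..{c - 1}}}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def image_size(self) -> int:
        return self.images.shape[1]

    def subset(self, indices: np.ndarray | list[int]) -> "LabeledImageSet":
        idx = np.asarray(indices, dtype=np.int64)
        return replace(self, images=self.images[idx], labels=self.labels[idx])


@dataclass
class PartitionPlan:
    """Disjoint per-client index shards covering a dataset."""

    k: int
    shard_indices: list[np.ndarray]
    shard_sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shard_indices = [np.asarray(s, dtype=np.int64) for s in self.shard_indices]
        self.shard_sizes = [len(s) for s in self.shard_indices]
        allidx = np.concatenate(self.shard_indices) if self.shard_indices else np.array([], dtype=np.int64)
        if len(np.unique(allidx)) != len(allidx):
            raise ValueError("partition shards overlap")


# geometry of the synthetic classes: (center offsets as a fraction of the image
# size, lesion radius fraction, lesion intensity).  Class 0 has no lesion.
_LESION_SPEC = {
    1: {"center": (-0.22, -0.22), "jitter": 0.06, "radius": (0.08, 0.12), "intensity": 110.0},
    2: {"center": (0.0, 0.0), "jitter": 0.05, "radius": (0.15, 0.20), "intensity": 80.0},
    3: {"center": (0.22, 0.22), "jitter": 0.06, "radius": (0.08, 0.12), "intensity": 130.0},
}


def _lesion_params(c: int) -> dict:
    if c in _LESION_SPEC:
        return _LESION_SPEC[c]
    # classes beyond the default four get generated positions around a ring
    ang = 2 * np.pi * (c % 8) / 8.0
    return {"center": (0.22 * np.cos(ang), 0.22 * np.sin(ang)),
            "jitter": 0.05, "radius": (0.10, 0.14), "intensity": 90.0 + 10.0 * c}


def generate_synthetic_images(n_per_class: int, n_classes: int = 4,
                              image_size: int = 32, seed: int = 0) -> LabeledImageSet:
    """Generate a balanced synthetic grayscale image set.

    Class 0 is a noisy brain disc with no lesion; classes >= 1 add a bright
    elliptical lesion with class-specific position, size and intensity.
    Deterministic given ``seed``.
    """
    if n_per_class < 1 or n_classes < 2:
        raise ValueError("need n_per_class >= 1 and n_classes >= 2")
    if image_size < 8:
        raise ValueError("image_size must be >= 8")
    rng = np.random.default_rng(seed)
    s = image_size
    yy, xx = np.mgrid[0:s, 0:s]
    cx = cy = (s - 1) / 2.0
    brain = (((xx - cx) / (0.45 * s)) ** 2 + ((yy - cy) / (0.40 * s)) ** 2) <= 1.0

    images = np.empty((n_per_class * n_classes, s, s))
    labels = np.empty(n_per_class * n_classes, dtype=np.int64)
    i = 0
    for c in range(n_classes):
        for _ in range(n_per_class):
            img = np.full((s, s), 20.0)
            img[brain] = 110.0
            img += rng.normal(0.0, 12.0, (s, s))
            if c >= 1:
                p = _lesion_params(c)
                lx = cx + (p["center"][0] + rng.uniform(-p["jitter"], p["jitter"])) * s
                ly = cy + (p["center"][1] + rng.uniform(-p["jitter"], p["jitter"])) * s
                rx = rng.uniform(*p["radius"]) * s
                ry = rng.uniform(*p["radius"]) * s
                lesion = (((xx - lx) / rx) ** 2 + ((yy - ly) / ry) ** 2) <= 1.0
                img[lesion] += p["intensity"] + rng.normal(0.0, 8.0)
            images[i] = np.clip(img, 0.0, 255.0)
            labels[i] = c
            i += 1
    names = tuple(DEFAULT_CLASS_NAMES[:n_classes]) if n_classes <= 4 else \
        tuple(f"class_{c}" for c in range(n_classes))
    return LabeledImageSet(images, labels, names, value_range=(0.0, 255.0))


def load_image_folder(path: str, image_size: int = 32) -> LabeledImageSet:
    """Load a class-per-subdirectory image folder.

    Labels follow sorted subdirectory order; images are converted to
    grayscale and resized to ``image_size`` squared.
    """
    if not os.path.isdir(path):
        raise FileNotFoundError(f"image folder not found: {path}")
    class_dirs = sorted(d for d in os.listdir(path)
                        if os.path.isdir(os.path.join(path, d)))
    if not class_dirs:
        raise OSError(f"no class subdirectories in: {path}")
    images, labels = [], []
    for label, cname in enumerate(class_dirs):
        cdir = os.path.join(path, cname)
        files = sorted(f for f in os.listdir(cdir)
                       if f.lower().endswith((".png", ".jpg", ".jpeg")))
        if not files:
            raise OSError(f"no readable images in: {cdir}")
        for f in files:
            with Image.open(os.path.join(cdir, f)) as im:
                arr = np.asarray(
                    im.convert("L").resize((image_size, image_size),
                                           Image.BILINEAR), dtype=np.float64)
            images.append(arr)
            labels.append(label)
    return LabeledImageSet(np.stack(images), np.asarray(labels),
                           tuple(class_dirs), value_range=(0.0, 255.0))


def save_image_folder(data: LabeledImageSet, path: str) -> None:
    """Write a set back out in the class-per-subdirectory layout (PNG)."""
    for c, name in enumerate(data.class_names):
        cdir = os.path.join(path, name)
        os.makedirs(cdir, exist_ok=True)
        for j, idx in enumerate(np.flatnonzero(data.labels == c)):
            img = np.clip(data.images[idx], 0, 255).astype(np.uint8)
            Image.fromarray(img, mode="L").save(os.path.join(cdir, f"{j:05d}.png"))


def preprocess(data: LabeledImageSet, target_size: int | None = None) -> LabeledImageSet:
    """Resize and min-max normalize each image to [-1, 1].

    Normalization is per image: x' = 2 (x - min) / (max - min) - 1. A constant
    image maps to all zeros (the midpoint), which keeps the map total without
    a divide-by-zero.
    """
    if len(data) == 0:
        raise ValueError("cannot preprocess an empty image set")
    imgs = data.images
    if target_size is not None and target_size != data.image_size:
        resized = np.empty((len(data), target_size, target_size))
        for i, img in enumerate(imgs):
            pim = Image.fromarray(img.astype(np.float32), mode="F")
            resized[i] = np.asarray(
                pim.resize((target_size, target_size), Image.BILINEAR),
                dtype=np.float64)
        imgs = resized
    lo = imgs.min(axis=(1, 2), keepdims=True)
    hi = imgs.max(axis=(1, 2), keepdims=True)
    span = hi - lo
    out = np.where(span > 0, 2.0 * (imgs - lo) / np.where(span > 0, span, 1.0) - 1.0, 0.0)
    return replace(data, images=out, value_range=(-1.0, 1.0))


def partition(data: LabeledImageSet, k: int, seed: int = 0) -> PartitionPlan:
    """IID near-equal split of sample indices into ``k`` disjoint shards."""
    n = len(data)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return PartitionPlan(k=k, shard_indices=list(np.array_split(perm, k)))


def train_test_split_set(data: LabeledImageSet, test_fraction: float = 0.2,
                         seed: int = 0) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified train/test split of a labeled image set."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(data))
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=data.labels)
    return data.subset(np.sort(tr)), data.subset(np.sort(te))
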