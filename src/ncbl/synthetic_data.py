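"""Seeded synthetic labeled-image generator.

Produces small K-class image sets with the structural ingredients the bias
scenarios need: one smooth template per class, optional subclass ("breed")
structure inside a class, designated confusable class pairs that share
template structure, and injectable semi-transparent confound patches
("logos") at fixed positions.

Templates are low-frequency Gaussian random fields: white noise smoothed by
a Gaussian kernel, standardized, and mapped into pixel space around mid-grey.
This gives class structure a small dense network can learn while keeping
every draw reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "GeneratorConfig",
    "LabeledImageSet",
    "Logo",
    "generate_dataset",
    "inject_logo",
    "split_dataset",
    "save_dataset",
    "load_dataset",
    "load_cifar10_batches",
]

_SPLIT_TAGS = ("train", "val", "test")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic stimulus set.

    ``confusable_pairs`` lists class-id pairs whose templates share a common
    component with weight ``shared_weight`` (0 = independent, 1 = identical),
    emulating visually similar categories such as truck/automobile.
    """

    n_classes: int = 10
    n_subclasses_per_class: int = 1
    image_shape: tuple[int, int, int] = (12, 12, 3)
    n_per_class: int = 100
    noise_sd: float = 0.06
    noise_sd_jitter: float = 0.0
    confusable_pairs: tuple[tuple[int, int], ...] = ()
    shared_weight: float = 0.0
    global_weight: float = 0.0
    class_groups: tuple[tuple[int, ...], ...] = ()
    group_weight: float = 0.0
    template_amplitude: float = 0.25
    subclass_scale: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_subclasses_per_class < 1:
            raise ValueError("n_subclasses_per_class must be >= 1")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.noise_sd_jitter <= 1.0:
            raise ValueError("noise_sd_jitter must lie in [0, 1]")
        if not 0.0 <= self.shared_weight <= 1.0:
            raise ValueError("shared_weight must lie in [0, 1]")
        if not 0.0 <= self.global_weight < 1.0:
            raise ValueError("global_weight must lie in [0, 1)")
        if not 0.0 < self.template_amplitude <= 0.5:
            raise ValueError("template_amplitude must lie in (0, 0.5]")
        if self.subclass_scale < 0:
            raise ValueError("subclass_scale must be nonnegative")
        if len(self.image_shape) != 3 or any(s < 1 for s in self.image_shape):
            raise ValueError("image_shape must be (H, W, C) with positive entries")
        for a, b in self.confusable_pairs:
            if a == b:
                raise ValueError("confusable pair must name two distinct classes")
            if not (0 <= a < self.n_classes and 0 <= b < self.n_classes):
                raise ValueError("confusable pair class id out of range")
        if not 0.0 <= self.group_weight < 1.0:
            raise ValueError("group_weight must lie in [0, 1)")
        seen: set[int] = set()
        for grp in self.class_groups:
            for c in grp:
                if not 0 <= c < self.n_classes:
                    raise ValueError("class group member out of range")
                if c in seen:
                    raise ValueError("class groups must be disjoint")
                seen.add(c)


@dataclass(frozen=True)
class Logo:
    """A small patch blended into images at a fixed anchor.

    ``opacity`` is the alpha of the patch: 0 leaves the image untouched,
    1 replaces the footprint pixels outright.
    """

    patch: np.ndarray
    anchor: tuple[int, int]
    opacity: float

    def __post_init__(self) -> None:
        patch = np.asarray(self.patch, dtype=float)
        if patch.ndim != 3:
            raise ValueError("logo patch must be h x w x C")
        if patch.min() < 0.0 or patch.max() > 1.0:
            raise ValueError("logo patch values must lie in [0, 1]")
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError("opacity must lie in [0, 1]")
        object.__setattr__(self, "patch", patch)

    def footprint(self, image_shape: tuple[int, int, int]) -> tuple[slice, slice]:
        """Row/column slices the patch occupies; raises if out of bounds."""
        r, c = self.anchor
        h, w, _ = self.patch.shape
        H, W, C = image_shape
        if r < 0 or c < 0 or r + h > H or c + w > W:
            raise ValueError(
                f"logo of shape {(h, w)} at anchor {(r, c)} does not fit in "
                f"image of shape {(H, W)}"
            )
        if self.patch.shape[2] != C:
            raise ValueError("logo channel count does not match image")
        return slice(r, r + h), slice(c, c + w)


@dataclass
class LabeledImageSet:
    """Images with class labels; the stimulus set of every scenario.

    ``sublabels`` index subclasses globally (subclass ``s`` of class ``c``
    has id ``c * S + s``), so each subclass belongs to exactly one class.
    ``templates`` / ``subclass_templates`` hold the noise-free class and
    subclass means in pixel space when the set came from the generator.
    """

    images: np.ndarray
    labels: np.ndarray
    sublabels: np.ndarray | None = None
    split: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)
    templates: np.ndarray | None = None
    subclass_templates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 4:
            raise ValueError("images must be n x H x W x C")
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images and labels disagree on sample count")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")
        if self.labels.size and (self.labels.min() < 0):
            raise ValueError("labels must be nonnegative class ids")
        if not self.class_names:
            k = int(self.labels.max()) + 1 if self.labels.size else 0
            self.class_names = [f"class_{i}" for i in range(k)]
        if self.labels.size and self.labels.max() >= len(self.class_names):
            raise ValueError("label out of range of class_names")
        if self.sublabels is not None:
            self.sublabels = np.asarray(self.sublabels, dtype=int)
            if self.sublabels.shape[0] != self.labels.shape[0]:
                raise ValueError("sublabels length mismatch")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.shape[0] != self.labels.shape[0]:
                raise ValueError("split length mismatch")
            bad = set(self.split) - set(_SPLIT_TAGS)
            if bad:
                raise ValueError(f"unknown split tags: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return tuple(self.images.shape[1:])  # type: ignore[return-value]

    def subset(self, mask: np.ndarray) -> "LabeledImageSet":
        """New set restricted to ``mask`` (boolean or index array)."""
        return LabeledImageSet(
            images=self.images[mask],
            labels=self.labels[mask],
            sublabels=None if self.sublabels is None else self.sublabels[mask],
            split=None if self.split is None else self.split[mask],
            class_names=list(self.class_names),
            templates=self.templates,
            subclass_templates=self.subclass_templates,
        )

    def split_subset(self, tag: str) -> "LabeledImageSet":
        if self.split is None:
            raise ValueError("dataset has no split tags; call split_dataset first")
        if tag not in _SPLIT_TAGS:
            raise ValueError(f"unknown split tag {tag!r}")
        return self.subset(self.split == tag)

    def flattened(self) -> np.ndarray:
        """Images as an (n, H*W*C) matrix, row-major, channels last."""
        return self.images.reshape(self.n_samples, -1)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int, int]) -> np.ndarray:
    """Standardized low-frequency random field, one per channel."""
    H, W, C = shape
    sigma = max(min(H, W) / 6.0, 1.0)
    field_ = gaussian_filter(
        rng.standard_normal((H, W, C)), sigma=(sigma, sigma, 0.0), mode="wrap"
    )
    field_ -= field_.mean()
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    return field_


def generate_dataset(config: GeneratorConfig) -> LabeledImageSet:
    """Draw a seeded labeled image set from per-class smooth templates.

    Per class ``c`` a smooth field ``F_c`` is drawn; members of a confusable
    pair are mixed with a pair-shared field using ``shared_weight``.  Each
    subclass adds a smaller smooth perturbation.  A sample of subclass ``s``
    is ``clip(template_s + N(0, noise_sd^2), 0, 1)``.  Identical config
    (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    K, S = config.n_classes, config.n_subclasses_per_class
    shape = config.image_shape

    fields = np.stack([_smooth_field(rng, shape) for _ in range(K)])
    if config.global_weight > 0.0:
        # structure shared by every class, as natural-image statistics are
        g = config.global_weight
        fields = (1.0 - g) * fields + g * _smooth_field(rng, shape)
    for grp in config.class_groups:
        # superclass structure (e.g. animals vs vehicles): members of a
        # group share one group-level field
        bw = config.group_weight
        if bw > 0.0:
            group_field = _smooth_field(rng, shape)
            for c in grp:
                fields[c] = (1.0 - bw) * fields[c] + bw * group_field
    for a, b in config.confusable_pairs:
        shared = _smooth_field(rng, shape)
        w = config.shared_weight
        fields[a] = (1.0 - w) * fields[a] + w * shared
        fields[b] = (1.0 - w) * fields[b] + w * shared

    # with a single subclass per class the subclass IS the class template
    if S == 1:
        sub_fields = np.zeros((K, 1, *shape))
    else:
        sub_fields = np.stack(
            [
                np.stack(
                    [config.subclass_scale * _smooth_field(rng, shape) for _ in range(S)]
                )
                for _ in range(K)
            ]
        )  # (K, S, H, W, C)

    amp = config.template_amplitude
    class_templates = np.clip(0.5 + amp * fields, 0.0, 1.0)
    subclass_templates = np.clip(
        0.5 + amp * (fields[:, None] + sub_fields), 0.0, 1.0
    )

    n = K * config.n_per_class
    images = np.empty((n, *shape), dtype=float)
    labels = np.empty(n, dtype=int)
    sublabels = np.empty(n, dtype=int)
    i = 0
    for c in range(K):
        for j in range(config.n_per_class):
            s = j % S  # cycle subclasses uniformly within a class
            base = subclass_templates[c, s]
            sd = config.noise_sd
            if config.noise_sd_jitter > 0.0:
                # per-sample difficulty: image quality varies across trials
                sd *= 1.0 + config.noise_sd_jitter * rng.uniform(-1.0, 1.0)
            noise = rng.normal(0.0, sd, size=shape) if sd else 0.0
            images[i] = np.clip(base + noise, 0.0, 1.0)
            labels[i] = c
            sublabels[i] = c * S + s
            i += 1

    return LabeledImageSet(
        images=images,
        labels=labels,
        sublabels=sublabels,
        class_names=[f"class_{c}" for c in range(K)],
        templates=class_templates,
        subclass_templates=subclass_templates,
    )


def inject_logo(
    data: LabeledImageSet,
    target_classes: Sequence[int],
    logos: Sequence[Logo],
) -> LabeledImageSet:
    """Alpha-blend one logo per targeted class into every sample of that class.

    Footprint pixels become ``(1 - opacity) * image + opacity * patch``; all
    other pixels, and all samples of non-targeted classes, are bit-unchanged.
    """
    if len(target_classes) != len(logos):
        raise ValueError("need exactly one logo per targeted class")
    if len(set(target_classes)) != len(target_classes):
        raise ValueError("duplicate target class")
    for c in target_classes:
        if not 0 <= c < data.n_classes:
            raise ValueError(f"target class {c} out of range")

    images = data.images.copy()
    for c, logo in zip(target_classes, logos):
        rows, cols = logo.footprint(data.image_shape)
        mask = data.labels == c
        a = logo.opacity
        images[mask, rows, cols, :] = (
            (1.0 - a) * images[mask, rows, cols, :] + a * logo.patch
        )
    out = replace_images(data, images)
    return out


def replace_images(data: LabeledImageSet, images: np.ndarray) -> LabeledImageSet:
    """Copy of ``data`` with a new image array (labels and tags preserved)."""
    return LabeledImageSet(
        images=images,
        labels=data.labels.copy(),
        sublabels=None if data.sublabels is None else data.sublabels.copy(),
        split=None if data.split is None else data.split.copy(),
        class_names=list(data.class_names),
        templates=data.templates,
        subclass_templates=data.subclass_templates,
    )


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of n items to fractions, summing exactly to n."""
    exact = [f * n for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_dataset(
    data: LabeledImageSet,
    fractions: tuple[float, float, float],
    seed: int,
) -> LabeledImageSet:
    """Assign train/val/test tags by a seeded stratified shuffle per class.

    Within each class the tag counts follow ``fractions`` under
    largest-remainder rounding, so they sum exactly to the class size.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    rng = np.random.default_rng(seed)
    split = np.empty(data.n_samples, dtype=object)
    for c in np.unique(data.labels):
        idx = np.flatnonzero(data.labels == c)
        idx = idx[rng.permutation(len(idx))]
        counts = _largest_remainder_counts(len(idx), fractions)
        start = 0
        for tag, cnt in zip(_SPLIT_TAGS, counts):
            split[idx[start : start + cnt]] = tag
            start += cnt
    out = replace_images(data, data.images.copy())
    out.split = split
    return out


# ---------------------------------------------------------------------------
# disk I/O: PNG directory + CSV manifest, with a lossless float sidecar


def save_dataset(data: LabeledImageSet, directory: str | Path) -> None:
    """Write PNGs plus ``manifest.csv`` and a lossless ``images.npz``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(data.n_samples):
        fname = f"img_{i:06d}.png"
        arr = np.clip(np.round(data.images[i] * 255), 0, 255).astype(np.uint8)
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        Image.fromarray(arr).save(directory / fname)
        rows.append(
            {
                "filename": fname,
                "label": int(data.labels[i]),
                "sublabel": int(data.sublabels[i]) if data.sublabels is not None else "",
                "split": data.split[i] if data.split is not None else "",
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    np.savez_compressed(directory / "images.npz", images=data.images)
    (directory / "meta.json").write_text(
        json.dumps({"class_names": data.class_names})
    )


def load_dataset(directory: str | Path) -> LabeledImageSet:
    """Read a dataset written by :func:`save_dataset` (float sidecar wins)."""
    import pandas as pd

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv", keep_default_na=False)
    images = np.load(directory / "images.npz")["images"]
    meta = json.loads((directory / "meta.json").read_text())
    sublabels = None
    if (manifest["sublabel"].astype(str) != "").all():
        sublabels = manifest["sublabel"].astype(int).to_numpy()
    split = None
    if (manifest["split"].astype(str) != "").all():
        split = manifest["split"].astype(str).to_numpy()
    return LabeledImageSet(
        images=images,
        labels=manifest["label"].to_numpy(),
        sublabels=sublabels,
        split=split,
        class_names=meta["class_names"],
    )


def load_cifar10_batches(directory: str | Path) -> LabeledImageSet:
    """Optional reader for the standard pickled CIFAR-10 python batches.

    Expects ``data_batch_1..5`` and ``test_batch`` under ``directory``.
    Never required by the test suite; provided so the full-scale runs can be
    reproduced when the archive is available locally.
    """
    import pickle

    directory = Path(directory)
    names = [f"data_batch_{i}" for i in range(1, 6)] + ["test_batch"]
    images, labels, split = [], [], []
    for name in names:
        path = directory / name
        if not path.exists():
            raise FileNotFoundError(f"missing CIFAR-10 batch: {path}")
        with open(path, "rb") as fh:
            batch = pickle.load(fh, encoding="bytes")
        x = batch[b"data"].reshape(-1, 3, 32, 32).transpose(0, 2, 3, 1) / 255.0
        images.append(x)
        labels.extend(batch[b"labels"])
        split.extend(["test" if name == "test_batch" else "train"] * len(x))
    class_names = [
        "airplane", "automobile", "bird", "cat", "deer",
        "dog", "frog", "horse", "ship", "truck",
    ]
    return LabeledImageSet(
        images=np.concatenate(images),
        labels=np.asarray(labels),
        split=np.asarray(split, dtype=object),
        class_names=class_names,
    )
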