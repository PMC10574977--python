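"""Image datasets, manifests, synthetic fixtures and split protocols.

A dataset is a CSV manifest (``id,path,label,split``) plus image files on
disk. Labels are binary: 0 = negative (majority in the imbalanced regimes
this package targets), 1 = positive (minority). Splits are tagged
``train``/``val``/``test``.

The synthetic generator emulates a small, heavily imbalanced two-class
grayscale dataset in the style of chest-radiograph screening collections:
negatives are pure noise fields, positives additionally carry one soft
bright Gaussian blob at a random location — a controllable, localisable
class signal that downstream class-activation maps can be checked against.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ImageRecord",
    "ImageDataset",
    "SyntheticSpec",
    "ManifestFormatError",
    "DatasetValidationError",
    "generate_synthetic_dataset",
    "read_manifest",
    "write_manifest",
    "load_images",
    "balanced_validation_split",
    "kfold_splits",
]

MANIFEST_COLUMNS = ("id", "path", "label", "split")
VALID_SPLITS = ("train", "val", "test")


class ManifestFormatError(ValueError):
    """Manifest CSV does not have the required structure."""


class DatasetValidationError(ValueError):
    """Manifest contents violate a dataset invariant."""


@dataclass(frozen=True)
class ImageRecord:
    id: str
    path: str
    label: int
    split: str

    def __post_init__(self):
        if self.label not in (0, 1):
            raise DatasetValidationError(f"label must be 0 or 1, got {self.label!r}")
        if self.split not in VALID_SPLITS:
            raise DatasetValidationError(
                f"split must be one of {VALID_SPLITS}, got {self.split!r}"
            )


@dataclass
class ImageDataset:
    """Ordered collection of labeled image records.

    ``root`` is the directory against which relative record paths resolve
    (normally the manifest's directory).
    """

    records: list[ImageRecord]
    image_side: int = 32
    root: Path | None = None

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DatasetValidationError("duplicate record ids in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "ImageDataset":
        recs = [r for r in self.records if r.split == split]
        return ImageDataset(recs, image_side=self.image_side, root=self.root)

    def counts(self, split: str | None = None) -> tuple[int, int]:
        """(n_neg, n_pos), optionally restricted to one split."""
        recs = self.records if split is None else [r for r in self.records if r.split == split]
        n_pos = sum(r.label for r in recs)
        return len(recs) - n_pos, n_pos

    def labels(self, split: str | None = None) -> np.ndarray:
        recs = self.records if split is None else [r for r in self.records if r.split == split]
        return np.array([r.label for r in recs], dtype=int)

    def resolve(self, record: ImageRecord) -> Path:
        p = Path(record.path)
        if not p.is_absolute() and self.root is not None:
            p = Path(self.root) / p
        return p

    def load(self, split: str | None = None, n_channels: int = 1) -> np.ndarray:
        recs = self.records if split is None else [r for r in self.records if r.split == split]
        return load_images([self.resolve(r) for r in recs], self.image_side, n_channels)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic imbalanced fixture.

    ``signal_amplitude`` scales the additive Gaussian-profile bright blob
    present only in positives; at 0 the two classes are statistically
    indistinguishable by construction. ``noise_sd`` is the per-pixel
    Gaussian noise standard deviation around a flat background.
    ``test_fraction`` carves a per-class stratified test split.
    """

    n_neg: int
    n_pos: int
    image_side: int = 32
    signal_amplitude: float = 0.4
    noise_sd: float = 0.15
    blob_radius_range: tuple[float, float] = (4.0, 8.0)
    seed: int = 0
    test_fraction: float = 0.0
    n_neg_test: int = 0
    n_pos_test: int = 0
    background: float = 0.35

    def __post_init__(self):
        if min(self.n_neg, self.n_pos, self.n_neg_test, self.n_pos_test) < 0:
            raise ValueError("class counts must be non-negative")
        if self.test_fraction > 0 and (self.n_neg_test or self.n_pos_test):
            raise ValueError(
                "give either test_fraction or explicit test counts, not both"
            )
        if self.n_neg + self.n_pos == 0:
            raise ValueError("empty dataset: n_neg + n_pos must be positive")
        if self.signal_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("signal_amplitude and noise_sd must be non-negative")
        lo, hi = self.blob_radius_range
        if not (0 < lo <= hi):
            raise ValueError("blob_radius_range must satisfy 0 < min <= max")
        if not (0.0 <= self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in [0, 1)")


def _blob(side: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * radius**2)))


def generate_synthetic_dataset(spec: SyntheticSpec, out_dir) -> ImageDataset:
    """Write a reproducible synthetic dataset under ``out_dir``.

    Produces 8-bit grayscale PNGs in ``out_dir/images``, a manifest
    ``manifest.csv`` and, for positives, a sidecar ``blobs.json`` recording
    the planted blob geometry (used by localisation checks, not by models).
    Bitwise deterministic given ``spec`` (including its seed).
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side

    records: list[ImageRecord] = []
    blobs: dict[str, dict] = {}
    lo, hi = spec.blob_radius_range
    plan = [
        ("neg", 0, i, "train" if i < spec.n_neg else "test")
        for i in range(spec.n_neg + spec.n_neg_test)
    ] + [
        ("pos", 1, i, "train" if i < spec.n_pos else "test")
        for i in range(spec.n_pos + spec.n_pos_test)
    ]
    for prefix, label, i, split in plan:
        rid = f"{prefix}-{i:05d}"
        img = spec.background + rng.normal(0.0, spec.noise_sd, size=(side, side))
        if label == 1:
            radius = rng.uniform(lo, min(hi, side / 2.0))
            margin = radius
            cx = rng.uniform(margin, side - margin)
            cy = rng.uniform(margin, side - margin)
            img += spec.signal_amplitude * _blob(side, cx, cy, radius)
            blobs[rid] = {"cx": cx, "cy": cy, "radius": radius}
        img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        rel = f"images/{rid}.png"
        Image.fromarray(img8, mode="L").save(out_dir / rel)
        records.append(ImageRecord(rid, rel, label, split))

    if spec.test_fraction > 0:
        records = _assign_test_split(records, spec.test_fraction, rng)

    ds = ImageDataset(records, image_side=side, root=out_dir)
    write_manifest(ds, out_dir / "manifest.csv")
    (out_dir / "blobs.json").write_text(json.dumps(blobs, indent=1, sort_keys=True))
    return ds


def _assign_test_split(records, fraction, rng) -> list[ImageRecord]:
    out = list(records)
    for label in (0, 1):
        idx = [i for i, r in enumerate(out) if r.label == label]
        n_test = int(round(fraction * len(idx)))
        chosen = rng.choice(len(idx), size=n_test, replace=False) if n_test else []
        for j in chosen:
            out[idx[j]] = replace(out[idx[j]], split="test")
    return out


# --------------------------------------------------------------------------
# Manifest I/O


def read_manifest(path, image_side: int = 32, strict: bool = False) -> ImageDataset:
    """Read a manifest CSV. Relative image paths resolve against its folder.

    ``strict`` additionally verifies that every image file exists.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "path": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"manifest missing column(s) {missing}")
    if not df["label"].isin([0, 1]).all():
        bad = sorted(set(df["label"]) - {0, 1})
        raise DatasetValidationError(f"labels outside {{0,1}}: {bad}")
    records = [
        ImageRecord(str(r.id), str(r.path), int(r.label), str(r.split))
        for r in df.itertuples(index=False)
    ]
    ds = ImageDataset(records, image_side=image_side, root=path.parent)
    if strict:
        for r in records:
            if not ds.resolve(r).exists():
                raise DatasetValidationError(f"image not found: {r.path}")
    return ds


def write_manifest(dataset: ImageDataset, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [(r.id, r.path, r.label, r.split) for r in dataset.records],
        columns=list(MANIFEST_COLUMNS),
    )
    df.to_csv(path, index=False)
    return path


def load_images(paths, image_side: int, n_channels: int = 1) -> np.ndarray:
    """Load images to float64 in [0, 1], shape (n, n_channels, side, side).

    Grayscale conversion, bilinear resize to the working side, channel
    replication if the backbone expects more than one channel.
    """
    out = np.empty((len(paths), n_channels, image_side, image_side))
    for i, p in enumerate(paths):
        with Image.open(p) as im:
            im = im.convert("L")
            if im.size != (image_side, image_side):
                im = im.resize((image_side, image_side), Image.BILINEAR)
            arr = np.asarray(im, dtype=float) / 255.0
        out[i] = arr[None, :, :]
    return out


# --------------------------------------------------------------------------
# Split protocols


def balanced_validation_split(
    dataset: ImageDataset, fraction: float, seed: int
) -> tuple[ImageDataset, ImageDataset]:
    """Carve a class-balanced validation set out of the train split.

    The validation size is ``round(fraction * n_train)``; each class
    contributes ``val_size // 2`` members, and an odd leftover slot goes to
    the majority class so scarce positives stay in training. If a class has
    fewer members than its quota, all of them go to validation (with a
    warning). Remaining records keep the ``train`` tag; sampled ones are
    re-tagged ``val``. Sampling is uniform without replacement, seeded.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    train = [r for r in dataset.records if r.split == "train"]
    labels = np.array([r.label for r in train])
    n_neg, n_pos = int((labels == 0).sum()), int((labels == 1).sum())
    if n_neg == 0 or n_pos == 0:
        raise DatasetValidationError("train split must contain both classes")
    val_size = int(round(fraction * len(train)))
    quota = {0: val_size // 2, 1: val_size // 2}
    if val_size % 2 == 1:
        quota[0 if n_neg >= n_pos else 1] += 1
    rng = np.random.default_rng(seed)
    val_idx: set[int] = set()
    for label in (0, 1):
        pool = [i for i, r in enumerate(train) if r.label == label]
        take = quota[label]
        if take > len(pool):
            warnings.warn(
                f"class {label} has only {len(pool)} train members; "
                f"taking all of them into validation (quota was {take})",
                stacklevel=2,
            )
            take = len(pool)
        val_idx.update(rng.choice(pool, size=take, replace=False).tolist())
    val_recs = [replace(train[i], split="val") for i in sorted(val_idx)]
    train_recs = [r for i, r in enumerate(train) if i not in val_idx]
    mk = lambda recs: ImageDataset(recs, image_side=dataset.image_side, root=dataset.root)
    return mk(train_recs), mk(val_recs)


def kfold_splits(
    dataset: ImageDataset, k: int, seed: int
) -> list[tuple[ImageDataset, ImageDataset]]:
    """Class-stratified k-fold partition of the dataset's records.

    Validation folds are pairwise disjoint and jointly exhaustive, and
    per-fold positive counts differ by at most one. Each returned pair
    re-tags its records ``train``/``val``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    recs = dataset.records
    y = np.array([r.label for r in recs])
    for label in (0, 1):
        if (y == label).sum() < k:
            raise DatasetValidationError(
                f"class {label} has fewer than k={k} members"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    out = []
    for tr_idx, va_idx in skf.split(np.zeros(len(recs)), y):
        tr = [replace(recs[i], split="train") for i in tr_idx]
        va = [replace(recs[i], split="val") for i in va_idx]
        out.append(
            (
                ImageDataset(tr, image_side=dataset.image_side, root=dataset.root),
                ImageDataset(va, image_side=dataset.image_side, root=dataset.root),
            )
        )
    return out
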