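"""Input loading, preprocessing and partitioning.

Reads image directories (one subdirectory per class) or delimited feature
tables, converts images to flat normalized feature vectors, produces
stratified train/test splits, and fits/applies per-feature standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}

#: floor for per-feature standard deviations; constant columns map to 0
STD_EPSILON = 1e-12


@dataclass
class RawImageSet:
    """A stack of same-sized grayscale images with integer class labels."""

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    source_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        n_classes = len(self.class_names)
        if n_classes < 2:
            raise ValueError("no classes found: need at least 2 classes")
        if len(self.images) > 0:
            shapes = {im.shape for im in self.images}
            if len(shapes) != 1:
                raise ValueError(f"images have inconsistent shapes: {shapes}")
            if self.labels.min() < 0 or self.labels.max() >= n_classes:
                raise ValueError("labels must lie in [0, n_classes - 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class Dataset:
    """Feature matrix ``X`` (N x M) with integer labels ``y`` (length N)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)


@dataclass
class StandardizationModel:
    """Per-feature location/scale fitted on training rows only.

    Uses the population SD convention (``ddof=0``); standard deviations are
    floored at :data:`STD_EPSILON` so constant columns standardize to zero.
    """

    mean: np.ndarray
    std: np.ndarray


def _iter_image_files(class_dir: Path) -> list[Path]:
    return sorted(
        p for p in class_dir.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )


def load_image_dataset(root_dir: str | Path, image_size: tuple[int, int]) -> RawImageSet:
    """Load a ``root/<class>/*.png`` directory layout into a :class:`RawImageSet`.

    Class ids follow lexicographic subdirectory order. Color images are
    converted to grayscale by ITU-R 601 luminance; all images are resized to
    ``image_size`` (height, width) with bilinear interpolation. Undecodable
    files are skipped with a warning; a class with no decodable image is an
    error.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) < 2:
        raise ValueError("no classes found: need >= 2 class subdirectories")

    height, width = image_size
    images: list[np.ndarray] = []
    labels: list[int] = []
    paths: list[str] = []
    class_names = [d.name for d in class_dirs]
    for class_id, class_dir in enumerate(class_dirs):
        n_loaded = 0
        for fp in _iter_image_files(class_dir):
            try:
                with Image.open(fp) as im:
                    gray = im.convert("L")  # ITU-R 601 luminance
                    resized = gray.resize((width, height), Image.BILINEAR)
                    arr = np.asarray(resized, dtype=np.uint8)
            except Exception as exc:  # undecodable file: skip, keep going
                logger.warning("skipping undecodable image %s: %s", fp, exc)
                continue
            images.append(arr)
            labels.append(class_id)
            paths.append(str(fp))
            n_loaded += 1
        if n_loaded == 0:
            raise ValueError(f"class {class_dir.name!r} has no decodable images")
    return RawImageSet(
        images=images,
        labels=np.asarray(labels),
        class_names=class_names,
        source_paths=paths,
    )


def to_feature_dataset(raw: RawImageSet) -> Dataset:
    """Normalize each image to [0, 1] and flatten row-major into feature rows.

    Integer images are divided by their dtype maximum; floating images are
    assumed to already lie in [0, 1].
    """
    rows = []
    for im in raw.images:
        arr = np.asarray(im)
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite pixels")
        if np.issubdtype(arr.dtype, np.integer):
            scale = float(np.iinfo(arr.dtype).max)
            row = arr.astype(np.float64).ravel() / scale
        else:
            row = arr.astype(np.float64).ravel()
        rows.append(row)
    X = np.vstack(rows)
    height, width = raw.images[0].shape
    names = [f"px_{r:03d}_{c:03d}" for r in range(height) for c in range(width)]
    return Dataset(X=X, y=raw.labels.copy(), feature_names=names,
                   class_names=list(raw.class_names))


def stratified_split(
    ds: Dataset, test_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Deterministic per-class split: round(n_c * test_fraction) test samples."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    counts = ds.class_counts()
    for c, n_c in enumerate(counts):
        if n_c < 2:
            name = ds.class_names[c] if c < len(ds.class_names) else str(c)
            raise ValueError(
                f"class {name!r} has {n_c} sample(s); need >= 2 to split"
            )
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in range(ds.n_classes):
        members = np.flatnonzero(ds.y == c)
        perm = rng.permutation(members)
        n_test = int(round(len(members) * test_fraction))
        n_test = min(max(n_test, 1), len(members) - 1)  # both sides nonempty
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    train_rows = np.sort(np.concatenate(train_idx))
    test_rows = np.sort(np.concatenate(test_idx))

    def subset(rows: np.ndarray) -> Dataset:
        return Dataset(
            X=ds.X[rows],
            y=ds.y[rows],
            feature_names=list(ds.feature_names),
            class_names=list(ds.class_names),
        )

    return subset(train_rows), subset(test_rows)


def fit_standardizer(train: Dataset) -> StandardizationModel:
    """Fit per-feature mean and population SD on training rows only."""
    if train.n_samples == 0:
        raise ValueError("cannot fit standardizer on an empty dataset")
    mean = train.X.mean(axis=0)
    std = train.X.std(axis=0, ddof=0)
    std = np.maximum(std, STD_EPSILON)
    return StandardizationModel(mean=mean, std=std)


def apply_standardizer(model: StandardizationModel, ds: Dataset) -> Dataset:
    if ds.n_features != model.mean.shape[0]:
        raise ValueError("feature count does not match the fitted model")
    X = (ds.X - model.mean) / model.std
    return Dataset(X=X, y=ds.y.copy(), feature_names=list(ds.feature_names),
                   class_names=list(ds.class_names))


def load_feature_table(
    path: str | Path, label_column: str = "label", delimiter: str = ","
) -> Dataset:
    """Read a delimited table with a header, one label column, numeric features.

    String labels are mapped to class ids in lexicographic order; integer
    labels are used as-is (class names are the stringified sorted values).
    """
    df = pd.read_csv(path, delimiter=delimiter)
    if label_column not in df.columns:
        raise ValueError(f"table has no {label_column!r} column")
    labels_raw = df[label_column]
    features = df.drop(columns=[label_column])
    uniques = sorted(labels_raw.unique(), key=str)
    if pd.api.types.is_integer_dtype(labels_raw):
        uniques = sorted(labels_raw.unique())
    mapping = {v: i for i, v in enumerate(uniques)}
    y = labels_raw.map(mapping).to_numpy()
    return Dataset(
        X=features.to_numpy(dtype=np.float64),
        y=y,
        feature_names=[str(c) for c in features.columns],
        class_names=[str(v) for v in uniques],
    )


def save_feature_table(
    ds: Dataset, path: str | Path, label_column: str = "label", delimiter: str = ","
) -> None:
    """Write a :class:`Dataset` back to the delimited-table format."""
    df = pd.DataFrame(ds.X, columns=ds.feature_names)
    df[label_column] = [ds.class_names[c] for c in ds.y]
    df.to_csv(path, sep=delimiter, index=False)


def save_matrix(
    Z: np.ndarray, path: str | Path, column_names: Sequence[str], delimiter: str = "\t"
) -> None:
    pd.DataFrame(Z, columns=list(column_names)).to_csv(path, sep=delimiter, index=False)


def load_matrix(path: str | Path, delimiter: str = "\t") -> np.ndarray:
    return pd.read_csv(path, delimiter=delimiter).to_numpy(dtype=np.float64)
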