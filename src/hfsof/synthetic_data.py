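"""Synthetic inputs for desk-scale testing: ultrasound-like phantom images
and feature tables with planted informative columns.

Phantoms combine a class-specific background level, a class-specific bright
horizontal band, a small number of elliptical lesions, multiplicative
Rayleigh speckle (unit mean) and additive Gaussian noise. Planted-feature
tables place class-dependent means (spaced ``delta`` standard deviations
apart) in ``k`` recorded columns and pure noise elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from hfsof.preprocess_io import Dataset, RawImageSet

#: scale making the Rayleigh speckle factor have unit mean
RAYLEIGH_UNIT_MEAN_SCALE = 1.0 / math.sqrt(math.pi / 2.0)

#: per-class supports mimicking a strongly imbalanced 6-class study at 1/10 scale
DEFAULT_PHANTOM_COUNTS = (118, 66, 24, 139, 74, 346)


@dataclass
class PhantomSpec:
    class_counts: tuple[int, ...] = DEFAULT_PHANTOM_COUNTS
    image_size: tuple[int, int] = (32, 32)
    background_levels: tuple[float, ...] | None = None
    band_centers: tuple[float, ...] | None = None  # fractional row positions
    band_contrast: float = 0.45
    max_lesions: int = 3
    lesion_contrast: float = 0.25
    speckle_sigma: float = 1.0  # 0 disables speckle, 1 = full Rayleigh factor
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.class_counts):
            raise ValueError("class counts must be >= 1")
        if self.image_size[0] < 16 or self.image_size[1] < 16:
            raise ValueError("image size must be >= 16x16")
        n_classes = len(self.class_counts)
        if self.background_levels is None:
            # distinct, well-spaced intensity levels per class
            self.background_levels = tuple(
                0.15 + 0.6 * c / max(n_classes - 1, 1) for c in range(n_classes)
            )
        if self.band_centers is None:
            self.band_centers = tuple(
                (c + 0.5) / n_classes for c in range(n_classes)
            )
        if len(self.background_levels) != n_classes:
            raise ValueError("background_levels length must match class count")
        if len(self.band_centers) != n_classes:
            raise ValueError("band_centers length must match class count")

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)


@dataclass
class PlantedFeatureSpec:
    n_samples: int = 300
    n_features: int = 50
    n_informative: int = 5
    delta: float = 3.0
    n_classes: int = 4
    class_ratios: tuple[float, ...] | None = None
    structure: str = "ovr"  # "ovr": one class shifted per column; "ladder": means 0, d, 2d, ...
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative >= self.n_features:
            raise ValueError("need n_informative < n_features")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.structure not in ("ovr", "ladder"):
            raise ValueError("structure must be 'ovr' or 'ladder'")
        if self.class_ratios is None:
            self.class_ratios = tuple(1.0 / self.n_classes for _ in range(self.n_classes))
        if len(self.class_ratios) != self.n_classes:
            raise ValueError("class_ratios length must match n_classes")


def _allocate_counts(n: int, ratios: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder apportionment of n samples to the given ratios."""
    ratios_arr = np.asarray(ratios, dtype=np.float64)
    ratios_arr = ratios_arr / ratios_arr.sum()
    raw = ratios_arr * n
    counts = np.floor(raw).astype(np.int64)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    counts[counts == 0] = 1
    while counts.sum() > n:
        counts[int(np.argmax(counts))] -= 1
    return counts


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]
) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    cy, cx = center
    ay, ax = axes
    return ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2 <= 1.0


def generate_phantoms(spec: PhantomSpec) -> RawImageSet:
    """Deterministic per-seed ultrasound-like phantom image set."""
    rng = np.random.default_rng(spec.seed)
    height, width = spec.image_size
    images: list[np.ndarray] = []
    labels: list[int] = []
    for class_id, count in enumerate(spec.class_counts):
        level = spec.background_levels[class_id]
        band_row = spec.band_centers[class_id] * height
        band_halfwidth = max(height / 10.0, 1.5)
        rows = np.arange(height, dtype=np.float64)
        band_profile = np.exp(-0.5 * ((rows - band_row) / band_halfwidth) ** 2)
        for _ in range(count):
            img = np.full((height, width), level, dtype=np.float64)
            img += spec.band_contrast * band_profile[:, None]
            n_lesions = int(rng.integers(0, spec.max_lesions + 1))
            for _ in range(n_lesions):
                cy = rng.uniform(0.2 * height, 0.8 * height)
                cx = rng.uniform(0.2 * width, 0.8 * width)
                ay = rng.uniform(0.06, 0.16) * height * (1.0 + 0.3 * class_id / spec.n_classes)
                ax = rng.uniform(0.06, 0.16) * width
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                img[_ellipse_mask((height, width), (cy, cx), (ay, ax))] += (
                    sign * spec.lesion_contrast * rng.uniform(0.5, 1.0)
                )
            if spec.speckle_sigma > 0:
                factor = rng.rayleigh(
                    scale=RAYLEIGH_UNIT_MEAN_SCALE, size=(height, width)
                )
                img = img * (1.0 + spec.speckle_sigma * (factor - 1.0))
            img += rng.normal(0.0, spec.noise_sigma, size=(height, width))
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(class_id)
    class_names = [f"class_{c}" for c in range(spec.n_classes)]
    return RawImageSet(
        images=images, labels=np.asarray(labels), class_names=class_names
    )


def generate_planted_features(spec: PlantedFeatureSpec) -> tuple[Dataset, np.ndarray]:
    """Feature table with k informative columns; returns ground-truth indices.

    Informative columns are N(mu_c, 1) with class means ``delta`` SD units
    apart; the rest are N(0, 1) independent of the label. Under the default
    ``"ovr"`` structure the i-th planted column shifts one class (cycling
    through the classes) by ``delta``, making the planted columns
    complementary — no small subset of them is individually sufficient, so
    subset-recovery tests exercise joint selection. The ``"ladder"``
    structure places class means at 0, delta, 2*delta, ... (class order
    permuted per column).
    """
    rng = np.random.default_rng(spec.seed)
    counts = _allocate_counts(spec.n_samples, spec.class_ratios)
    y = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(y)
    X = rng.normal(0.0, 1.0, size=(spec.n_samples, spec.n_features))
    informative = np.sort(
        rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    )
    for i, j in enumerate(informative):
        if spec.structure == "ovr":
            target = i % spec.n_classes
            means = np.where(np.arange(spec.n_classes) == target, spec.delta, 0.0)
        else:
            class_order = rng.permutation(spec.n_classes)
            means = class_order * spec.delta
        X[:, j] += means[y]
    names = [f"f_{j:03d}" for j in range(spec.n_features)]
    class_names = [f"class_{c}" for c in range(spec.n_classes)]
    ds = Dataset(X=X, y=y, feature_names=names, class_names=class_names)
    return ds, informative
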