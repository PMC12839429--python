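import numpy as np
import pytest
from PIL import Image

from hfsof.preprocess_io import Dataset
from hfsof.synthetic_data import PlantedFeatureSpec, generate_planted_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_small():
    """Tiny planted-feature dataset: n=120, d=10, k=2, C=3."""
    spec = PlantedFeatureSpec(
        n_samples=120, n_features=10, n_informative=2, delta=3.0,
        n_classes=3, seed=7,
    )
    return generate_planted_features(spec)


@pytest.fixture
def two_class_dataset(rng):
    """Linearly separable two-class toy set with a wide margin."""
    n = 60
    X = rng.normal(0.0, 0.3, size=(n, 4))
    y = np.repeat([0, 1], n // 2)
    X[y == 1, 0] += 8.0
    X[y == 1, 1] -= 8.0
    return Dataset(
        X=X, y=y,
        feature_names=[f"f{j}" for j in range(4)],
        class_names=["neg", "pos"],
    )


@pytest.fixture
def image_dir(tmp_path):
    """root/<class>/*.png layout: class a has 3 images, class b has 2."""
    rng = np.random.default_rng(0)
    for name, count in (("a", 3), ("b", 2)):
        d = tmp_path / "imgs" / name
        d.mkdir(parents=True)
        for i in range(count):
            arr = rng.integers(0, 256, size=(12, 10), dtype=np.uint8)
            Image.fromarray(arr, mode="L").save(d / f"im{i}.png")
    return tmp_path / "imgs"
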