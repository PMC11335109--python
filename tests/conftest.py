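import numpy as np
import pandas as pd
import pytest

from dyadlink import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(n_dyads=379, seed=0)


@pytest.fixture(scope="session")
def dataset379(default_config) -> pd.DataFrame:
    """One study-sized synthetic dataset shared across read-only tests."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def big_dataset() -> pd.DataFrame:
    """n=5000 draw used for moment-recovery checks."""
    return generate_dataset(GeneratorConfig(n_dyads=5000, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blobs300():
    """Three well-separated Gaussian blobs in the unit square (n=300)."""
    r = np.random.default_rng(7)
    centers = np.array([[0.15, 0.2], [0.5, 0.8], [0.85, 0.25]])
    labels = np.repeat([0, 1, 2], 100)
    X = centers[labels] + 0.02 * r.standard_normal((300, 2))
    return X, labels
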