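import numpy as np
import pytest

from grasspix.labelling import PixelDataset
from grasspix.synthetic import generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def scene():
    """One default-prototype synthetic scene shared across tests."""
    return generate_scene(96, 96, seed=7)


def make_separable_dataset(n_per_class=120, seed=0):
    """Two classes with disjoint hue ranges: trivially separable."""
    rng = np.random.default_rng(seed)
    f1 = rng.random((n_per_class, 10))
    f1[:, 0] = rng.uniform(0, 60, n_per_class)      # hue band A
    f2 = rng.random((n_per_class, 10))
    f2[:, 0] = rng.uniform(180, 240, n_per_class)   # hue band B
    feats = np.vstack([f1, f2])
    labels = np.r_[np.full(n_per_class, 1), np.full(n_per_class, 6)]
    return PixelDataset(feats, labels)


@pytest.fixture(scope="session")
def separable_data():
    return make_separable_dataset()
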