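import numpy as np
import pytest

from lgnet.data import SyntheticSpec, generate_synthetic, split_dataset


@pytest.fixture(scope="session")
def synthetic_set():
    """Shared 4-class synthetic set (two local, two global classes)."""
    spec = SyntheticSpec(num_classes=4, images_per_class=60, seed=0)
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def split_synthetic_set(synthetic_set):
    return split_dataset(synthetic_set, (0.8, 0.2), seed=0, names=("train", "val"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
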