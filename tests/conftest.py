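import numpy as np
import pytest

from foxtune.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Separable 3-class phantom set at desk scale."""
    spec = SyntheticSpec(n_per_class=(80, 80, 80), image_size=64,
                         noise_sd=8.0, seed=7)
    return generate_dataset(spec)


def sphere(x):
    return float(x @ x)
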