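import numpy as np
import pytest

from lafter.synthetic import SyntheticSpec, make_experiment


@pytest.fixture(scope="session")
def experiment32():
    """Small half-map experiment: 32^3, flat FSC 0.5, truncation 4 voxels."""
    spec = SyntheticSpec(shape=32, truncation_resolution=4.0, target_fsc=0.5, seed=7)
    return make_experiment(spec)


@pytest.fixture(scope="session")
def experiment64():
    """Reference-size experiment: 64^3, flat FSC 0.5, truncation 4 voxels."""
    spec = SyntheticSpec(shape=64, truncation_resolution=4.0, target_fsc=0.5, seed=0)
    return make_experiment(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
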