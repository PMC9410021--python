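import numpy as np
import pytest

from spine_uda.labels import load_reference_distances, load_vertebra_sizes
from spine_uda.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def reference_distances():
    return load_reference_distances()


@pytest.fixture(scope="session")
def vertebra_sizes():
    return load_vertebra_sizes()


def small_phantom_config(seed=0, domain="source", **kwargs):
    """A compact phantom used throughout the suite: 6 thoracic vertebrae on a
    33 x 64 x 224 grid at 1 mm spacing."""
    defaults = dict(
        n_vertebrae=6,
        first_vertebra_id=10,
        grid_shape=(33, 64, 224),
        seed=seed,
        domain=domain,
    )
    defaults.update(kwargs)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def phantom_sample():
    return generate_phantom(small_phantom_config(seed=7))


@pytest.fixture(scope="session")
def target_phantom_sample():
    return generate_phantom(small_phantom_config(seed=7, domain="target"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
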