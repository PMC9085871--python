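import numpy as np
import pytest

from couplemap.atlas import make_toy_cortex
from couplemap.synthetic import GenerativeSpec


@pytest.fixture(scope="session")
def small_spec():
    return GenerativeSpec(n_parcels=40, vertices_per_parcel=5, seed=7)


@pytest.fixture(scope="session")
def small_cortex(small_spec):
    return small_spec.make_cortex()


@pytest.fixture(scope="session")
def cortex100():
    return make_toy_cortex(100, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
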