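import numpy as np
import pytest

from csfspace.cli import _training_atlas
from csfspace.config import RunConfig
from csfspace.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def atlas_96():
    """Atlas prior built from five training phantoms at the default 96^3 grid."""
    return _training_atlas(96, 42)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return make_phantom(PhantomSpec(seed=5))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Cohort noise setting: noise SD = 5% of the GM class mean."""
    return make_phantom(PhantomSpec(noise_sd=4.0, seed=11))


@pytest.fixture()
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
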