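import numpy as np
import pytest

from sictf.epidemics import EpidemicParams
from sictf.networks import generate_hnm


@pytest.fixture(scope="session")
def default_params():
    return EpidemicParams()


@pytest.fixture(scope="session")
def small_hnm():
    """A 48-node household network (16 households of 3, d_c = 3)."""
    return generate_hnm(48, 2, 3, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
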