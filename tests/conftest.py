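import numpy as np
import pytest

from nanodna import geometry
from nanodna.transport import MediumModel


@pytest.fixture(scope="session")
def model41():
    """Canonical 41-BP atomic model with the 14.3 nm bounding cylinder."""
    return geometry.build_high_res_bdna(41, bounding_height=14.3)


@pytest.fixture(scope="session")
def model5():
    """Small atomic model for cheap per-test geometry work."""
    return geometry.build_high_res_bdna(5)


@pytest.fixture(scope="session")
def simple42():
    return geometry.build_simple_bdna(42)


@pytest.fixture(scope="session")
def medium():
    return MediumModel.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
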