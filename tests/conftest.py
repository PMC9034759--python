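import numpy as np
import pytest

from lobtype import default_fixture
from lobtype.geometry import build_layer_frame


@pytest.fixture(scope="session")
def fixture_sc():
    """The documented standard fixture: 8 unlabeled types x 60 cells, seed 1."""
    return default_fixture(1)


@pytest.fixture(scope="session")
def fitted_frame(fixture_sc):
    """Layer frame recovered from the fixture's reference postsynapses."""
    return build_layer_frame(fixture_sc.reference_postsynapses)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
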