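import numpy as np
import pytest

from structparafac import ThreeWayLayout, bentler_mcclain_fixture


@pytest.fixture(scope="session")
def mtmm():
    """Packaged 12 x 12 MTMM correlation fixture (J=4 traits, K=3 methods)."""
    return bentler_mcclain_fixture()


@pytest.fixture
def layout43():
    return ThreeWayLayout(4, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20200816)
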