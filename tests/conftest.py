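import numpy as np
import pytest

from phiscore import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def components_image():
    """Three-level fixture: dark blocks (some bridged at M) + mid-gray blocks."""
    return make_fixture(FixtureSpec(kind="components"))


@pytest.fixture(scope="session")
def holes_image():
    """Three-level fixture: dark rings with mid-gray interiors + mid-gray rings."""
    return make_fixture(FixtureSpec(kind="holes"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
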