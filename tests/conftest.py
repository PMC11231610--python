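import numpy as np
import pytest

from spinbind.forward import SpinComponent, default_field_axis
from spinbind.synth import component_library


@pytest.fixture(scope="session")
def wide_axis():
    """Field axis wide enough for rigid-limit wings of Azz ~ 90 MHz."""
    return default_field_axis(328.0, 346.0, 3072)


@pytest.fixture(scope="session")
def std_axis():
    """The standard 10 mT acquisition window."""
    return default_field_axis()


@pytest.fixture(scope="session")
def library():
    return component_library()


@pytest.fixture(scope="session")
def free_component(library):
    return library[0]


@pytest.fixture(scope="session")
def mw_freq():
    return 9.47


def count_zero_crossings(y, rel_threshold=1e-3):
    """Sign changes of a trace, ignoring numerically silent regions."""
    s = np.sign(y)
    s[np.abs(y) < rel_threshold * np.abs(y).max()] = 0
    s = s[s != 0]
    return int(np.sum(s[1:] * s[:-1] < 0))
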