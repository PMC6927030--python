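import numpy as np
import pytest

from lvadctl.cvs import CVSParams
from lvadctl.pump import load_pump_params


@pytest.fixture(scope="session")
def s1():
    return load_pump_params("S1")


@pytest.fixture(scope="session")
def s2():
    return load_pump_params("S2")


@pytest.fixture(scope="session")
def baseline():
    """Shipped heart-failure baseline circulation."""
    return CVSParams()


@pytest.fixture(scope="session")
def pulsatile_head():
    """Synthetic pulsatile pressure head at 80 bpm on a 1 ms grid."""
    t = np.arange(0.0, 6.0, 1e-3)
    H = 100.0 + 40.0 * np.sin(2 * np.pi * t / 0.75)
    return t, H
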