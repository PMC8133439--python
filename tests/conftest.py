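import numpy as np
import pytest

from c14growth import C14Sample, Window, synth_curve


@pytest.fixture(scope="session")
def window_6040() -> Window:
    return Window(6000, 4000)


@pytest.fixture(scope="session")
def identity_curve():
    """Identity curve with zero curve error: calibration is a discretised Normal."""
    return synth_curve("identity", (3000, 7500), tau0=0.0)


@pytest.fixture(scope="session")
def identity_curve_tau20():
    return synth_curve("identity", (3000, 7500), tau0=20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def sample_5000() -> C14Sample:
    return C14Sample("TEST-1", 5000.0, 20.0)
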