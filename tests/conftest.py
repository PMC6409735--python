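import numpy as np
import pytest

from adcpkpd.parameters import DoseRegimen, default_parameters


@pytest.fixture(scope="session")
def n87():
    return default_parameters("n87")


@pytest.fixture(scope="session")
def mcf7():
    return default_parameters("mcf7")


@pytest.fixture(scope="session")
def regimen_10():
    return DoseRegimen(dose_mg_per_kg=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
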