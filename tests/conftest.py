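import logging

import numpy as np
import pytest

import ncpower as ncp


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # package-level warnings (clamping, band excursions) are expected in tests
    logging.getLogger("ncpower").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def tte_preset():
    return ncp.get_preset("tte")


@pytest.fixture(scope="session")
def binary_preset():
    return ncp.get_preset("binary")


@pytest.fixture(scope="session")
def stub_80():
    """Stub engine drawing ncx2(1, 7.849 * N / 200): true power 0.800 at N=200."""
    return ncp.NoncentralStubEngine(df=1, lambda_ref=7.849, n_ref=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
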