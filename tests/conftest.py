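import numpy as np
import pytest

from petprompt import ScannerModel, calibrate_scanner, load_fraction_table


@pytest.fixture(scope="session")
def scanner():
    return ScannerModel()


@pytest.fixture(scope="session")
def calibrated():
    """Scanner with the I-131 singles-yield scale fixed at the 300 µCi,
    [350, 650) keV table point."""
    return calibrate_scanner()


@pytest.fixture(scope="session")
def table():
    return load_fraction_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
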