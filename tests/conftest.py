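import numpy as np
import pytest

from arid14c.atmos import AtmosphericCurve, synthetic_bomb_curve


@pytest.fixture(scope="session")
def curve():
    """Packaged default bomb curve through 2020."""
    return synthetic_bomb_curve(last_year=2020)


@pytest.fixture(scope="session")
def flat_curve():
    """Constant 0‰ atmosphere (pre-bomb steady state everywhere)."""
    years = np.arange(1900.0, 2021.0)
    return AtmosphericCurve(years, np.zeros_like(years), label="flat 0")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
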