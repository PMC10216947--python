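import numpy as np
import pytest

from edukin import CellCycleParams
from edukin.datasets import load_cumulative_series


@pytest.fixture(scope="session")
def params_1dpa():
    """Published kinetics of the cumulative experiment starting at 1 dpa."""
    return CellCycleParams(tc=33.2, ts=1.3, gf=85.7)


@pytest.fixture(scope="session")
def params_2dpa():
    """Published kinetics of the cumulative experiment starting at 2 dpa."""
    return CellCycleParams(tc=25.7, ts=7.3, gf=76.0)


@pytest.fixture(scope="session")
def series_1dpa():
    return load_cumulative_series("1dpa")


@pytest.fixture(scope="session")
def series_2dpa():
    return load_cumulative_series("2dpa")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
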