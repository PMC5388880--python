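import numpy as np
import pytest

from neurovasc.bolus import BolusTrace, gamma_variate
from neurovasc.synthetic import BolusCohortConfig, PacSignalConfig


@pytest.fixture
def time_grid():
    """12 s scan at the 20 ms line period."""
    return np.arange(0.0, 12.0, 0.02)


@pytest.fixture
def clean_trace(time_grid):
    """Noiseless gamma-variate bolus: b=0, A=1, t0=2, alpha=3, beta=0.5 (TTP 3.5 s)."""
    f = gamma_variate(time_grid, 0.0, 1.0, 2.0, 3.0, 0.5)
    return BolusTrace("v0", "arteriole", "normocapnia", time_grid, f)


@pytest.fixture
def small_cohort_config():
    """A 26-vessel cohort, fast enough for unit tests."""
    return BolusCohortConfig(
        n_vessels_per_type={"arteriole": 10, "capillary": 8, "venule": 8},
        n_animals=3, seed=7,
    )


@pytest.fixture
def fast_pac_config():
    """120 s PAC signal generated directly at the 1 kHz analysis rate."""
    return PacSignalConfig(sampling_rate=1000.0, seed=11)
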