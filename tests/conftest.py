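import numpy as np
import pytest

from mnasim import InletSchedule, Numerics, TransportParams
from mnasim.synthetic import (
    CALIBRATED_DECAY,
    CALIBRATED_SORPTION_COEFF,
    DEFAULT_DISPERSIVITY,
    DEFAULT_SORPTION_RATE,
    INFLUENT_MEAN,
    reference_column,
)


@pytest.fixture(scope="session")
def spec1():
    """Biotic column (#1)."""
    return reference_column(1)


@pytest.fixture(scope="session")
def spec2():
    """Sterile control column (#2)."""
    return reference_column(2)


@pytest.fixture(scope="session")
def fast_numerics():
    """Coarse but stable numerics for fitting-heavy tests (CN is A-stable)."""
    return Numerics(nx=100, dt=0.05, save_states=False)


@pytest.fixture(scope="session")
def inlet_const():
    return InletSchedule.constant(INFLUENT_MEAN)


@pytest.fixture(scope="session")
def calibrated_params(spec1):
    """Kinetic-sorption transport parameters at the calibrated values."""
    return TransportParams.for_column(
        spec1,
        dispersivity=DEFAULT_DISPERSIVITY,
        sorption_coeff=CALIBRATED_SORPTION_COEFF,
        sorption_rate=DEFAULT_SORPTION_RATE,
        decay=CALIBRATED_DECAY,
    )


@pytest.fixture(scope="session")
def sample_times():
    """The 13 effluent sampling instants: every 2 d ending at 25 d."""
    return np.arange(25.0, 0.0, -2.0)[::-1]
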