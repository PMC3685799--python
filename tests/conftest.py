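import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from calorpart.chamber import ChamberSpec, FedDayParameters
from calorpart.traces import SignalTrace

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

N = 8640
DT = 10.0


@pytest.fixture
def zero_trace():
    return SignalTrace(0.0, DT, np.zeros(N))


@pytest.fixture
def default_spec():
    return ChamberSpec(physical_volume=12000.0, outflow=7500.0)


@pytest.fixture
def resting_params():
    """A quiet animal: resting exchange only."""
    return FedDayParameters(
        VOFED=33.0, VCFED=36.0, VOFOR=0.0, VCFOR=0.0,
        O2TEF=0.0, CO2TEF=0.0, TTEF=2.0,
    )


def impulse_feed(mass_g: float, tick: int = 1000) -> SignalTrace:
    """Cumulative trace of a single instantaneous meal."""
    cum = np.zeros(N)
    cum[tick:] = mass_g
    return SignalTrace(0.0, DT, cum)


@pytest.fixture
def impulse_meal():
    return impulse_feed(500.0)
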