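import numpy as np
import pytest

from eispulse import CircuitParams, PulseSpec


@pytest.fixture
def default_params() -> CircuitParams:
    """Reference circuit used throughout the waveform examples."""
    return CircuitParams(cpe_t=1e-7, cpe_p=0.8, r1=500.0, c=1e-9, r2=300.0)


@pytest.fixture
def lab_pulse() -> PulseSpec:
    """The in-vitro stimulus: 50 uA, 50 us per phase, no interphase gap."""
    return PulseSpec(i_amp=50e-6, t0=50e-6)


@pytest.fixture
def dense_times(lab_pulse) -> np.ndarray:
    """Fine uniform grid covering the pulse and an equal decay tail."""
    return np.arange(0.0, 4 * lab_pulse.t0, lab_pulse.t0 / 200)
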