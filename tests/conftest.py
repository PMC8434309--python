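import numpy as np
import pytest

from ecgsync.detector_core import DetectorConfig, UniformSignal
from ecgsync.simulator import generate_preset


@pytest.fixture
def cfg():
    return DetectorConfig()


@pytest.fixture(scope="session")
def clean_trace():
    """12 noiseless beats at 60 bpm with exact R annotations."""
    return generate_preset("clean", seed=0, n_beats=12)


@pytest.fixture(scope="session")
def wander_trace():
    """20 beats with the 0.5*R, 0.3 Hz baseline-wander stressor."""
    return generate_preset("wander", seed=1, n_beats=20)


@pytest.fixture
def ramp():
    """Linear ramp of slope 2 units/s on the 5 ms tick grid."""
    tick = 0.005
    n = 400
    t = np.arange(n) * tick
    return UniformSignal(0.0, tick, 2.0 * t)
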