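import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import alpharhythm as ar

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule160():
    return ar.make_trial_schedule(160, seed=11)


@pytest.fixture(scope="session")
def small_layout():
    """2 left + 2 right + 1 midline combined positions (10 raw channels)."""
    return ar.make_sensor_layout(2, 2, 1)


@pytest.fixture(scope="session")
def fast_params():
    """Generator parameters scaled for quick unit tests."""
    return ar.GeneratorParams(sampling_rate=100.0)


@pytest.fixture(scope="session")
def clean_recording(schedule160, small_layout):
    """Noise-free recording with planted modulation, shared across tests."""
    params = ar.GeneratorParams(sampling_rate=100.0, noise_std=0.0, seed=2)
    return ar.simulate_meg(schedule160, small_layout, params)
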