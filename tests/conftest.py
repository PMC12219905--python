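import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from molli_ptnn import (
    SequenceParams,
    build_schedule,
    synthesize_triggers,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return SequenceParams()


@pytest.fixture(scope="session")
def ideal_params():
    return SequenceParams(ideal=True)


@pytest.fixture(scope="session")
def schedule_533():
    """5(3)3 at a metronomic 60 bpm simulated ECG."""
    return build_schedule("5(3)3", synthesize_triggers(1000.0, 0.0, 12, seed=0))


@pytest.fixture(scope="session")
def schedule_503():
    return build_schedule("5(0)3", synthesize_triggers(1000.0, 0.0, 9, seed=0))


@pytest.fixture(scope="session")
def schedule_varied():
    """5(3)3 with beat-to-beat RR variability."""
    return build_schedule("5(3)3", synthesize_triggers(950.0, 60.0, 12, seed=11))
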