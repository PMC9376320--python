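import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pneumotach as pt

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def devices():
    return pt.load_device_table()


@pytest.fixture(scope="session")
def p1(devices):
    return devices["pneumotach-1"]


@pytest.fixture(scope="session")
def p2(devices):
    return devices["pneumotach-2"]


@pytest.fixture(scope="session")
def p3(devices):
    return devices["pneumotach-3"]


@pytest.fixture
def constant_pressure_pair():
    """Two constant-pressure maneuvers generated from K1=0.2, K2=1.0.

    P = 0.08 cmH2O held 5 s (flow 0.2 L/s, volume 1 L) and P = 0.35 cmH2O
    held 2 s (flow 0.5 L/s, volume 1 L).
    """
    t1 = np.linspace(0.0, 5.0, 1001)
    t2 = np.linspace(0.0, 2.0, 401)
    m1 = pt.ManeuverRecord(
        pt.PressureSignal(t=t1, y=np.full(t1.size, 0.08)), 1.0, "slow-const"
    )
    m2 = pt.ManeuverRecord(
        pt.PressureSignal(t=t2, y=np.full(t2.size, 0.35)), 1.0, "fast-const"
    )
    return m1, m2
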