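import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mgsim as mg

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def limits():
    return mg.MotionLimits()


def sinusoid_trajectory(dt: float, duration: float = 20.0) -> mg.Trajectory:
    """Smooth analytic trajectory with exact rate and acceleration columns."""
    t = np.arange(0.0, duration + dt / 2, dt)
    al = 0.8 * np.sin(1.3 * t)
    ar = 0.8 * 1.3 * np.cos(1.3 * t)
    aa = -0.8 * 1.3 ** 2 * np.sin(1.3 * t)
    be = 0.5 * np.sin(0.9 * t + 0.4)
    br = 0.5 * 0.9 * np.cos(0.9 * t + 0.4)
    ba = -0.5 * 0.9 ** 2 * np.sin(0.9 * t + 0.4)
    return mg.Trajectory(t, al, be, ar, br, aa, ba, dt)


def constant_spin_trajectory(rate: float, duration: float,
                             dt: float) -> mg.Trajectory:
    """Outer axis spinning at a constant rate, inner axis at rest."""
    t = np.arange(0.0, duration + dt / 2, dt)
    zeros = np.zeros_like(t)
    return mg.Trajectory(t, rate * t, zeros, np.full_like(t, rate), zeros,
                         zeros, zeros, dt)
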