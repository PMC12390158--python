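import numpy as np
import pytest

from spineimu.simulate import (
    EarthField,
    ParticipantParams,
    SensorParams,
    build_task_script,
    simulate_kinematics,
    synthesize_imu,
)


@pytest.fixture(scope="session")
def earth():
    return EarthField()


@pytest.fixture(scope="session")
def script():
    return build_task_script(seed=0)


@pytest.fixture(scope="session")
def session_truth(script):
    """Noise-free scripted session, shared across tests."""
    return simulate_kinematics(script, ParticipantParams(), seed=1)


@pytest.fixture(scope="session")
def clean_spine_streams(session_truth, earth):
    """Noise-free upper/lower sensor streams for the scripted session."""
    return {
        sid: synthesize_imu(session_truth, SensorParams(sensor_id=sid), earth=earth)
        for sid in ("upper", "lower")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def still_stream(
    n_s=60.0,
    rate=20.0,
    gyr_noise=0.0,
    acc_noise=0.0,
    mag_noise=0.0,
    bias=(0.0, 0.0, 0.0),
    seed=0,
    earth=None,
):
    """A motionless upright sensor stream (helper used by several tests)."""
    from spineimu.core import SensorStream

    earth = earth or EarthField()
    rng = np.random.default_rng(seed)
    n = int(n_s * rate)
    t = np.arange(n) / rate
    acc = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.normal(0, acc_noise, (n, 3))
    gyr = np.tile(np.asarray(bias, float), (n, 1)) + rng.normal(0, gyr_noise, (n, 3))
    mag = np.tile(earth.vector(), (n, 1)) + rng.normal(0, mag_noise, (n, 3))
    return SensorStream("still", t, acc, gyr, mag, rate_hz=rate)
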