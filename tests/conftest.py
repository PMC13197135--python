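import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import esotransit as et

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def seated():
    """Seed-1 seated swallow at default noise, with its ground truth."""
    scenario = et.build_scenario("seated_reference", {"seed": 1})
    log, gt = et.generate_swallow(scenario)
    return scenario, log, gt


@pytest.fixture(scope="session")
def seated_noiseless():
    """Noise- and cardiac-free seated swallow (analytic signal checks)."""
    scenario = et.build_scenario(
        "seated_reference",
        {
            "seed": 1,
            "cardiac_amplitude_m_s2": 0.0,
            "noise": {
                "accel_sigma": 0.0,
                "gyro_sigma": 0.0,
                "mag_sigma": 0.0,
                "pressure_sigma": 0.0,
            },
        },
    )
    log, gt = et.generate_swallow(scenario)
    return scenario, log, gt


@pytest.fixture(scope="session")
def seated_report(seated):
    _, log, _ = seated
    return et.analyze_log(log)


@pytest.fixture(scope="session")
def supine():
    scenario = et.build_scenario("supine_reference", {"seed": 1})
    log, gt = et.generate_swallow(scenario)
    return scenario, log, gt


@pytest.fixture(scope="session")
def static_log():
    """Stationary-posture log with zero noise and no cardiac component."""
    scenario = et.build_scenario(
        "stationary_banana",
        {
            "seed": 3,
            "cardiac_amplitude_m_s2": 0.0,
            "duration_s": 12.0,
            "noise": {
                "accel_sigma": 0.0,
                "gyro_sigma": 0.0,
                "mag_sigma": 0.0,
                "pressure_sigma": 0.0,
            },
        },
    )
    log, gt = et.generate_swallow(scenario)
    return log, gt


def assert_quat_close(a, b, tol_deg):
    from esotransit.quaternion import quat_angle_between

    ang = np.degrees(quat_angle_between(a, b))
    assert np.max(ang) < tol_deg, f"max angular error {np.max(ang):.3f} deg"
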