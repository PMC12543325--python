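import numpy as np
import pytest

from bpvkit.simulate import (
    AnimalConfig,
    CircadianProfile,
    PressorKinetics,
    SALINE_KINETICS,
    build_pump_schedule,
    simulate_telemetry,
)


@pytest.fixture(scope="session")
def quiet_animal():
    """Noiseless animal with no activity bursts: fully deterministic traces."""
    return AnimalConfig(noise_sd_bp=0.0, noise_sd_hr=0.0, activity_burst_rate=0.0)


@pytest.fixture(scope="session")
def circadian():
    return CircadianProfile()


@pytest.fixture(scope="session")
def angii_kinetics():
    return PressorKinetics()


@pytest.fixture(scope="session")
def two_day_schedule():
    return build_pump_schedule(3.0, 1.0, 2.0)


@pytest.fixture(scope="session")
def noiseless_angii_recording(quiet_animal, circadian, two_day_schedule, angii_kinetics):
    """Two days of noiseless pulsed-pressor telemetry."""
    return simulate_telemetry(
        quiet_animal, circadian, two_day_schedule, angii_kinetics, days=2
    )


@pytest.fixture(scope="session")
def noiseless_saline_recording(quiet_animal, circadian, two_day_schedule):
    return simulate_telemetry(
        quiet_animal, circadian, two_day_schedule, SALINE_KINETICS, days=2
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
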