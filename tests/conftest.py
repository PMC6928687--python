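import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from gaitstrain import (
    GridModel,
    ProtocolSpec,
    SensorModel,
    generate_cohort,
    sample_profile,
    simulate_joint_angles,
)


@pytest.fixture(scope="session")
def short_protocol() -> ProtocolSpec:
    """Two speeds, three repeats, 5 s trials: fast but structurally complete."""
    return ProtocolSpec(speeds=(8.0, 12.0), trial_duration=5.0, repeats=3)


@pytest.fixture(scope="session")
def small_cohort(short_protocol):
    return generate_cohort(2, short_protocol, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def one_trial(small_cohort):
    return small_cohort.trials[0]


@pytest.fixture(scope="session")
def profile():
    return sample_profile(np.random.default_rng(7), "P01")


@pytest.fixture(scope="session")
def angle_trial(profile, short_protocol):
    return simulate_joint_angles(
        profile, 10.0, 0, short_protocol, np.random.default_rng(3)
    )


@pytest.fixture(scope="session")
def grid_model() -> GridModel:
    return GridModel()


@pytest.fixture(scope="session")
def linear_sensor_model() -> SensorModel:
    return SensorModel(saturation="linear")
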