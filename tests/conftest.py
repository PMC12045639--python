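import numpy as np
import pytest

from seismocrab import PlantedBehaviour, SceneConfig, gen_session

FS = 1612.0


@pytest.fixture(scope="session")
def small_session():
    """One synthetic session with a drumming event, two body drops and a
    non-percussive tag, used across I/O and pipeline tests."""
    config = SceneConfig(
        duration=30.0,
        seed=20240915,
        far_distance_cm=50.0,
        wind_profile=[(0.0, 2.0)],
        events=[
            PlantedBehaviour("UGD", 4.0),
            PlantedBehaviour("simWBD", 10.0),
            PlantedBehaviour("seqBD", 14.0),
            PlantedBehaviour("waving", 20.0),
        ],
    )
    session, events, truth = gen_session(config)
    return session, events, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
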