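import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_tracker_config():
    from dipolecycle.tracker import TrackerConfig

    return TrackerConfig(n_features=300, min_distance=6, window_size=15, n_pyramids=2)


@pytest.fixture
def fiber_image():
    from dipolecycle.synthetic import TextureParams, _fiber_texture

    return _fiber_texture(TextureParams(shape=(180, 180), seed=7))
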