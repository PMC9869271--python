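import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A deterministic 200x150 scene with a moderate number of glands."""
    from glandseg import SceneConfig, generate_scene

    return generate_scene(SceneConfig(width=200, height=150, spot_count=30,
                                      spot_radius_range=(1, 3), seed=77))
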