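import numpy as np
import pytest

from pointal import SceneParams, SimDetectorParams, SimulatedDetector, generate_pool


@pytest.fixture(scope="session")
def small_scene_params() -> SceneParams:
    """Compact scenes for fast loop tests."""
    return SceneParams(n_objects_range=(5, 15))


@pytest.fixture(scope="session")
def small_pool(small_scene_params):
    return generate_pool(80, small_scene_params, seed=11)


@pytest.fixture()
def detector():
    return SimulatedDetector(SimDetectorParams(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
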