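import numpy as np
import pytest

from hsistress import SceneParams, simulate_scene


@pytest.fixture(scope="session")
def default_params() -> SceneParams:
    return SceneParams()


@pytest.fixture(scope="session")
def small_params() -> SceneParams:
    """Reduced spatial footprint for fast per-scene tests."""
    return SceneParams(image_rows=48, image_cols=48, leaf_count=2)


@pytest.fixture(scope="session")
def noisy_scene(small_params):
    return simulate_scene(2, small_params, seed=11)


@pytest.fixture(scope="session")
def noiseless_scene(small_params):
    return simulate_scene(1, small_params.noiseless(), seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
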