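import numpy as np
import pytest

from arcore.phantom import SceneConfig, make_scene


def small_scene_config(**overrides) -> SceneConfig:
    """A desk-scale scene: fewer streamlines, same geometry and thresholds."""
    kwargs = dict(n_bundle=40, n_per_distractor=6)
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


@pytest.fixture(scope="session")
def small_scene():
    return make_scene(small_scene_config(), seed=11)


@pytest.fixture(scope="session")
def default_scene():
    """The full-size scene (1,000 bundle streamlines) used for recovery checks."""
    return make_scene(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
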