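import numpy as np
import pytest

from fluokernel import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One full-size default scene (640x640, 12 kernels, gap 5)."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def scene_batch():
    """20 seeded default scenes shared by the recovery tests."""
    return [generate_scene(SceneConfig(seed=s)) for s in range(20)]


@pytest.fixture(scope="session")
def small_scene():
    """Small scene for fast I/O and CLI tests."""
    cfg = SceneConfig(width_px=192, height_px=192, n_kernels=4, seed=3)
    return cfg, generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
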