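import numpy as np
import pytest

from s1lai import scene as sc


@pytest.fixture(scope="session")
def small_scene() -> sc.Scene:
    """24×24 scene, cheap enough for per-module tests."""
    return sc.generate_scene(sc.SceneConfig(rows=24, cols=24, seed=42))


@pytest.fixture(scope="session")
def default_scene() -> sc.Scene:
    """Full-size (60×60) default scene used by end-to-end checks."""
    return sc.generate_scene(sc.SceneConfig(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
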