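import numpy as np
import pytest

from colpoqc.synthetic import SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scene():
    """Default 640x480 scene at 0.125 mm/px (2-mm squares -> 16 px)."""
    return SceneSpec(width_px=640, height_px=480, seed=7, mm_per_px=0.125)


@pytest.fixture
def small_scene():
    return SceneSpec(width_px=200, height_px=200, seed=11, mm_per_px=0.25)
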