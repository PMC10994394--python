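import numpy as np
import pytest

from syrdose import PipelineConfig, SynthScene, render


@pytest.fixture(scope="session")
def default_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_scene():
    """A clean 5 ml, 40%-fill colorless scene plus its ground truth."""
    scene = SynthScene(capacity_ml=5, fill_fraction=0.4, seed=1)
    img, truth = render(scene)
    return scene, img, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def rect_mask(shape, top, left, height, width):
    m = np.zeros(shape, dtype=np.uint8)
    m[top : top + height, left : left + width] = 1
    return m
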