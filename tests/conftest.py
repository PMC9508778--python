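import numpy as np
import pytest

from gazepheno.core import PipelineConfig, ScreenGeometry


@pytest.fixture
def config():
    """Default pipeline configuration (full screen, 4x heatmap grid)."""
    return PipelineConfig(heatmap_downsample=4)


@pytest.fixture
def small_config():
    """A small screen for fast rasterization-heavy tests."""
    return PipelineConfig(screen=ScreenGeometry(width_px=400, height_px=300,
                                                px_per_degree=41.0),
                          heatmap_downsample=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
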