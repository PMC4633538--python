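import numpy as np
import pytest

from epstra.slide_io import CHANNELS, MultiChannelSlide, TiledChannelImage
from epstra.synth import SynthParams, generate_slide


def make_slide(channel_arrays: dict[str, np.ndarray], tile_shape=(8, 8),
               bit_depth=8) -> MultiChannelSlide:
    """Build a slide from full-extent channel arrays (missing channels
    are zero-filled)."""
    extent = next(iter(channel_arrays.values())).shape
    channels = {}
    for name in CHANNELS:
        arr = channel_arrays.get(name, np.zeros(extent, dtype=np.uint16))
        channels[name] = TiledChannelImage.from_stitched(
            name, np.asarray(arr), tile_shape, bit_depth=bit_depth)
    return MultiChannelSlide(channels)


@pytest.fixture(scope="session")
def default_fov():
    """One default-condition synthetic FOV (slide, truth, rois)."""
    return generate_slide(SynthParams(seed=3))


@pytest.fixture(scope="session")
def clean_fov():
    """A noise-free, gradient-free FOV without holes or artifacts."""
    return generate_slide(SynthParams(
        seed=3, noise_sd=0.0, gradient_range=(1.0, 1.0),
        nuclear_hole_rate=0.0, artifact_blobs=0))
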