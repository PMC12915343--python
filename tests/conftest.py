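"""Shared fixtures: small synthetic images and rendered presets."""

import numpy as np
import pytest
from hypothesis import settings

from nodulequant.core_io import ImageRGB, RunConfig
from nodulequant import simulate

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


def make_uniform_image(color, h=8, w=8, pixel_size_mm=1.0):
    arr = np.zeros((h, w, 3), dtype=np.uint8)
    arr[:, :] = color
    return ImageRGB(pixels=arr, source_path="synthetic", pixel_size_mm=pixel_size_mm)


@pytest.fixture
def uniform_image():
    return make_uniform_image


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def clean_render():
    """Clean preset rendered once per session: 5+5+5 nodules, zero noise."""
    cfg = simulate.preset_config("clean", seed=11)
    image, truth = simulate.render(cfg)
    return cfg, image, truth
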