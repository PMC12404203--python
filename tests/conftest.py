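import dataclasses

import numpy as np
import pytest

import somitoclock as sc
from somitoclock.synth import PRESETS, WavePreset


@pytest.fixture(scope="session")
def wt_preset() -> WavePreset:
    return PRESETS["wt_embedded"]


@pytest.fixture(scope="session")
def small_preset() -> WavePreset:
    """A reduced-size movie preset for fast pipeline tests."""
    return WavePreset(
        name="small", period_min=260.0, origin="posterior",
        baseline=100.0, amplitude=200.0, noise_sd=8.0,
        band_length_px=90, band_width_px=30,
        duration_min=1040.0, image_shape=(128, 128), seed=7,
    )


@pytest.fixture(scope="session")
def wt_movie(wt_preset):
    """One full-size wild-type movie plus its ground truth."""
    return sc.generate_somitoid_movie(dataclasses.replace(wt_preset, seed=3))


@pytest.fixture(scope="session")
def small_movie(small_preset):
    return sc.generate_somitoid_movie(small_preset)


@pytest.fixture(scope="session")
def small_analysis(small_movie):
    movie, truth = small_movie
    summary, inter = sc.pipeline.analyze_movie(movie)
    return movie, truth, summary, inter


@pytest.fixture()
def straight_band_mask():
    """Axis-aligned 180x50 rectangle of foreground in a 256x256 image."""
    img = np.zeros((256, 256), dtype=bool)
    img[103:153, 38:218] = True
    return sc.Mask(img)
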