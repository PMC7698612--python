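import numpy as np
import pytest

from nvtherm import MEAN_PARAMS, NoiseModel, SceneConfig, SweepGrid


@pytest.fixture
def mean_params():
    """Ensemble-mean line-shape parameters."""
    return MEAN_PARAMS


@pytest.fixture
def narrow_grid():
    """The 50-point 2860-2880 MHz sub-sweep grid (0.4 MHz spacing)."""
    return SweepGrid(2860.0, 2880.0, 50)


@pytest.fixture
def wide_grid():
    """The 50-point 2850-2890 MHz sub-sweep grid (0.8 MHz spacing)."""
    return SweepGrid(2850.0, 2890.0, 50)


@pytest.fixture
def clean_single_spot_scene():
    """Noise-free single-spot scene with zero background, float64 for exact checks."""
    return SceneConfig(
        image_shape=(64, 64),
        n_spots=1,
        n_repeats=2,
        noise=NoiseModel(0.0),
        background=0.0,
        background_noise_sd=0.0,
        draw_params_per_spot=False,
        dtype="float64",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210)
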