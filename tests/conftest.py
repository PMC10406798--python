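import numpy as np
import pytest

from mstissue import SpectralCube, WavelengthGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    return WavelengthGrid([400.0, 450.0, 500.0, 550.0, 600.0, 650.0])


@pytest.fixture
def random_absorbance_cube(rng, small_grid):
    """8x8x6 strictly positive absorbance cube with no special structure."""
    data = rng.uniform(0.05, 1.5, size=(8, 8, len(small_grid)))
    return SpectralCube(data, small_grid, "absorbance")


@pytest.fixture
def tiny_phantom():
    """Noise-free, unquantized 64x64 phantom with its ground truth."""
    from mstissue import eye_phantom, render_transmission_cube

    spec = eye_phantom(shape=(64, 64), seed=11, noise_sigma=0.0, n_frames=2,
                       levels=None)
    T, truth = render_transmission_cube(spec)
    return spec, T, truth
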