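import numpy as np
import pytest

from netspect.spectral import SpectralDensity


@pytest.fixture
def rng():
    return np.random.default_rng(20230330)


def random_density(rng, grid=None, n_points=64) -> SpectralDensity:
    """A random unit-area density on a fixed grid (test helper)."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, n_points)
    values = rng.random(grid.size) + 1e-3
    values /= np.trapezoid(values, grid)
    return SpectralDensity(grid, values, bandwidth=1.0)


def density_from_values(grid, values) -> SpectralDensity:
    """Wrap arbitrary nonnegative values as a unit-area density."""
    values = np.asarray(values, dtype=float)
    values = values / np.trapezoid(values, grid)
    return SpectralDensity(np.asarray(grid, dtype=float), values, bandwidth=1.0)
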