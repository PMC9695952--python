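import numpy as np
import pytest

from skinspec import (
    ReflectanceSpectrum,
    full_grid,
    visible_grid,
)


@pytest.fixture(scope="session")
def vgrid():
    return visible_grid()


@pytest.fixture
def flat_visible(vgrid):
    """Flat 50% reflector on the 67-point visible grid."""
    return ReflectanceSpectrum(vgrid, np.full(67, 0.5), label="flat50")


@pytest.fixture
def flat_full():
    """Flat 50% reflector covering the full 400-1000 nm sensor range."""
    g = full_grid()
    return ReflectanceSpectrum(g, np.full(len(g), 0.5), label="flat50_full")


@pytest.fixture(scope="session")
def fixture_palette():
    from skinspec import read_palette
    from importlib import resources

    path = resources.files("skinspec.data").joinpath(
        "synthetic_skintone_palette.csv"
    )
    return read_palette(str(path))


def random_spectrum(rng, grid=None):
    """Helper: smooth random reflectance spectrum for property tests."""
    from skinspec import visible_grid

    if grid is None:
        grid = visible_grid()
    n = len(grid)
    base = rng.uniform(0.1, 0.8)
    wobble = rng.uniform(-0.05, 0.05) * np.sin(
        np.linspace(0, rng.uniform(1, 3) * np.pi, n)
    )
    return ReflectanceSpectrum(grid, np.clip(base + wobble, 0.01, 1.0))
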