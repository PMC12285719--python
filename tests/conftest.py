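import numpy as np
import pytest

from plumelayers.spectra import DEFAULT_GRID, Spectrum
from plumelayers.vision import build_visual_system


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def vs():
    """Default violet-sensitive tetrachromat visual system."""
    return build_visual_system()


@pytest.fixture
def flat_spectrum(grid):
    def make(level: float, name: str = "") -> Spectrum:
        return Spectrum(grid, np.full(grid.n, float(level)), name)

    return make


@pytest.fixture
def random_spectrum(grid):
    """Seeded factory for strictly positive random smooth-ish spectra."""

    def make(rng: np.random.Generator) -> Spectrum:
        base = rng.uniform(0.05, 0.8)
        amp = rng.uniform(0.0, min(base - 0.02, 0.9 - base))
        center = rng.uniform(350, 650)
        width = rng.uniform(30, 150)
        vals = base + amp * np.sin((grid.wavelengths - center) / width)
        return Spectrum(grid, np.clip(vals, 1e-4, 1.0))

    return make
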