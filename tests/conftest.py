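import numpy as np
import pytest

from zspeed import (
    DEFAULT_POOLS,
    PoolSpec,
    ZSpectrum,
    make_offset_grid,
    simulate_phantom,
    simulate_zspectrum,
)


@pytest.fixture(scope="session")
def grid51():
    return make_offset_grid(-5, 5, 0.2)


@pytest.fixture(scope="session")
def grid101():
    return make_offset_grid(-5, 5, 0.1)


@pytest.fixture(scope="session")
def water_pool():
    return PoolSpec(0.8, 0.0, 1.4, name="water")


@pytest.fixture(scope="session")
def water_spectrum(grid101, water_pool):
    """Noise-free single-pool spectrum, dip exactly at 0 ppm."""
    return simulate_zspectrum(grid101, [water_pool], noise_sd=0.0)


@pytest.fixture(scope="session")
def brain_spectrum(grid101):
    """Noise-free multi-pool mouse-brain-like spectrum."""
    return simulate_zspectrum(grid101, DEFAULT_POOLS, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_phantom(grid51):
    """Tiny noise-free two-slice phantom with zero B0 shift."""
    return simulate_phantom(
        n_subjects=1, n_slices=2, shape=(8, 8), grid=grid51,
        b0_field=0.0, noise_sd=0.0, seed=11,
    )[0]
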