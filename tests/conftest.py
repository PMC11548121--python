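import numpy as np
import pytest
from hypothesis import settings

import collitrans as ct

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=60)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quartz_water_cuvette():
    """A standard 10 mm quartz cuvette filled with a water-based medium."""
    return ct.CuvetteSpec(n_surround=1.0, n_wall=1.46, n_medium=1.33,
                          path_length_mm=10.0)


@pytest.fixture(scope="session")
def small_fixture_spec():
    """Coarse-grid noiseless fixture: fast, exactly invertible."""
    return ct.FixtureSpec(
        wavelength_nm=np.arange(500.0, 1000.0, 5.0),
        noise_sd=0.0,
        masked_intervals_nm=(),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_fixture(small_fixture_spec):
    return ct.generate_measurement_pair(small_fixture_spec)


@pytest.fixture(scope="session")
def mie_phase_1um():
    """Mie phase function of 1 um polystyrene spheres in water at 600 nm."""
    x = np.pi * 1.0e3 * 1.33 / 600.0
    return ct.phase_function_table(x, 1.586 / 1.33)
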