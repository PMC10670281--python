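import numpy as np
import pytest

from o2spec import PhantomParams, default_grid, generate_phantom_spectrum


@pytest.fixture
def grid():
    return default_grid()


@pytest.fixture
def params():
    return PhantomParams()


@pytest.fixture
def oxygenated_spectrum(grid, params):
    return generate_phantom_spectrum(params, grid)


@pytest.fixture
def purged_spectrum(grid):
    return generate_phantom_spectrum(PhantomParams(oxygenated=False), grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
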