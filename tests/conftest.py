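import warnings

import numpy as np
import pytest

from mesovisc.grid import AcquisitionGrid
from mesovisc.synthetic import homogeneous_phantom, simulate_wavefield


@pytest.fixture(scope="session")
def grid_small() -> AcquisitionGrid:
    """Isotropic in-plane grid, single encoding component, protocol frequencies."""
    return AcquisitionGrid((8, 64, 64), (2.5, 2.5, 2.5), (30.0, 40.0, 50.0, 60.0), 8, 1)


@pytest.fixture(scope="session")
def elastic_field(grid_small):
    """Noiseless plane wave in a 1 kPa elastic phantom (c = 1 m/s)."""
    phantom = homogeneous_phantom(grid_small, 1.0, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return phantom, simulate_wavefield(phantom, grid_small)


@pytest.fixture(scope="session")
def viscous_field(grid_small):
    """Noiseless damped plane wave, |G*| = 2 kPa, phi = 0.6 rad."""
    phantom = homogeneous_phantom(grid_small, 2.0, 0.6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return phantom, simulate_wavefield(phantom, grid_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
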