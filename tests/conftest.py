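import numpy as np
import pytest

from psfinv import OpticalConfig, build_pupil_grid
from psfinv.psf import field_factors
from psfinv.pupil import apodization


@pytest.fixture(scope="session")
def small_cfg():
    """Compact astigmatic-system configuration for fast fit tests."""
    return OpticalConfig(na=1.3, wavelength=660, n_immersion=1.406,
                         pixel_size_xy=120, z_step=100, roi_size=13,
                         oversample=2)


@pytest.fixture(scope="session")
def std_cfg():
    """The benchmark configuration (21 px ROIs)."""
    return OpticalConfig(na=1.35, wavelength=660, n_immersion=1.406,
                         pixel_size_xy=120, z_step=50, roi_size=21,
                         oversample=2)


@pytest.fixture(scope="session")
def std_grid(std_cfg):
    return build_pupil_grid(std_cfg)


@pytest.fixture(scope="session")
def small_grid(small_cfg):
    return build_pupil_grid(small_cfg)


@pytest.fixture(scope="session")
def std_basis(std_grid):
    return std_grid.zernike_basis(max_radial_order=8)


@pytest.fixture(scope="session")
def scalar_factors(small_grid, small_cfg):
    return field_factors(small_grid, small_cfg, vectorial=False)


@pytest.fixture(scope="session")
def small_apod(small_grid):
    return apodization(small_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
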