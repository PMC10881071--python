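import numpy as np
import pytest

from tismorph.nlo import CellMask
from tismorph.synthetic import PhenotypeParams


def make_mask(shape=(10, 10), full=True, pixel_size_um=0.35) -> CellMask:
    mask = np.ones(shape, bool) if full else np.zeros(shape, bool)
    return CellMask(mask, pixel_size_um=pixel_size_um)


@pytest.fixture
def full_mask():
    return make_mask()


@pytest.fixture
def clean_nlo_params():
    """A small noise-free, artifact-free FOV for fast exact checks."""
    return PhenotypeParams(
        fov_px=160, n_cells_per_fov=3, cell_radius_um=5.0,
        noise_sd=0.0, outlier_rate=0.0, serpentine_shift_px=0,
    )


@pytest.fixture
def qpi_sphere_params():
    """A single spherical cell, no lipid, no noise: analytic phantom."""
    return PhenotypeParams(
        n_cells_per_fov=0, n_cells_per_tomogram=1,
        cell_radius_um=5.0, cell_thickness_um=10.0, shape_jitter=0.0,
        droplet_density_per_cell=0.0, noise_sd=0.0,
    )
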