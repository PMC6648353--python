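"""Shared fixtures: small phantoms, coil profiles and masks.

Everything is generated at test time on 32^3 grids with 4 mm voxels so the
whole suite stays fast; session scope because the generators are pure.
"""

import numpy as np
import pytest

from coilbias.synthetic import (CoilProfile, make_coil_profile,
                                make_diffusion_scheme, make_tensor_truth,
                                make_tissue_phantom)

GRID = (32, 32, 32)
VOXEL_MM = 4.0


@pytest.fixture(scope="session")
def phantom():
    return make_tissue_phantom(GRID, VOXEL_MM, seed=5)


@pytest.fixture(scope="session")
def coil8():
    return make_coil_profile("eight_ch", GRID, VOXEL_MM)


@pytest.fixture(scope="session")
def coil32():
    return make_coil_profile("thirty_two_ch", GRID, VOXEL_MM)


@pytest.fixture(scope="session")
def flat_coil():
    """Unit gain, noiseless: for exactness tests."""
    return CoilProfile("eight_ch", np.ones(GRID), 0.0, VOXEL_MM)


@pytest.fixture(scope="session")
def scheme():
    return make_diffusion_scheme()


@pytest.fixture(scope="session")
def tensor_truth(phantom):
    return make_tensor_truth(phantom)


@pytest.fixture(scope="session")
def ball_mask():
    """Spherical analysis mask on the 32^3 grid (~9300 voxels)."""
    x, y, z = np.meshgrid(*[np.arange(32)] * 3, indexing="ij")
    return ((x - 15.5) ** 2 + (y - 15.5) ** 2 + (z - 15.5) ** 2) < 13**2


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
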