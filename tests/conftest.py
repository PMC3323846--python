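"""Shared fixtures: a hexagonal mini-scanner small enough for brute-force
oracles (dense matrices, exhaustive orbit enumeration) yet non-degenerate
(2 x 2 crystals per module, 24-element symmetry group)."""

import numpy as np
import pytest

from blobpet.blobgrid import BlobParams, build_polar_grid
from blobpet.geometry import ScannerSpec, build_symmetry_lut
from blobpet.srm import analytic_srm_full, analytic_srm_wedge


@pytest.fixture(scope="session")
def mini_spec():
    return ScannerSpec(
        n_modules=6, n_layers=1, crystals_tangential=2, crystals_axial=2,
        crystal_size_mm=((3.0, 3.0, 8.0),), layer_face_radius_mm=(12.0,),
        axial_pitch_mm=3.0, tangential_pitch_mm=3.0)


@pytest.fixture(scope="session")
def mini_grid():
    return build_polar_grid(2, 12, 2, 3.0, params=BlobParams(delta=3.0),
                            n_modules=6)


@pytest.fixture(scope="session")
def mini_lut(mini_spec, mini_grid):
    return build_symmetry_lut(mini_spec, mini_grid)


@pytest.fixture(scope="session")
def mini_srm(mini_spec, mini_grid, mini_lut):
    """Wedge-folded analytic SRM, no element floor (keeps tiny entries so
    fold/unfold comparisons are exact)."""
    return analytic_srm_wedge(mini_spec, mini_grid, mini_lut, n_rays=4,
                              floor=0.0)


@pytest.fixture(scope="session")
def mini_srm_full(mini_spec, mini_grid):
    """Brute-force SRM over all blobs, built without any symmetry use."""
    return analytic_srm_full(mini_spec, mini_grid, n_rays=4, floor=0.0)


@pytest.fixture(scope="session")
def default_spec():
    return ScannerSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20120402)
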