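"""Shared fixtures: coarse phantoms and handcrafted voxel models.

All test inputs are generated programmatically; grids are kept coarse so
the whole suite stays interactive.
"""

from __future__ import annotations

import numpy as np
import pytest

from autobeam.dose import KernelParams
from autobeam.grid import GridGeometry
from autobeam.phantoms import AnatomySpec, PatientModel, generate_patient

COARSE_GRID = GridGeometry(16.0, (20, 14, 18))


@pytest.fixture(scope="session")
def coarse_grid() -> GridGeometry:
    return COARSE_GRID


@pytest.fixture(scope="session")
def coarse_model(coarse_grid) -> PatientModel:
    """Median-volume patient on the 16 mm study grid."""
    return generate_patient(
        AnatomySpec(ptv_target_volume_cc=605.0), seed=1, grid=coarse_grid
    )


@pytest.fixture(scope="session")
def coarse_kernel() -> KernelParams:
    return KernelParams(sigma_penumbra_mm=16.0)


def make_slab_model(
    shape=(12, 12, 8), voxel_mm=10.0, ptv_size=(2, 2, 2), density=1.0
) -> PatientModel:
    """Homogeneous box patient with a central cuboid PTV and 1-voxel organs.

    Used for closed-form dose checks where analytic geometry must be exact.
    """
    grid = GridGeometry(voxel_mm, shape)
    full = np.ones(shape, dtype=bool)
    masks = {name: np.zeros(shape, dtype=bool) for name in
             ("PTV", "lung_L", "lung_R", "heart", "breast_L", "breast_R")}
    masks["patient"] = full
    cx, cy, cz = (s // 2 for s in shape)
    px, py, pz = ptv_size
    masks["PTV"][cx - px // 2 : cx - px // 2 + px,
                 cy - py // 2 : cy - py // 2 + py,
                 cz - pz // 2 : cz - pz // 2 + pz] = True
    # park the organs in distinct corners, away from the target
    organ_voxels = {
        "lung_L": (shape[0] - 1, 0, 0),
        "lung_R": (0, 0, 0),
        "heart": (0, shape[1] - 1, 0),
        "breast_L": (shape[0] - 1, shape[1] - 1, 0),
        "breast_R": (0, 0, shape[2] - 1),
    }
    for name, idx in organ_voxels.items():
        masks[name][idx] = True
    dens = np.zeros(shape)
    dens[full] = density
    model = PatientModel(
        grid=grid, masks=masks, density=dens, flags=AnatomySpec(), seed=0
    )
    model.validate()
    return model


@pytest.fixture(scope="session")
def slab_model() -> PatientModel:
    return make_slab_model()
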