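"""Voxel-grid geometry shared by phantom generation, dose calculation and metrics.

Axes follow a patient-centric convention with the isocenter at the grid
center: x runs right→left, y posterior→anterior, z inferior→superior.
All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry", "DEFAULT_GRID"]


@dataclass(frozen=True)
class GridGeometry:
    """Isotropic voxel lattice centred on the isocenter.

    Parameters
    ----------
    voxel_size_mm:
        Edge length of the (cubic) voxels.
    shape:
        Voxel counts along (x, y, z).
    """

    voxel_size_mm: float = 4.0
    shape: tuple[int, int, int] = (80, 55, 70)

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape!r}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (1 cc = 1000 mm^3)."""
        return self.voxel_size_mm**3 / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size_mm for s in self.shape)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis, centred on 0."""
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size_mm

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) voxel-centre coordinate arrays."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def points(self) -> np.ndarray:
        """All voxel centres as an (n_voxels, 3) array in C order."""
        x, y, z = self.coordinate_grids()
        pts = np.empty(self.shape + (3,), dtype=float)
        pts[..., 0], pts[..., 1], pts[..., 2] = np.broadcast_arrays(x, y, z)
        return pts.reshape(-1, 3)

    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to mm coordinates."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        for ax in range(3):
            aff[ax, 3] = -(self.shape[ax] - 1) / 2.0 * self.voxel_size_mm
        return aff

    def mask_volume_cc(self, mask: np.ndarray) -> float:
        """cc occupied by a boolean mask: voxel count times voxel volume."""
        return float(np.count_nonzero(mask)) * self.voxel_volume_cc


DEFAULT_GRID = GridGeometry()
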