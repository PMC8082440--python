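"""Analytic beamlet dose-influence engine.

A transparent substitute for a full transport engine: parallel
(non-divergent) beams of Gaussian pencil beamlets with exponential
attenuation along density-weighted (radiological) depth. Good enough to
compare beam-direction geometry; explicitly not a clinical dose model.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy import ndimage, sparse

from .beams import BeamDirection
from .phantoms import PatientModel

__all__ = [
    "KernelParams",
    "BeamletGrid",
    "DoseInfluence",
    "build_beamlet_grid",
    "compute_influence",
    "total_dose",
    "save_influence",
    "load_influence",
]

#: influence entries below this fraction of the per-beamlet maximum are dropped
TRUNCATION_FRACTION = 1e-4


@dataclass(frozen=True)
class KernelParams:
    """Pencil-kernel parameters of the analytic engine.

    mu is the effective linear attenuation per mm of water-equivalent depth
    (6 MV-like default), sigma_penumbra_mm the lateral Gaussian spread and
    output_factor the surface dose in Gy per unit fluence.
    """

    mu_per_mm: float = 0.005
    sigma_penumbra_mm: float = 4.0
    output_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_per_mm <= 0:
            raise ValueError("mu_per_mm must be positive")
        if self.sigma_penumbra_mm <= 0:
            raise ValueError("sigma_penumbra_mm must be positive")


def _beam_basis(beam: BeamDirection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed (u, v, w) frame: w = propagation, (u, v) = beam's-eye view."""
    w = -beam.unit_vector  # propagation: source toward isocenter
    z = np.array([0.0, 0.0, 1.0])
    u = np.cross(z, w)
    nu = np.linalg.norm(u)
    if nu < 1e-9:  # beam along the z axis
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = u / nu
    v = np.cross(w, u)
    return u, v, w


@dataclass(frozen=True)
class BeamletGrid:
    """Rectangular beamlet lattice in the beam's-eye-view plane."""

    beam: BeamDirection
    beamlet_size_mm: float
    centers: np.ndarray  # (n_beamlets, 2) (u, v) offsets at isocenter

    @property
    def n_beamlets(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class DoseInfluence:
    """Sparse linear map from beamlet fluence to voxel dose for one beam."""

    beam: BeamDirection
    matrix: sparse.csc_matrix  # (n_voxels, n_beamlets), Gy per unit fluence
    grid_shape: tuple[int, int, int]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]


def build_beamlet_grid(
    model: PatientModel,
    beam: BeamDirection,
    beamlet_size_mm: float = 10.0,
    margin_mm: float = 10.0,
) -> BeamletGrid:
    """Lattice covering the PTV's orthographic projection plus a margin."""
    ptv = model.masks["PTV"]
    if not ptv.any():
        raise ValueError("PTV is empty; cannot build a beamlet grid")
    u, v, _ = _beam_basis(beam)
    pts = model.grid.points()[ptv.reshape(-1)]
    pu = pts @ u
    pv = pts @ v
    lo_u, hi_u = pu.min() - margin_mm, pu.max() + margin_mm
    lo_v, hi_v = pv.min() - margin_mm, pv.max() + margin_mm
    nu = max(1, int(np.ceil((hi_u - lo_u) / beamlet_size_mm)))
    nv = max(1, int(np.ceil((hi_v - lo_v) / beamlet_size_mm)))
    cu = 0.5 * (lo_u + hi_u) + (np.arange(nu) - (nu - 1) / 2.0) * beamlet_size_mm
    cv = 0.5 * (lo_v + hi_v) + (np.arange(nv) - (nv - 1) / 2.0) * beamlet_size_mm
    uu, vv = np.meshgrid(cu, cv, indexing="ij")
    centers = np.column_stack([uu.ravel(), vv.ravel()])
    return BeamletGrid(beam=beam, beamlet_size_mm=beamlet_size_mm, centers=centers)


def _radiological_depth(
    model: PatientModel, w: np.ndarray, points: np.ndarray, step_mm: float
) -> np.ndarray:
    """Density-weighted depth from the grid boundary to each point along -w.

    Sampled by stepping upstream through the (zero-padded) density volume
    with trilinear interpolation; densities are zero outside the patient so
    the integral starts at the patient surface.
    """
    grid = model.grid
    extent = np.linalg.norm(grid.extent_mm)
    n_steps = int(np.ceil(extent / step_mm))
    # voxel-index coordinates of sample points for map_coordinates
    origin = np.array([grid.axis_coords(ax)[0] for ax in range(3)])
    inv = 1.0 / grid.voxel_size_mm
    depth = np.zeros(len(points))
    offs = (np.arange(n_steps) + 0.5) * step_mm
    # process in chunks to bound memory
    chunk = max(1, int(2e6 / n_steps))
    for start in range(0, len(points), chunk):
        p = points[start : start + chunk]
        sample = p[:, None, :] - offs[None, :, None] * w[None, None, :]
        idx = (sample - origin) * inv
        dens = ndimage.map_coordinates(
            model.density, idx.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
        ).reshape(len(p), n_steps)
        depth[start : start + chunk] = dens.sum(axis=1) * step_mm
    return depth


def compute_influence(
    model: PatientModel,
    grid: BeamletGrid,
    params: KernelParams = KernelParams(),
    depth_step_mm: float | None = None,
) -> DoseInfluence:
    """Dose per unit fluence for every (patient voxel, beamlet) pair.

    matrix[v, j] = output_factor * exp(-mu * d_rad(v)) * exp(-r(v, j)^2 / (2 sigma^2))
    with d_rad the radiological depth of voxel v along the beam axis and r
    its lateral distance from beamlet j's ray. Entries below 1e-4 of the
    beamlet maximum are truncated to zero; voxels outside the patient get
    all-zero rows.
    """
    g = model.grid
    u, v, w = _beam_basis(grid.beam)
    patient = model.masks["patient"].reshape(-1)
    pts = g.points()[patient]
    if depth_step_mm is None:
        depth_step_mm = g.voxel_size_mm / 2.0
    depth = _radiological_depth(model, w, pts, depth_step_mm)
    axial = params.output_factor * np.exp(-params.mu_per_mm * depth)
    pu = pts @ u
    pv = pts @ v
    sigma = params.sigma_penumbra_mm
    # lateral cutoff where the Gaussian alone falls below the truncation level
    r_cut = sigma * np.sqrt(-2.0 * np.log(TRUNCATION_FRACTION))
    voxel_ids = np.flatnonzero(patient)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for j, (cu, cv) in enumerate(grid.centers):
        near = (np.abs(pu - cu) <= r_cut) & (np.abs(pv - cv) <= r_cut)
        if not near.any():
            continue
        r2 = (pu[near] - cu) ** 2 + (pv[near] - cv) ** 2
        dose = axial[near] * np.exp(-r2 / (2.0 * sigma**2))
        keep = dose >= TRUNCATION_FRACTION * dose.max()
        rows.append(voxel_ids[near][keep])
        cols.append(np.full(int(keep.sum()), j))
        vals.append(dose[keep])
    if rows:
        matrix = sparse.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(g.n_voxels, grid.n_beamlets),
        )
    else:
        matrix = sparse.csc_matrix((g.n_voxels, grid.n_beamlets))
    return DoseInfluence(beam=grid.beam, matrix=matrix, grid_shape=g.shape)


def total_dose(influences: list[DoseInfluence], fluence: np.ndarray) -> np.ndarray:
    """Total voxel dose (flat array) for a concatenated fluence vector."""
    fluence = np.asarray(fluence, dtype=float)
    n_total = sum(inf.n_beamlets for inf in influences)
    if fluence.shape != (n_total,):
        raise ValueError(f"fluence length {fluence.shape} != total beamlets {n_total}")
    if (fluence < 0).any():
        raise ValueError("fluence must be nonnegative")
    if not influences:
        return np.zeros(0)
    dose = np.zeros(influences[0].matrix.shape[0])
    offset = 0
    for inf in influences:
        nb = inf.n_beamlets
        dose += inf.matrix @ fluence[offset : offset + nb]
        offset += nb
    return dose


def save_influence(influence: DoseInfluence, path) -> None:
    coo = influence.matrix.tocoo()
    with h5py.File(path, "w") as fh:
        fh.create_dataset("row", data=coo.row)
        fh.create_dataset("col", data=coo.col)
        fh.create_dataset("val", data=coo.data)
        fh.attrs["shape"] = influence.matrix.shape
        fh.attrs["grid_shape"] = influence.grid_shape
        fh.attrs["gantry_deg"] = influence.beam.gantry_deg
        fh.attrs["couch_deg"] = influence.beam.couch_deg


def load_influence(path) -> DoseInfluence:
    with h5py.File(path, "r") as fh:
        matrix = sparse.csc_matrix(
            (fh["val"][:], (fh["row"][:], fh["col"][:])),
            shape=tuple(fh.attrs["shape"]),
        )
        beam = BeamDirection(float(fh.attrs["gantry_deg"]), float(fh.attrs["couch_deg"]))
        grid_shape = tuple(int(s) for s in fh.attrs["grid_shape"])
    return DoseInfluence(beam=beam, matrix=matrix, grid_shape=grid_shape)
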