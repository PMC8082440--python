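"""Seeded synthetic female-thorax phantom generation.

Patient models are built from parameterized geometric primitives: an
elliptic-cylinder torso, two ellipsoidal low-density lungs, an ellipsoidal
heart sitting anterior-inferior between the lungs, anterior hemispherical
breasts, and a mediastinal-tube target volume (PTV) with optional
supraclavicular and axillary lobes. Anatomy flags and a target PTV volume
control the variability across a generated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml

from .grid import DEFAULT_GRID, GridGeometry

__all__ = [
    "AnatomySpec",
    "CohortSpec",
    "PatientModel",
    "InfeasibleAnatomyError",
    "generate_patient",
    "generate_cohort",
    "save_patient",
    "load_patient",
]

STRUCTURES = ("PTV", "lung_L", "lung_R", "heart", "breast_L", "breast_R", "patient")
#: organs whose masks must be pairwise disjoint
ORGANS = ("lung_L", "lung_R", "heart", "breast_L", "breast_R")

LUNG_DENSITY = 0.25
SOFT_TISSUE_DENSITY = 1.0

#: realized-volume contract of :func:`generate_patient`
VOLUME_TOLERANCE = 0.10

#: study-cohort PTV volume distribution (cc)
COHORT_VOLUME_MEDIAN_CC = 605.0
COHORT_VOLUME_RANGE_CC = (97.0, 1654.0)
# sigma chosen so that clipping to the range affects <5% of log-normal draws
COHORT_VOLUME_SIGMA_LOG = 0.55

DEFAULT_FLAG_PROBABILITIES: dict[str, float] = {
    "supraclavicular_L": 0.3,
    "supraclavicular_R": 0.3,
    "axillary_L": 0.2,
    "axillary_R": 0.2,
    "bulky": 0.25,
}


class InfeasibleAnatomyError(ValueError):
    """Requested anatomy cannot be realized on the given grid."""


@dataclass(frozen=True)
class AnatomySpec:
    """Per-patient anatomical parameters.

    ``superior_extent`` / ``inferior_extent`` are the cranio-caudal limits of
    the mediastinal target tube, in mm relative to the isocenter (z axis,
    superior positive). ``lateral_asymmetry`` shifts the PTV centroid off the
    midline (positive toward the patient's left).
    """

    ptv_target_volume_cc: float = COHORT_VOLUME_MEDIAN_CC
    superior_extent_mm: float = 100.0
    inferior_extent_mm: float = -60.0
    supraclavicular: tuple[bool, bool] = (False, False)  # (left, right)
    axillary: tuple[bool, bool] = (False, False)  # (left, right)
    bulky: bool = False
    lateral_asymmetry_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.ptv_target_volume_cc <= 0:
            raise ValueError("ptv_target_volume_cc must be positive")
        if self.superior_extent_mm <= self.inferior_extent_mm:
            raise ValueError("superior_extent_mm must exceed inferior_extent_mm")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling parameters for a synthetic patient cohort.

    PTV volumes are drawn log-normally with the given median and log-scale
    sigma, clipped to ``volume_range_cc``; anatomy flags are independent
    Bernoulli draws. Per-patient seeds are ``seed + patient_index``.
    """

    n_patients: int = 25
    seed: int = 0
    volume_median_cc: float = COHORT_VOLUME_MEDIAN_CC
    volume_sigma_log: float = COHORT_VOLUME_SIGMA_LOG
    volume_range_cc: tuple[float, float] = COHORT_VOLUME_RANGE_CC
    flag_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLAG_PROBABILITIES)
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not all(0.0 <= p <= 1.0 for p in self.flag_probabilities.values()):
            raise ValueError("flag probabilities must lie in [0, 1]")
        if self.volume_range_cc[0] >= self.volume_range_cc[1]:
            raise ValueError("volume_range_cc must be increasing")


@dataclass
class PatientModel:
    """Voxelized anatomy: structure masks, density and grid geometry."""

    grid: GridGeometry
    masks: dict[str, np.ndarray]
    density: np.ndarray
    flags: AnatomySpec
    seed: int

    def structure_volume_cc(self, name: str) -> float:
        return self.grid.mask_volume_cc(self.masks[name])

    def structure_mask(self, name: str) -> np.ndarray:
        """Mask by name; 'lungs' and 'breasts' resolve to side unions."""
        if name == "lungs":
            return self.masks["lung_L"] | self.masks["lung_R"]
        if name == "breasts":
            return self.masks["breast_L"] | self.masks["breast_R"]
        return self.masks[name]

    @property
    def ptv_volume_cc(self) -> float:
        return self.structure_volume_cc("PTV")

    def validate(self) -> None:
        """Assert all model invariants; raises AssertionError on violation."""
        patient = self.masks["patient"]
        assert self.masks["PTV"].any(), "PTV is empty"
        for name in STRUCTURES:
            assert self.masks[name].shape == self.grid.shape
            assert self.masks[name].dtype == bool
            assert not (self.masks[name] & ~patient).any(), f"{name} outside patient"
        for i, a in enumerate(ORGANS):
            for b in ORGANS[i + 1 :]:
                assert not (self.masks[a] & self.masks[b]).any(), f"{a} ∩ {b} != 0"
        assert (self.density[patient] > 0).all(), "zero density inside patient"
        assert (self.density[~patient] == 0).all(), "nonzero density outside patient"


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _build_ptv(
    coords,
    spec: AnatomySpec,
    scale: float,
    torso: np.ndarray,
    wobble: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
) -> np.ndarray:
    """Target mask at a given uniform transverse scale, clipped to the torso.

    ``wobble`` bends the tube axis gently along z (amplitudes and phases in
    mm/rad). Besides looking like a real, curved mediastinal axis, the bend
    staggers voxel-boundary crossings so the realized volume varies smoothly
    with ``scale`` even on coarse grids.
    """
    x, y, z = coords
    a0, b0 = 30.0, 24.0  # base transverse semi-axes (lateral, AP), mm
    if spec.bulky:
        a0 *= 1.4
    length = spec.superior_extent_mm - spec.inferior_extent_mm
    wx, wy, px, py = wobble
    cx = spec.lateral_asymmetry_mm + wx * np.sin(2.0 * np.pi * z / length + px)
    cy = 15.0 + wy * np.cos(2.0 * np.pi * z / length + py)
    tube = (
        (((x - cx) / (a0 * scale)) ** 2 + ((y - cy) / (b0 * scale)) ** 2 <= 1.0)
        & (z >= spec.inferior_extent_mm)
        & (z <= spec.superior_extent_mm)
    )
    ptv = tube
    lobe_scale = max(scale, 0.4)
    z_top = spec.superior_extent_mm
    for side, present in zip((+1, -1), spec.supraclavicular):
        if present:
            ptv = ptv | _ellipsoid(
                coords,
                (side * 40.0, 25.0, z_top + 10.0),
                (25.0 * lobe_scale, 20.0 * lobe_scale, 25.0 * lobe_scale),
            )
    for side, present in zip((+1, -1), spec.axillary):
        if present:
            ptv = ptv | _ellipsoid(
                coords,
                (side * 95.0, 20.0, z_top - 20.0),
                (30.0 * lobe_scale, 25.0 * lobe_scale, 30.0 * lobe_scale),
            )
    return ptv & torso


def generate_patient(
    spec: AnatomySpec,
    seed: int,
    grid: GridGeometry = DEFAULT_GRID,
) -> PatientModel:
    """Build a deterministic synthetic patient from an anatomy spec.

    The realized PTV volume matches ``spec.ptv_target_volume_cc`` within
    ±10% (the transverse extent of the target tube is solved for by
    bisection). Raises :class:`InfeasibleAnatomyError` when the requested
    volume cannot be fitted into the mediastinal envelope on this grid.
    """
    half_z = grid.extent_mm[2] / 2.0
    if spec.superior_extent_mm > half_z or spec.inferior_extent_mm < -half_z:
        raise InfeasibleAnatomyError(
            f"target extents [{spec.inferior_extent_mm}, {spec.superior_extent_mm}] mm "
            f"exceed the grid z half-extent {half_z} mm"
        )

    rng = np.random.default_rng(seed)
    coords = grid.coordinate_grids()
    x, y, z = coords

    # torso: elliptic cylinder with mild per-patient size jitter
    torso_ax = 140.0 + rng.normal(0.0, 6.0)
    torso_ay = 90.0 + rng.normal(0.0, 4.0)
    torso = (x / torso_ax) ** 2 + (y / torso_ay) ** 2 <= 1.0

    lungs = {}
    for name, side in (("lung_L", +1), ("lung_R", -1)):
        center = (
            side * (72.0 + rng.normal(0.0, 3.0)),
            -5.0 + rng.normal(0.0, 3.0),
            10.0 + rng.normal(0.0, 5.0),
        )
        semi = (
            50.0 + rng.normal(0.0, 2.0),
            65.0 + rng.normal(0.0, 2.0),
            105.0 + rng.normal(0.0, 4.0),
        )
        lungs[name] = _ellipsoid(coords, center, semi) & torso

    heart = (
        _ellipsoid(
            coords,
            (-12.0 + rng.normal(0.0, 2.0), 5.0, -45.0 + rng.normal(0.0, 3.0)),
            (42.0, 42.0, 52.0),
        )
        & torso
    )

    breasts = {}
    breast_r = 45.0 + rng.normal(0.0, 4.0)
    for name, side in (("breast_L", +1), ("breast_R", -1)):
        bx = side * 55.0
        by = torso_ay * np.sqrt(max(0.0, 1.0 - (bx / torso_ax) ** 2))
        sphere = _ellipsoid(coords, (bx, by, -40.0), (breast_r, breast_r, breast_r))
        breasts[name] = sphere & (side * x > 0)

    patient = torso | breasts["breast_L"] | breasts["breast_R"]

    # solve the transverse PTV scale for the target volume by bisection
    target = spec.ptv_target_volume_cc
    wobble = (
        float(rng.uniform(3.0, 8.0)),
        float(rng.uniform(3.0, 8.0)),
        float(rng.uniform(0.0, 2.0 * np.pi)),
        float(rng.uniform(0.0, 2.0 * np.pi)),
    )
    lo, hi = 0.05, 6.0
    if grid.mask_volume_cc(_build_ptv(coords, spec, hi, patient, wobble)) < target * (
        1.0 - VOLUME_TOLERANCE
    ):
        raise InfeasibleAnatomyError(
            f"target volume {target} cc does not fit the torso envelope"
        )
    ptv = best_ptv = None
    best_err = np.inf
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        ptv = _build_ptv(coords, spec, mid, patient, wobble)
        vol = grid.mask_volume_cc(ptv)
        if abs(vol - target) < best_err and ptv.any():
            best_err, best_ptv = abs(vol - target), ptv
        if abs(vol - target) <= 0.02 * target:
            break
        if vol < target:
            lo = mid
        else:
            hi = mid
    ptv = best_ptv
    vol = grid.mask_volume_cc(ptv)
    if not ptv.any() or abs(vol - target) > VOLUME_TOLERANCE * target:
        raise InfeasibleAnatomyError(
            f"realized PTV volume {vol:.1f} cc misses target {target} cc by >10%"
        )

    # carve overlaps so organ masks are pairwise disjoint (PTV has priority)
    taken = ptv.copy()
    masks: dict[str, np.ndarray] = {"PTV": ptv}
    for name, m in (
        ("heart", heart),
        ("lung_L", lungs["lung_L"]),
        ("lung_R", lungs["lung_R"]),
        ("breast_L", breasts["breast_L"]),
        ("breast_R", breasts["breast_R"]),
    ):
        m = m & ~taken
        taken |= m
        masks[name] = m
    masks["patient"] = patient

    density = np.zeros(grid.shape, dtype=float)
    density[patient] = SOFT_TISSUE_DENSITY
    density[masks["lung_L"] | masks["lung_R"]] = LUNG_DENSITY

    model = PatientModel(grid=grid, masks=masks, density=density, flags=spec, seed=seed)
    model.validate()
    return model


def draw_anatomy_spec(cohort: CohortSpec, rng: np.random.Generator) -> AnatomySpec:
    """Sample one AnatomySpec from the cohort distribution."""
    lo, hi = cohort.volume_range_cc
    volume = float(
        np.clip(
            np.exp(np.log(cohort.volume_median_cc) + cohort.volume_sigma_log * rng.standard_normal()),
            lo,
            hi,
        )
    )
    p = cohort.flag_probabilities
    flag = lambda key: bool(rng.random() < p.get(key, 0.0))
    return AnatomySpec(
        ptv_target_volume_cc=volume,
        superior_extent_mm=float(rng.uniform(60.0, 120.0)),
        inferior_extent_mm=float(rng.uniform(-100.0, -20.0)),
        supraclavicular=(flag("supraclavicular_L"), flag("supraclavicular_R")),
        axillary=(flag("axillary_L"), flag("axillary_R")),
        bulky=flag("bulky"),
        lateral_asymmetry_mm=float(rng.normal(0.0, 12.0)),
    )


def generate_cohort(
    cohort: CohortSpec, grid: GridGeometry = DEFAULT_GRID
) -> list[PatientModel]:
    """Generate ``cohort.n_patients`` independent patients, reproducibly.

    Patient ``i`` uses seed ``cohort.seed + i`` both for spec sampling and
    geometry jitter, so cohorts are identical across runs and patients are
    insensitive to the presence of other patients.
    """
    models = []
    for i in range(cohort.n_patients):
        patient_seed = cohort.seed + i
        rng = np.random.default_rng(patient_seed)
        spec = draw_anatomy_spec(cohort, rng)
        models.append(generate_patient(spec, seed=patient_seed, grid=grid))
    return models


# ---------------------------------------------------------------------------
# serialization


def _spec_to_dict(spec: AnatomySpec) -> dict:
    return {
        "ptv_target_volume_cc": spec.ptv_target_volume_cc,
        "superior_extent_mm": spec.superior_extent_mm,
        "inferior_extent_mm": spec.inferior_extent_mm,
        "supraclavicular": list(spec.supraclavicular),
        "axillary": list(spec.axillary),
        "bulky": spec.bulky,
        "lateral_asymmetry_mm": spec.lateral_asymmetry_mm,
    }


def _spec_from_dict(d: dict) -> AnatomySpec:
    d = dict(d)
    for key in ("supraclavicular", "axillary"):
        d[key] = tuple(bool(v) for v in d[key])
    return AnatomySpec(**d)


def save_patient(model: PatientModel, directory) -> None:
    """Write one NIfTI per structure plus density and a YAML sidecar."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = model.grid.affine()
    for name, mask in model.masks.items():
        img = nib.Nifti1Image(mask.astype(np.uint8), affine)
        nib.save(img, directory / f"mask_{name}.nii")
    nib.save(nib.Nifti1Image(model.density, affine), directory / "density.nii")
    meta = {
        "seed": model.seed,
        "voxel_size_mm": model.grid.voxel_size_mm,
        "shape": list(model.grid.shape),
        "flags": _spec_to_dict(model.flags),
    }
    with open(directory / "patient.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_patient(directory) -> PatientModel:
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "patient.yaml") as fh:
        meta = yaml.safe_load(fh)
    grid = GridGeometry(meta["voxel_size_mm"], tuple(meta["shape"]))
    masks = {
        name: np.asarray(nib.load(directory / f"mask_{name}.nii").dataobj).astype(bool)
        for name in STRUCTURES
    }
    density = np.asarray(nib.load(directory / "density.nii").dataobj, dtype=float)
    return PatientModel(
        grid=grid,
        masks=masks,
        density=density,
        flags=_spec_from_dict(meta["flags"]),
        seed=int(meta["seed"]),
    )
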