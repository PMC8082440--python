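"""Exact DVH analytics, clinical plan parameters and goal checking.

Conventions: Vx counts voxels with dose >= threshold; percentage-of-
prescription thresholds are relative to the 30 Gy prescription (so V95% is
evaluated at 28.5 Gy); absolute volumes are voxel count x voxel volume with
no sub-voxel interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .phantoms import PatientModel

__all__ = [
    "PlanMetrics",
    "GoalReport",
    "compute_dvh",
    "compute_metrics",
    "check_goals",
]

DEFAULT_PRESCRIPTION_GY = 30.0


@dataclass(frozen=True)
class PlanMetrics:
    """Clinical plan parameters of a single plan (percent, Gy, cc)."""

    ptv_v95_pct: float
    ptv_vunder90_cc: float
    ptv_v107_pct: float
    ci: float
    heart_dmean_gy: float
    lungs_dmean_gy: float
    breast_l_dmean_gy: float
    breast_r_dmean_gy: float
    breast_l_v4_pct: float
    breast_r_v4_pct: float
    lungs_v5_pct: float
    lungs_v20_pct: float
    patient_v5_cc: float
    patient_v20_cc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class GoalResult:
    name: str
    threshold: float
    achieved: float
    passes: bool
    preferred_threshold: float | None = None
    preferred_passes: bool | None = None


@dataclass(frozen=True)
class GoalReport:
    goals: tuple[GoalResult, ...]
    coverage_ok: bool

    def as_dict(self) -> dict:
        return {
            "coverage_ok": self.coverage_ok,
            "goals": [asdict(g) for g in self.goals],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def compute_dvh(
    dose: np.ndarray, mask: np.ndarray, bin_width_gy: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-volume histogram of a structure.

    Returns (thresholds_gy, volume_pct) where volume_pct[i] is the
    percentage of the structure receiving at least thresholds_gy[i]. The
    curve starts at 100% for 0 Gy and is monotone non-increasing.
    """
    d = np.asarray(dose)[np.asarray(mask, dtype=bool)]
    if d.size == 0:
        raise ValueError("DVH of an empty mask")
    top = max(float(d.max()), bin_width_gy)
    thresholds = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    volume_pct = np.array([100.0 * np.mean(d >= t) for t in thresholds])
    return thresholds, volume_pct


def _v_pct(d: np.ndarray, threshold: float) -> float:
    return float(100.0 * np.mean(d >= threshold))


def compute_metrics(
    dose: np.ndarray,
    model: PatientModel,
    prescription_gy: float = DEFAULT_PRESCRIPTION_GY,
) -> PlanMetrics:
    """All reported plan parameters for one dose distribution."""
    dose = np.asarray(dose)
    if dose.shape != model.grid.shape:
        dose = dose.reshape(model.grid.shape)
    for name in ("PTV", "patient", "heart", "lung_L", "lung_R", "breast_L", "breast_R"):
        if name not in model.masks:
            raise ValueError(f"missing structure mask {name!r}")

    vox_cc = model.grid.voxel_volume_cc
    t95 = 0.95 * prescription_gy
    t90 = 0.90 * prescription_gy
    t107 = 1.07 * prescription_gy

    ptv = dose[model.masks["PTV"]]
    patient = dose[model.masks["patient"]]
    lungs = dose[model.structure_mask("lungs")]
    heart = dose[model.masks["heart"]]
    breast_l = dose[model.masks["breast_L"]]
    breast_r = dose[model.masks["breast_R"]]

    ptv_volume_cc = model.structure_volume_cc("PTV")
    patient_v95_cc = float(np.count_nonzero(patient >= t95)) * vox_cc

    return PlanMetrics(
        ptv_v95_pct=_v_pct(ptv, t95),
        ptv_vunder90_cc=float(np.count_nonzero(ptv < t90)) * vox_cc,
        ptv_v107_pct=_v_pct(ptv, t107),
        ci=patient_v95_cc / ptv_volume_cc,
        heart_dmean_gy=float(heart.mean()),
        lungs_dmean_gy=float(lungs.mean()),
        breast_l_dmean_gy=float(breast_l.mean()),
        breast_r_dmean_gy=float(breast_r.mean()),
        breast_l_v4_pct=_v_pct(breast_l, 4.0),
        breast_r_v4_pct=_v_pct(breast_r, 4.0),
        lungs_v5_pct=_v_pct(lungs, 5.0),
        lungs_v20_pct=_v_pct(lungs, 20.0),
        patient_v5_cc=float(np.count_nonzero(patient >= 5.0)) * vox_cc,
        patient_v20_cc=float(np.count_nonzero(patient >= 20.0)) * vox_cc,
    )


#: (name, metric attribute, required threshold, preferred threshold, direction)
_GOAL_DEFS = (
    ("ptv_v95", "ptv_v95_pct", 95.0, None, ">="),
    ("ptv_vunder90", "ptv_vunder90_cc", 5.0, 2.0, "<"),
    ("breast_l_dmean", "breast_l_dmean_gy", 5.0, 2.0, "<"),
    ("breast_r_dmean", "breast_r_dmean_gy", 5.0, 2.0, "<"),
    ("heart_dmean", "heart_dmean_gy", 26.0, 10.0, "<"),
    ("lungs_dmean", "lungs_dmean_gy", 15.0, 13.5, "<"),
    ("lungs_v5", "lungs_v5_pct", 55.0, 50.0, "<"),
    ("lungs_v20", "lungs_v20_pct", 30.0, None, "<"),
)


def check_goals(metrics: PlanMetrics) -> GoalReport:
    """Evaluate every protocol goal (required and preferred thresholds).

    ``coverage_ok`` is True iff PTV V95% >= 95 (the only requirement treated
    as truly hard).
    """
    results = []
    md = metrics.as_dict()
    for name, attr, required, preferred, direction in _GOAL_DEFS:
        achieved = md[attr]
        if direction == ">=":
            passes = achieved >= required
            pref_pass = None if preferred is None else achieved >= preferred
        else:
            passes = achieved < required
            pref_pass = None if preferred is None else achieved < preferred
        results.append(
            GoalResult(
                name=name,
                threshold=required,
                achieved=achieved,
                passes=passes,
                preferred_threshold=preferred,
                preferred_passes=pref_pass,
            )
        )
    coverage_ok = metrics.ptv_v95_pct >= 95.0
    return GoalReport(goals=tuple(results), coverage_ok=coverage_ok)
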