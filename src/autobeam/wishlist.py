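"""Prioritized multi-criteria ("wish-list") fluence optimization.

A wish-list holds hard constraints plus an ordered list of convex
objectives with goal values. Plans are produced by sequential solves, one
per priority: minimize the current objective subject to the hard
constraints and epsilon-constraints pinning every higher-priority
objective at ``max(goal, achieved * (1 + slack))``. Each stage is a linear
program (all supported objectives are LP-representable via auxiliary
variables); gEUD with a != 1 falls back to an SLSQP solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import sparse
from scipy.optimize import linprog

from .beams import BeamSet
from .dose import DoseInfluence, total_dose
from .phantoms import PatientModel

__all__ = [
    "HardConstraint",
    "Objective",
    "WishList",
    "Plan",
    "StageInfeasibleError",
    "SolverError",
    "evaluate_objective",
    "solve_wishlist",
    "default_wishlist",
    "load_wishlist",
    "save_wishlist",
]

OBJECTIVE_KINDS = ("mean_dose", "mean_underdose_below", "mean_overdose_above", "geud")
CONSTRAINT_KINDS = ("max_dose", "mean_dose")

FEASIBILITY_TOL = 1e-6
RELATIVE_OBJECTIVE_TOL = 1e-4


class StageInfeasibleError(RuntimeError):
    """A priority stage has no feasible fluence."""

    def __init__(self, priority: int, message: str = ""):
        self.priority = priority
        super().__init__(
            f"wish-list stage for priority {priority} is infeasible"
            + (f": {message}" if message else "")
        )


class SolverError(RuntimeError):
    """The underlying solver failed to converge."""


@dataclass(frozen=True)
class HardConstraint:
    structure: str
    kind: str  # max_dose | mean_dose
    bound_gy: float

    def __post_init__(self) -> None:
        if self.kind not in CONSTRAINT_KINDS:
            raise ValueError(f"unknown hard-constraint kind {self.kind!r}")
        if self.bound_gy < 0:
            raise ValueError("bound must be >= 0")


@dataclass(frozen=True)
class Objective:
    priority: int
    structure: str
    kind: str
    goal_gy: float
    threshold_gy: float | None = None  # for mean_underdose_below / mean_overdose_above
    geud_a: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.kind in ("mean_underdose_below", "mean_overdose_above"):
            if self.threshold_gy is None or self.threshold_gy < 0:
                raise ValueError(f"{self.kind} requires a nonnegative threshold")
        if self.kind == "geud" and (self.geud_a is None or self.geud_a < 1):
            raise ValueError("geud requires a >= 1 (convexity)")
        if self.goal_gy < 0:
            raise ValueError("goal must be >= 0")


@dataclass(frozen=True)
class WishList:
    """Planning protocol: hard constraints plus prioritized objectives."""

    hard_constraints: tuple[HardConstraint, ...]
    objectives: tuple[Objective, ...]
    slack_delta: float = 0.03
    prescription_gy: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hard_constraints", tuple(self.hard_constraints))
        object.__setattr__(
            self, "objectives", tuple(sorted(self.objectives, key=lambda o: o.priority))
        )
        prios = [o.priority for o in self.objectives]
        if prios != list(range(1, len(prios) + 1)):
            raise ValueError(f"priorities must be unique and consecutive from 1, got {prios}")
        if self.slack_delta < 0:
            raise ValueError("slack_delta must be >= 0")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")


@dataclass
class Plan:
    """An optimized plan: fluence, resulting dose and achieved objectives."""

    beam_set: BeamSet
    fluence: np.ndarray
    dose: np.ndarray  # full-grid 3-D dose, Gy
    objective_values: np.ndarray  # per priority, on the optimization grid
    bounds: np.ndarray  # epsilon-constraint bound recorded per priority
    solver_status: str = "optimal"


def evaluate_objective(
    dose: np.ndarray,
    mask: np.ndarray,
    kind: str,
    threshold_gy: float | None = None,
    geud_a: float | None = None,
) -> float:
    """Evaluate one convex objective over a structure mask (Gy)."""
    d = np.asarray(dose)[np.asarray(mask, dtype=bool)]
    if d.size == 0:
        raise ValueError("objective evaluated on an empty mask")
    if kind == "mean_dose":
        return float(d.mean())
    if kind == "mean_underdose_below":
        return float(np.maximum(threshold_gy - d, 0.0).mean())
    if kind == "mean_overdose_above":
        return float(np.maximum(d - threshold_gy, 0.0).mean())
    if kind == "geud":
        return float(np.mean(d**geud_a) ** (1.0 / geud_a))
    raise ValueError(f"unknown objective kind {kind!r}")


# ---------------------------------------------------------------------------
# stage solver


class _Workspace:
    """Optimization-grid view of the influence matrices and structures."""

    def __init__(
        self,
        wishlist: WishList,
        influences: list[DoseInfluence],
        model: PatientModel,
        downsample: int,
        dose_offset: np.ndarray | None,
        full_ptv: bool = True,
    ):
        grid = model.grid
        patient = model.masks["patient"]
        stride = np.zeros(grid.shape, dtype=bool)
        ds = max(1, int(downsample))
        stride[::ds, ::ds, ::ds] = True
        opt_mask = patient & stride
        # down-sampling must never thin the target: cold spots concentrate
        # at unsampled voxels (degenerate optima put the coverage deficit
        # wherever it is not constrained), so production solves keep every
        # PTV voxel; scoring-only solves may skip this for speed
        if full_ptv:
            opt_mask |= model.masks["PTV"]
        names = {c.structure for c in wishlist.hard_constraints}
        names |= {o.structure for o in wishlist.objectives}
        # structures too small to survive the stride keep all their voxels
        for name in names:
            m = model.structure_mask(name)
            if not (m & opt_mask).any():
                if not m.any():
                    raise ValueError(f"structure {name!r} is empty")
                opt_mask |= m
        self.opt_idx = np.flatnonzero(opt_mask.reshape(-1))
        A = sparse.hstack([inf.matrix for inf in influences], format="csr")
        self.A = A[self.opt_idx]
        self.n_beamlets = self.A.shape[1]
        self.offset = (
            np.zeros(len(self.opt_idx))
            if dose_offset is None
            else np.asarray(dose_offset).reshape(-1)[self.opt_idx]
        )
        self._rows: dict[str, np.ndarray] = {}
        self._sub: dict[str, sparse.csr_matrix] = {}
        for name in names:
            m = model.structure_mask(name).reshape(-1)
            rows = np.flatnonzero(m[self.opt_idx])
            if rows.size == 0:
                raise ValueError(f"structure {name!r} has no optimization voxels")
            self._rows[name] = rows
            self._sub[name] = self.A[rows]

    def rows(self, name: str) -> np.ndarray:
        return self._rows[name]

    def sub(self, name: str) -> sparse.csr_matrix:
        return self._sub[name]

    def hot(self, name: str) -> np.ndarray:
        """Rows of ``sub(name)`` with any nonzero influence entry."""
        key = ("hot", name)
        if key not in self._sub:
            self._sub[key] = np.diff(self._sub[name].indptr) > 0
        return self._sub[key]


def _check_coverage_feasible(wishlist: WishList, ws: _Workspace, model: PatientModel) -> None:
    """Reject wish-lists whose hard max-dose bounds make coverage impossible."""
    for obj in wishlist.objectives:
        if obj.kind != "mean_underdose_below":
            continue
        om = model.structure_mask(obj.structure)
        for hc in wishlist.hard_constraints:
            if hc.kind != "max_dose":
                continue
            hm = model.structure_mask(hc.structure)
            if hc.bound_gy < obj.threshold_gy - FEASIBILITY_TOL and not (om & ~hm).any():
                raise StageInfeasibleError(
                    obj.priority,
                    f"max_dose({hc.structure}) <= {hc.bound_gy} Gy caps every "
                    f"{obj.structure} voxel below the {obj.threshold_gy} Gy "
                    "underdose threshold",
                )


def _solve_stages(
    wishlist: WishList,
    ws: _Workspace,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the sequential epsilon-constraint solves on the optimization grid.

    Returns (fluence, achieved objective values, recorded bounds).
    """
    nb = ws.n_beamlets
    objectives = wishlist.objectives
    achieved = np.full(len(objectives), np.nan)
    bounds_rec = np.full(len(objectives), np.nan)
    fluence = np.zeros(nb)

    # auxiliary-variable blocks for piecewise objectives, keyed by priority
    piecewise = {
        o.priority: o
        for o in objectives
        if o.kind in ("mean_underdose_below", "mean_overdose_above")
    }

    for stage_idx, obj in enumerate(objectives):
        active_aux = [
            p for p in sorted(piecewise) if p < obj.priority or p == obj.priority
        ]
        aux_offsets: dict[int, int] = {}
        n_aux = 0
        for p in active_aux:
            aux_offsets[p] = nb + n_aux
            n_aux += len(ws.rows(piecewise[p].structure))
        n_var = nb + n_aux

        A_rows: list[sparse.spmatrix] = []
        b_rows: list[np.ndarray] = []

        def add(A_block, b_block):
            A_rows.append(sparse.csr_matrix(A_block))
            b_rows.append(np.atleast_1d(np.asarray(b_block, dtype=float)))

        def pad(mat: sparse.spmatrix) -> sparse.spmatrix:
            if mat.shape[1] == n_var:
                return mat
            return sparse.hstack(
                [mat, sparse.csr_matrix((mat.shape[0], n_var - mat.shape[1]))]
            )

        # hard constraints
        for hc in wishlist.hard_constraints:
            S = ws.sub(hc.structure)
            off = ws.offset[ws.rows(hc.structure)]
            if hc.kind == "max_dose":
                # rows without influence are trivially satisfied; the rhs is
                # clamped at 0 so a fixed incumbent dose marginally above the
                # bound (possible at voxels unsampled in its own solve) does
                # not make the stage infeasible - new beams only add dose
                hot = ws.hot(hc.structure)
                add(pad(S[hot]), np.maximum(hc.bound_gy - off[hot], 0.0))
            else:  # mean_dose
                row = sparse.csr_matrix(S.mean(axis=0))
                add(pad(row), max(hc.bound_gy - off.mean(), 0.0))

        # epsilon constraints on higher priorities + aux definitions
        for p in active_aux:
            po = piecewise[p]
            S = ws.sub(po.structure)
            off = ws.offset[ws.rows(po.structure)]
            k = S.shape[0]
            o0 = aux_offsets[p]
            eye = sparse.identity(k, format="csr")
            Z = sparse.csr_matrix((k, n_var))
            if po.kind == "mean_underdose_below":
                # z_v >= t - (A f)_v - off_v
                block = sparse.hstack(
                    [-S, sparse.csr_matrix((k, o0 - nb)), -eye,
                     sparse.csr_matrix((k, n_var - o0 - k))]
                )
                add(block, off - po.threshold_gy)
            else:
                # z_v >= (A f)_v + off_v - t
                block = sparse.hstack(
                    [S, sparse.csr_matrix((k, o0 - nb)), -eye,
                     sparse.csr_matrix((k, n_var - o0 - k))]
                )
                add(block, po.threshold_gy - off)
            if p < obj.priority:
                mean_row = sparse.csr_matrix(
                    (np.full(k, 1.0 / k), (np.zeros(k, dtype=int), np.arange(o0, o0 + k))),
                    shape=(1, n_var),
                )
                add(mean_row, bounds_rec[p - 1])
        for prev in objectives[:stage_idx]:
            if prev.priority in piecewise:
                continue
            S = ws.sub(prev.structure)
            off = ws.offset[ws.rows(prev.structure)]
            if prev.kind == "mean_dose" or (prev.kind == "geud" and prev.geud_a == 1):
                row = sparse.csr_matrix(S.mean(axis=0))
                add(pad(row), bounds_rec[prev.priority - 1] - off.mean())
            else:
                raise NotImplementedError(
                    "gEUD(a != 1) epsilon-constraints are not supported by the LP path"
                )

        # objective vector and constant term
        c = np.zeros(n_var)
        const = 0.0
        if obj.kind in ("mean_underdose_below", "mean_overdose_above"):
            o0 = aux_offsets[obj.priority]
            k = len(ws.rows(obj.structure))
            c[o0 : o0 + k] = 1.0 / k
        elif obj.kind == "mean_dose" or (obj.kind == "geud" and obj.geud_a == 1):
            S = ws.sub(obj.structure)
            c[:nb] = np.asarray(S.mean(axis=0)).ravel()
            const = float(ws.offset[ws.rows(obj.structure)].mean())
        else:
            fluence, value = _solve_geud_stage(
                obj, ws, wishlist, objectives[:stage_idx], bounds_rec, fluence
            )
            achieved[stage_idx] = value
            bounds_rec[stage_idx] = max(
                obj.goal_gy, value * (1.0 + wishlist.slack_delta)
            )
            continue

        A_ub = sparse.vstack(A_rows, format="csr") if A_rows else None
        b_ub = np.concatenate(b_rows) if b_rows else None
        # interior point is far more robust than simplex on these highly
        # degenerate stages; fall back to the default simplex if it bails
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs-ipm")
        if res.status not in (0, 2):
            res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
        if res.status == 2:
            raise StageInfeasibleError(obj.priority)
        if res.status != 0:
            raise SolverError(
                f"solver failed at priority {obj.priority}: {res.message}"
            )
        fluence = np.maximum(res.x[:nb], 0.0)  # clip solver round-off
        value = float(res.fun + const)
        achieved[stage_idx] = value
        bounds_rec[stage_idx] = max(obj.goal_gy, value * (1.0 + wishlist.slack_delta))

    # re-evaluate all objectives at the final fluence (opt grid)
    dose_opt = ws.A @ fluence + ws.offset
    final = np.array(
        [
            _eval_on_rows(dose_opt, ws.rows(o.structure), o)
            for o in objectives
        ]
    )
    return fluence, final, bounds_rec


def _eval_on_rows(dose_opt: np.ndarray, rows: np.ndarray, obj: Objective) -> float:
    d = dose_opt[rows]
    if obj.kind == "mean_dose":
        return float(d.mean())
    if obj.kind == "mean_underdose_below":
        return float(np.maximum(obj.threshold_gy - d, 0.0).mean())
    if obj.kind == "mean_overdose_above":
        return float(np.maximum(d - obj.threshold_gy, 0.0).mean())
    return float(np.mean(d**obj.geud_a) ** (1.0 / obj.geud_a))


def _solve_geud_stage(obj, ws, wishlist, prior_objectives, bounds_rec, f0):
    """SLSQP fallback for a gEUD (a != 1) stage; small problems only."""
    from scipy.optimize import minimize

    rows = ws.rows(obj.structure)
    S = ws.sub(obj.structure).toarray()
    off = ws.offset[rows]
    a = obj.geud_a

    def objective(f):
        d = S @ f + off
        return float(np.mean(np.maximum(d, 1e-12) ** a) ** (1.0 / a))

    constraints = []
    for hc in wishlist.hard_constraints:
        Sh = ws.sub(hc.structure).toarray()
        offh = ws.offset[ws.rows(hc.structure)]
        if hc.kind == "max_dose":
            constraints.append(
                {"type": "ineq", "fun": lambda f, Sh=Sh, offh=offh, b=hc.bound_gy: b - (Sh @ f + offh)}
            )
        else:
            constraints.append(
                {"type": "ineq", "fun": lambda f, Sh=Sh, offh=offh, b=hc.bound_gy: b - (Sh @ f + offh).mean()}
            )
    for prev in prior_objectives:
        Sp = ws.sub(prev.structure).toarray()
        offp = ws.offset[ws.rows(prev.structure)]
        bound = bounds_rec[prev.priority - 1]

        def g(f, Sp=Sp, offp=offp, prev=prev, bound=bound):
            d = Sp @ f + offp
            if prev.kind == "mean_dose":
                val = d.mean()
            elif prev.kind == "mean_underdose_below":
                val = np.maximum(prev.threshold_gy - d, 0.0).mean()
            elif prev.kind == "mean_overdose_above":
                val = np.maximum(d - prev.threshold_gy, 0.0).mean()
            else:
                val = np.mean(np.maximum(d, 1e-12) ** prev.geud_a) ** (1.0 / prev.geud_a)
            return bound - val

        constraints.append({"type": "ineq", "fun": g})

    res = minimize(
        objective,
        f0,
        method="SLSQP",
        bounds=[(0, None)] * len(f0),
        constraints=constraints,
        options={"maxiter": 300, "ftol": 1e-9},
    )
    if not res.success:
        raise SolverError(f"SLSQP failed at priority {obj.priority}: {res.message}")
    return np.maximum(res.x, 0.0), objective(res.x)


def solve_wishlist(
    wishlist: WishList,
    influences: list[DoseInfluence],
    model: PatientModel,
    beam_set: BeamSet | None = None,
    downsample: int = 2,
    dose_offset: np.ndarray | None = None,
    full_ptv: bool = True,
) -> Plan:
    """Produce a Pareto-optimal plan for a fixed beam set.

    Sequential convex solves, one per priority; the optimization runs on a
    voxel grid down-sampled by ``downsample`` per axis (PTV voxels always
    kept), the returned dose is on the full grid.
    """
    if not influences:
        raise ValueError("at least one beam influence is required")
    ws = _Workspace(wishlist, influences, model, downsample, dose_offset, full_ptv)
    _check_coverage_feasible(wishlist, ws, model)
    fluence, achieved, bounds_rec = _solve_stages(wishlist, ws)
    dose = total_dose(influences, fluence)
    if dose_offset is not None:
        dose = dose + np.asarray(dose_offset).reshape(-1)
    if beam_set is None:
        beam_set = BeamSet(tuple(inf.beam for inf in influences))
    return Plan(
        beam_set=beam_set,
        fluence=fluence,
        dose=dose.reshape(model.grid.shape),
        objective_values=achieved,
        bounds=bounds_rec,
        solver_status="optimal",
    )


# ---------------------------------------------------------------------------
# default protocol and (de)serialization


def default_wishlist() -> WishList:
    """Reconstructed planning protocol for the 30 Gy prescription.

    Hard 110% maximum-dose caps on target and patient; priorities: target
    coverage (mean underdose below 95% of prescription), then heart, lungs
    and per-side breast mean dose at their preferred clinical thresholds, a
    lung low-dose surrogate, and overall conformality. The exact clinical
    protocol is proprietary; this ordering follows the printed planning
    aims and is flagged as a reconstruction.
    """
    return WishList(
        hard_constraints=(
            HardConstraint("PTV", "max_dose", 33.0),
            HardConstraint("patient", "max_dose", 33.0),
        ),
        objectives=(
            # underdose is driven relative to the full prescription: parking
            # the target exactly on the 95% evaluation threshold would leave
            # coverage on a knife edge, so the optimizer aims at 30 Gy
            Objective(1, "PTV", "mean_underdose_below", goal_gy=0.0, threshold_gy=30.0),
            Objective(2, "heart", "mean_dose", goal_gy=10.0),
            Objective(3, "lungs", "mean_dose", goal_gy=13.5),
            Objective(4, "breast_L", "mean_dose", goal_gy=2.0),
            Objective(5, "breast_R", "mean_dose", goal_gy=2.0),
            Objective(6, "lungs", "mean_overdose_above", goal_gy=1.0, threshold_gy=5.0),
            Objective(7, "patient", "mean_dose", goal_gy=0.0),
        ),
        slack_delta=0.03,
        prescription_gy=30.0,
    )


def _wishlist_to_dict(wl: WishList) -> dict:
    return {
        "prescription_gy": wl.prescription_gy,
        "slack_delta": wl.slack_delta,
        "hard_constraints": [
            {"structure": c.structure, "kind": c.kind, "bound_gy": c.bound_gy}
            for c in wl.hard_constraints
        ],
        "objectives": [
            {
                "priority": o.priority,
                "structure": o.structure,
                "kind": o.kind,
                "goal_gy": o.goal_gy,
                **({"threshold_gy": o.threshold_gy} if o.threshold_gy is not None else {}),
                **({"geud_a": o.geud_a} if o.geud_a is not None else {}),
            }
            for o in wl.objectives
        ],
    }


def save_wishlist(wishlist: WishList, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_wishlist_to_dict(wishlist), fh, sort_keys=False)


def _wishlist_from_dict(d: dict) -> WishList:
    return WishList(
        hard_constraints=tuple(HardConstraint(**c) for c in d.get("hard_constraints", [])),
        objectives=tuple(Objective(**o) for o in d.get("objectives", [])),
        slack_delta=float(d.get("slack_delta", 0.03)),
        prescription_gy=float(d.get("prescription_gy", 30.0)),
    )


def load_wishlist(path=None) -> WishList:
    """Load a wish-list YAML; with no path, the packaged default."""
    if path is None:
        text = resources.files("autobeam").joinpath("data/wishlist_default.yaml").read_text()
        return _wishlist_from_dict(yaml.safe_load(text))
    with open(path) as fh:
        return _wishlist_from_dict(yaml.safe_load(fh))
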