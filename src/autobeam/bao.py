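"""Greedy beam-angle optimization wrapped around the wish-list solver.

Beams are added one at a time: every unselected candidate is scored by the
prioritized objective vector of the incumbent set plus that candidate, the
lexicographic best wins (deterministic couch-then-gantry tie-break), and
the fluence is re-optimized over the grown incumbent. Scoring is either a
full wish-list re-solve per candidate or an incremental solve that keeps
the incumbent dose fixed and optimizes only the candidate's beamlets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .beams import BeamDirection, BeamSet
from .dose import DoseInfluence, KernelParams, build_beamlet_grid, compute_influence, total_dose
from .phantoms import PatientModel
from .wishlist import Plan, WishList, solve_wishlist

__all__ = [
    "BAOConfig",
    "BAOTrace",
    "InfluenceCache",
    "lexicographic_compare",
    "greedy_select",
    "save_trace",
]

LEX_TOL = 1e-6


@dataclass(frozen=True)
class BAOConfig:
    """Settings for greedy beam-angle selection.

    ``scoring_mode='full'`` re-solves the complete wish-list per candidate;
    ``'incremental'`` freezes the incumbent fluence and optimizes only the
    candidate's beamlets (validated against full scoring on small cases).
    ``scoring_downsample`` coarsens the optimization voxel grid during
    scoring only; the final plan always uses ``final_downsample``.
    """

    scoring_mode: str = "incremental"
    scoring_downsample: int = 3
    final_downsample: int = 2
    beamlet_size_mm: float = 10.0
    margin_mm: float = 10.0
    #: score candidates with only the first N priorities (None = all);
    #: lower priorities rarely change the ranking but dominate the runtime
    scoring_priorities: int | None = None
    #: constrain every PTV voxel during scoring solves too; final plans
    #: always do, scoring only needs a consistent ranking
    scoring_full_ptv: bool = True

    def __post_init__(self) -> None:
        if self.scoring_mode not in ("full", "incremental"):
            raise ValueError(f"unknown scoring mode {self.scoring_mode!r}")
        if self.scoring_priorities is not None and self.scoring_priorities < 1:
            raise ValueError("scoring_priorities must be >= 1")


@dataclass
class BAOTrace:
    """Per-iteration audit trail of the greedy selection."""

    selected: list[BeamDirection] = field(default_factory=list)
    objective_vectors: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selected)


class InfluenceCache:
    """Lazy per-(patient, beam) influence matrices, shared across runs."""

    def __init__(
        self,
        model: PatientModel,
        kernel: KernelParams = KernelParams(),
        beamlet_size_mm: float = 10.0,
        margin_mm: float = 10.0,
    ):
        self.model = model
        self.kernel = kernel
        self.beamlet_size_mm = beamlet_size_mm
        self.margin_mm = margin_mm
        self._cache: dict[tuple[float, float], DoseInfluence] = {}

    def get(self, beam: BeamDirection) -> DoseInfluence:
        key = (beam.gantry_deg, beam.couch_deg)
        if key not in self._cache:
            grid = build_beamlet_grid(
                self.model, beam, self.beamlet_size_mm, self.margin_mm
            )
            self._cache[key] = compute_influence(self.model, grid, self.kernel)
        return self._cache[key]

    def get_all(self, beams) -> list[DoseInfluence]:
        return [self.get(b) for b in beams]


def lexicographic_compare(a: np.ndarray, b: np.ndarray, tol: float = LEX_TOL) -> int:
    """-1 if a is better (smaller), +1 if b is better, 0 if equal within tol."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"objective vectors differ in length: {a.shape} vs {b.shape}")
    for ai, bi in zip(a, b):
        if ai < bi - tol:
            return -1
        if bi < ai - tol:
            return 1
    return 0


def greedy_select(
    model: PatientModel,
    candidates: BeamSet,
    x: int,
    wishlist: WishList,
    config: BAOConfig = BAOConfig(),
    cache: InfluenceCache | None = None,
    kernel: KernelParams = KernelParams(),
) -> tuple[Plan, BAOTrace]:
    """Select ``x`` beams greedily and return the re-optimized final plan.

    The final plan is solved on the standard optimization grid over the
    selected beams; the trace records each iteration's winning beam and the
    incumbent objective vector before and after re-optimization.
    """
    if not 1 <= x <= len(candidates):
        raise ValueError(f"x={x} outside [1, {len(candidates)}]")
    if cache is None:
        cache = InfluenceCache(
            model, kernel, config.beamlet_size_mm, config.margin_mm
        )
    if config.scoring_priorities is None or config.scoring_priorities >= len(
        wishlist.objectives
    ):
        scoring_wl = wishlist
    else:
        scoring_wl = WishList(
            hard_constraints=wishlist.hard_constraints,
            objectives=wishlist.objectives[: config.scoring_priorities],
            slack_delta=wishlist.slack_delta,
            prescription_gy=wishlist.prescription_gy,
        )

    selected: list[int] = []
    trace = BAOTrace()
    incumbent_fluence: np.ndarray | None = None

    for _ in range(x):
        remaining = [i for i in range(len(candidates)) if i not in selected]
        best_idx: int | None = None
        best_vec: np.ndarray | None = None
        if config.scoring_mode == "incremental" and selected:
            incumbent_infl = cache.get_all(candidates[i] for i in selected)
            offset = total_dose(incumbent_infl, incumbent_fluence)
        else:
            offset = None
        for i in remaining:
            beam = candidates[i]
            if config.scoring_mode == "full" or not selected:
                infl = cache.get_all(candidates[j] for j in selected + [i])
                plan = solve_wishlist(
                    scoring_wl,
                    infl,
                    model,
                    downsample=config.scoring_downsample,
                    full_ptv=config.scoring_full_ptv,
                )
            else:
                plan = solve_wishlist(
                    scoring_wl,
                    [cache.get(beam)],
                    model,
                    downsample=config.scoring_downsample,
                    dose_offset=offset,
                    full_ptv=config.scoring_full_ptv,
                )
            vec = plan.objective_values
            if best_vec is None:
                best_idx, best_vec = i, vec
                continue
            cmp = lexicographic_compare(vec, best_vec)
            if cmp < 0 or (
                cmp == 0
                and beam.sort_key() < candidates[best_idx].sort_key()
            ):
                best_idx, best_vec = i, vec
        selected.append(best_idx)
        # full fluence re-optimization over the incumbent
        infl = cache.get_all(candidates[j] for j in selected)
        incumbent_plan = solve_wishlist(
            scoring_wl,
            infl,
            model,
            downsample=config.scoring_downsample,
            full_ptv=config.scoring_full_ptv,
        )
        incumbent_fluence = incumbent_plan.fluence
        trace.selected.append(candidates[best_idx])
        trace.objective_vectors.append(incumbent_plan.objective_values)

    final_infl = cache.get_all(candidates[j] for j in selected)
    final_plan = solve_wishlist(
        wishlist,
        final_infl,
        model,
        beam_set=candidates.subset(selected),
        downsample=config.final_downsample,
    )
    return final_plan, trace


def save_trace(trace: BAOTrace, path) -> None:
    rows = []
    for it, (beam, vec) in enumerate(zip(trace.selected, trace.objective_vectors)):
        row = {
            "iteration": it + 1,
            "gantry_deg": beam.gantry_deg,
            "couch_deg": beam.couch_deg,
        }
        row.update({f"objective_{k + 1}": v for k, v in enumerate(vec)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
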