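import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse
from scipy.optimize import linprog

from autobeam.beams import BeamDirection
from autobeam.dose import KernelParams, build_beamlet_grid, compute_influence
from autobeam.wishlist import (
    HardConstraint,
    Objective,
    StageInfeasibleError,
    WishList,
    default_wishlist,
    evaluate_objective,
    load_wishlist,
    save_wishlist,
    solve_wishlist,
)

from conftest import make_slab_model


@pytest.fixture(scope="module")
def slab():
    return make_slab_model(shape=(10, 10, 6), voxel_mm=10.0, ptv_size=(2, 2, 2))


@pytest.fixture(scope="module")
def slab_influences(slab):
    params = KernelParams()
    out = []
    for g in (0, 90, 180, -90):
        grid = build_beamlet_grid(slab, BeamDirection(g, 0), 10, 10)
        out.append(compute_influence(slab, grid, params))
    return out


class TestEvaluateObjective:
    def test_uniform_mean(self):
        dose = np.full(50, 30.0)
        mask = np.ones(50, bool)
        assert evaluate_objective(dose, mask, "mean_dose") == pytest.approx(30.0)

    def test_underdose_zero_when_covered(self):
        dose = np.full(20, 29.0)
        mask = np.ones(20, bool)
        assert evaluate_objective(
            dose, mask, "mean_underdose_below", threshold_gy=28.5
        ) == 0.0

    def test_overdose(self):
        dose = np.array([4.0, 6.0, 8.0])
        mask = np.ones(3, bool)
        assert evaluate_objective(
            dose, mask, "mean_overdose_above", threshold_gy=5.0
        ) == pytest.approx((0 + 1 + 3) / 3)

    @given(st.integers(min_value=1, max_value=50), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=50, deadline=None)
    def test_geud_a1_equals_mean(self, n, seed):
        dose = np.random.default_rng(seed).random(n) * 40
        mask = np.ones(n, bool)
        assert evaluate_objective(dose, mask, "geud", geud_a=1.0) == pytest.approx(
            evaluate_objective(dose, mask, "mean_dose")
        )

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            evaluate_objective(np.ones(5), np.zeros(5, bool), "mean_dose")


class TestWishListInvariants:
    def test_nonconsecutive_priorities_rejected(self):
        with pytest.raises(ValueError):
            WishList(
                hard_constraints=(),
                objectives=(
                    Objective(1, "PTV", "mean_dose", 0.0),
                    Objective(3, "heart", "mean_dose", 0.0),
                ),
            )

    def test_negative_slack_rejected(self):
        with pytest.raises(ValueError):
            WishList(hard_constraints=(), objectives=(), slack_delta=-0.1)

    def test_bad_objective_kind(self):
        with pytest.raises(ValueError):
            Objective(1, "PTV", "nonsense", 0.0)

    def test_geud_requires_convex_a(self):
        with pytest.raises(ValueError):
            Objective(1, "PTV", "geud", 0.0, geud_a=0.5)


class TestDefaultWishlist:
    def test_priority_one_is_target_coverage(self):
        wl = default_wishlist()
        assert wl.objectives[0].structure == "PTV"
        assert wl.objectives[0].kind == "mean_underdose_below"

    def test_goals_match_protocol_preferred_values(self):
        wl = default_wishlist()
        goals = {(o.structure, o.kind): o.goal_gy for o in wl.objectives}
        assert goals[("heart", "mean_dose")] == 10.0
        assert goals[("lungs", "mean_dose")] == 13.5
        assert goals[("breast_L", "mean_dose")] == 2.0
        assert goals[("breast_R", "mean_dose")] == 2.0

    def test_invariants_hold(self):
        wl = default_wishlist()
        assert [o.priority for o in wl.objectives] == list(
            range(1, len(wl.objectives) + 1)
        )
        assert wl.prescription_gy == 30.0

    def test_packaged_yaml_matches_factory(self):
        assert load_wishlist() == default_wishlist()

    def test_yaml_roundtrip(self, tmp_path):
        wl = default_wishlist()
        save_wishlist(wl, tmp_path / "wl.yaml")
        assert load_wishlist(tmp_path / "wl.yaml") == wl


class TestSolveWishlist:
    def test_single_priority_matches_oneshot_oracle(self, slab, slab_influences):
        """Stage solve == independently constructed single LP (1e-4 rel)."""
        wl = WishList(
            hard_constraints=(HardConstraint("patient", "max_dose", 33.0),),
            objectives=(
                Objective(1, "PTV", "mean_underdose_below", 0.0, threshold_gy=30.0),
            ),
        )
        infl = slab_influences[:2]
        plan = solve_wishlist(wl, infl, slab, downsample=1)

        # independent one-shot LP on the full voxel grid
        A = sparse.hstack([i.matrix for i in infl], format="csr")
        patient = slab.masks["patient"].reshape(-1)
        ptv = slab.masks["PTV"].reshape(-1)
        Ap, At = A[patient], A[ptv]
        nb, k = A.shape[1], At.shape[0]
        c = np.concatenate([np.zeros(nb), np.full(k, 1.0 / k)])
        A_ub = sparse.vstack(
            [
                sparse.hstack([Ap, sparse.csr_matrix((Ap.shape[0], k))]),
                sparse.hstack([-At, -sparse.identity(k)]),
            ]
        )
        b_ub = np.concatenate([np.full(Ap.shape[0], 33.0), np.full(k, -30.0)])
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
        assert res.status == 0
        assert plan.objective_values[0] == pytest.approx(
            res.fun, rel=1e-4, abs=1e-6
        )

    def test_unattainable_coverage_is_infeasible(self, slab, slab_influences):
        wl = WishList(
            hard_constraints=(HardConstraint("patient", "max_dose", 0.0),),
            objectives=(
                Objective(1, "PTV", "mean_underdose_below", 0.0, threshold_gy=28.5),
            ),
        )
        with pytest.raises(StageInfeasibleError) as err:
            solve_wishlist(wl, slab_influences[:2], slab, downsample=1)
        assert err.value.priority == 1

    def test_higher_priorities_respect_bounds(self, slab, slab_influences):
        wl = WishList(
            hard_constraints=(HardConstraint("patient", "max_dose", 33.0),),
            objectives=(
                Objective(1, "PTV", "mean_underdose_below", 0.0, threshold_gy=30.0),
                Objective(2, "heart", "mean_dose", 1.0),
                Objective(3, "lungs", "mean_dose", 1.0),
                Objective(4, "patient", "mean_dose", 0.0),
            ),
        )
        plan = solve_wishlist(wl, slab_influences, slab, downsample=1)
        assert (plan.objective_values <= plan.bounds + 1e-6).all()

    def test_lexicographic_consistency_random_goals(self, slab, slab_influences):
        rng = np.random.default_rng(5)
        for _ in range(4):
            wl = WishList(
                hard_constraints=(HardConstraint("patient", "max_dose", 33.0),),
                objectives=(
                    Objective(1, "PTV", "mean_underdose_below", 0.0, threshold_gy=30.0),
                    Objective(2, "heart", "mean_dose", float(rng.uniform(0, 20))),
                    Objective(3, "patient", "mean_dose", float(rng.uniform(0, 10))),
                ),
            )
            plan = solve_wishlist(wl, slab_influences[:3], slab, downsample=1)
            assert plan.objective_values[0] <= plan.bounds[0] + 1e-6

    def test_monotone_in_beam_set(self, slab, slab_influences):
        """Extra beams can carry zero fluence, so priority 1 cannot worsen."""
        wl = WishList(
            hard_constraints=(HardConstraint("patient", "max_dose", 31.0),),
            objectives=(
                Objective(1, "PTV", "mean_underdose_below", 0.0, threshold_gy=31.0),
            ),
        )
        small = solve_wishlist(wl, slab_influences[:1], slab, downsample=1)
        large = solve_wishlist(wl, slab_influences, slab, downsample=1)
        assert large.objective_values[0] <= small.objective_values[0] + 1e-6

    def test_scale_equivariance(self, slab):
        wl = WishList(
            hard_constraints=(HardConstraint("patient", "max_dose", 33.0),),
            objectives=(
                Objective(1, "PTV", "mean_underdose_below", 0.0, threshold_gy=30.0),
                Objective(2, "patient", "mean_dose", 0.0),
            ),
        )
        plans = []
        for of in (1.0, 2.0):
            params = KernelParams(output_factor=of)
            infl = []
            for g in (0, 120):
                grid = build_beamlet_grid(slab, BeamDirection(g, 0), 10, 10)
                infl.append(compute_influence(slab, grid, params))
            plans.append(solve_wishlist(wl, infl, slab, downsample=1))
        np.testing.assert_allclose(
            plans[0].objective_values, plans[1].objective_values, rtol=1e-4, atol=1e-6
        )
        np.testing.assert_allclose(plans[0].dose, plans[1].dose, rtol=1e-3, atol=1e-4)

    def test_geud_stage_solves(self, slab, slab_influences):
        wl = WishList(
            hard_constraints=(HardConstraint("patient", "max_dose", 33.0),),
            objectives=(Objective(1, "PTV", "geud", 30.0, geud_a=2.0),),
        )
        plan = solve_wishlist(wl, slab_influences[:1], slab, downsample=2)
        # gEUD(2) >= mean dose (power-mean inequality), both on the opt grid
        mean_val = evaluate_objective(plan.dose, slab.masks["PTV"], "mean_dose")
        assert plan.objective_values[0] >= mean_val - 1e-6

    def test_no_influences_rejected(self, slab):
        with pytest.raises(ValueError):
            solve_wishlist(default_wishlist(), [], slab)

    def test_dose_matches_fluence(self, slab, slab_influences):
        from autobeam.dose import total_dose

        wl = WishList(
            hard_constraints=(HardConstraint("patient", "max_dose", 33.0),),
            objectives=(
                Objective(1, "PTV", "mean_underdose_below", 0.0, threshold_gy=30.0),
            ),
        )
        plan = solve_wishlist(wl, slab_influences[:2], slab, downsample=1)
        np.testing.assert_allclose(
            plan.dose.reshape(-1), total_dose(slab_influences[:2], plan.fluence)
        )
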