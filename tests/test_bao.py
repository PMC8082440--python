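import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autobeam.bao import BAOConfig, InfluenceCache, greedy_select, lexicographic_compare
from autobeam.beams import BeamDirection, BeamSet
from autobeam.dose import KernelParams
from autobeam.wishlist import HardConstraint, Objective, WishList, solve_wishlist


@pytest.fixture(scope="module")
def toy_wishlist():
    return WishList(
        hard_constraints=(HardConstraint("patient", "max_dose", 33.0),),
        objectives=(
            Objective(1, "PTV", "mean_underdose_below", 0.0, threshold_gy=31.0),
            Objective(2, "heart", "mean_dose", 5.0),
            Objective(3, "lungs", "mean_dose", 5.0),
        ),
        slack_delta=0.03,
        prescription_gy=30.0,
    )


@pytest.fixture(scope="module")
def cache(coarse_model, coarse_kernel):
    return InfluenceCache(coarse_model, coarse_kernel, 32.0, 32.0)


FOUR_CANDIDATES = BeamSet(
    (
        BeamDirection(0, 0),
        BeamDirection(90, 0),
        BeamDirection(-180, 0),
        BeamDirection(-90, 0),
    )
)

FULL_CFG = BAOConfig(
    scoring_mode="full",
    scoring_downsample=2,
    final_downsample=2,
    beamlet_size_mm=32.0,
    margin_mm=32.0,
)


def exhaustive_best(model, candidates, x, wishlist, cache):
    """Brute-force subset oracle: full wish-list solve per subset."""
    best = None
    for sub in itertools.combinations(range(len(candidates)), x):
        plan = solve_wishlist(
            wishlist, cache.get_all(candidates[i] for i in sub), model, downsample=2
        )
        if best is None or lexicographic_compare(plan.objective_values, best) < 0:
            best = plan.objective_values
    return best


class TestLexicographicCompare:
    def test_equal(self):
        assert lexicographic_compare([1.0, 2.0], [1.0, 2.0]) == 0

    def test_priority_one_dominates(self):
        assert lexicographic_compare([0.0, 5.0], [0.1, 1.0]) == -1

    def test_within_tolerance_falls_through(self):
        assert lexicographic_compare([1.0, 3.0], [1.0 + 1e-9, 4.0]) == -1

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=6),
        st.integers(0, 10**6),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, vec, seed):
        rng = np.random.default_rng(seed)
        a = np.asarray(vec)
        b = a + rng.normal(0, 1, size=a.shape)
        assert lexicographic_compare(a, b) == -lexicographic_compare(b, a)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            lexicographic_compare([1.0], [1.0, 2.0])


class TestGreedySelect:
    def test_x_equals_all_candidates(self, coarse_model, toy_wishlist, cache):
        plan, trace = greedy_select(
            coarse_model, FOUR_CANDIDATES, 4, toy_wishlist, FULL_CFG, cache=cache
        )
        assert {(b.gantry_deg, b.couch_deg) for b in trace.selected} == {
            (b.gantry_deg, b.couch_deg) for b in FOUR_CANDIDATES
        }

    def test_exhaustive_subset_oracle(self, coarse_model, toy_wishlist, cache):
        """Greedy vs all C(4,2) subsets, each solved with the full wish-list.

        The oracle value is the reference; where greedy is suboptimal the
        gap is reported and must stay small on this instance.
        """
        oracle = exhaustive_best(coarse_model, FOUR_CANDIDATES, 2, toy_wishlist, cache)
        plan, _ = greedy_select(
            coarse_model, FOUR_CANDIDATES, 2, toy_wishlist, FULL_CFG, cache=cache
        )
        greedy_vec = plan.objective_values
        # greedy can never beat the exhaustive optimum
        assert lexicographic_compare(oracle, greedy_vec) <= 0
        # priority 1 must match the oracle to 1e-3 relative
        assert greedy_vec[0] == pytest.approx(oracle[0], rel=1e-3, abs=1e-6)
        for k in range(1, len(oracle)):
            gap = (greedy_vec[k] - oracle[k]) / max(abs(oracle[k]), 1e-9)
            if gap > 1e-3:
                warnings.warn(
                    f"greedy suboptimal at priority {k + 1}: "
                    f"{greedy_vec[k]:.4f} vs oracle {oracle[k]:.4f} "
                    f"(relative gap {gap:.2%})"
                )
            assert gap <= 0.05  # small, reported gap on this instance

    def test_noncoplanar_superset_oracle(self, coarse_model, toy_wishlist, cache):
        """Best subset from a superset of candidates is never worse."""
        six = BeamSet(
            FOUR_CANDIDATES.beams + (BeamDirection(20, 90), BeamDirection(-20, 90))
        )
        best4 = exhaustive_best(coarse_model, FOUR_CANDIDATES, 2, toy_wishlist, cache)
        best6 = exhaustive_best(coarse_model, six, 2, toy_wishlist, cache)
        assert lexicographic_compare(best6, best4) <= 0

    def test_determinism(self, coarse_model, toy_wishlist, cache):
        sels = []
        for _ in range(2):
            _, trace = greedy_select(
                coarse_model, FOUR_CANDIDATES, 3, toy_wishlist, FULL_CFG, cache=cache
            )
            sels.append([(b.gantry_deg, b.couch_deg) for b in trace.selected])
        assert sels[0] == sels[1]

    def test_trace_contract(self, coarse_model, toy_wishlist, cache):
        plan, trace = greedy_select(
            coarse_model, FOUR_CANDIDATES, 3, toy_wishlist, FULL_CFG, cache=cache
        )
        assert len(trace) == 3
        keys = [(b.gantry_deg, b.couch_deg) for b in trace.selected]
        assert len(set(keys)) == 3
        cand_keys = {(b.gantry_deg, b.couch_deg) for b in FOUR_CANDIDATES}
        assert set(keys) <= cand_keys
        assert len(plan.beam_set) == 3

    def test_weak_monotonicity_in_x(self, coarse_model, toy_wishlist, cache):
        values = []
        for x in (2, 3, 4):
            plan, _ = greedy_select(
                coarse_model, FOUR_CANDIDATES, x, toy_wishlist, FULL_CFG, cache=cache
            )
            values.append(plan.objective_values[0])
        assert values[1] <= values[0] + 1e-6
        assert values[2] <= values[1] + 1e-6

    def test_incremental_validated_against_full_scoring(
        self, coarse_model, toy_wishlist, cache
    ):
        """Incremental scoring is an approximation of full scoring.

        Iteration 1 is mathematically identical in both modes (empty
        incumbent), so the first selected beam must coincide; afterwards
        the modes may diverge, but the re-optimized final plan must match
        on priority 1 and stay within a bounded gap below it.
        """
        inc_cfg = BAOConfig(
            scoring_mode="incremental",
            scoring_downsample=2,
            final_downsample=2,
            beamlet_size_mm=32.0,
            margin_mm=32.0,
        )
        p_full, t_full = greedy_select(
            coarse_model, FOUR_CANDIDATES, 2, toy_wishlist, FULL_CFG, cache=cache
        )
        p_inc, t_inc = greedy_select(
            coarse_model, FOUR_CANDIDATES, 2, toy_wishlist, inc_cfg, cache=cache
        )
        assert t_full.selected[0] == t_inc.selected[0]
        assert p_inc.objective_values[0] == pytest.approx(
            p_full.objective_values[0], rel=1e-3, abs=1e-6
        )
        for k in range(1, len(p_full.objective_values)):
            gap = abs(p_inc.objective_values[k] - p_full.objective_values[k]) / max(
                abs(p_full.objective_values[k]), 1e-9
            )
            assert gap <= 0.25

    def test_x_out_of_range(self, coarse_model, toy_wishlist, cache):
        with pytest.raises(ValueError):
            greedy_select(
                coarse_model, FOUR_CANDIDATES, 5, toy_wishlist, FULL_CFG, cache=cache
            )

    def test_save_trace(self, coarse_model, toy_wishlist, cache, tmp_path):
        from autobeam.bao import save_trace
        import pandas as pd

        _, trace = greedy_select(
            coarse_model, FOUR_CANDIDATES, 2, toy_wishlist, FULL_CFG, cache=cache
        )
        save_trace(trace, tmp_path / "trace.csv")
        df = pd.read_csv(tmp_path / "trace.csv")
        assert len(df) == 2
        assert "objective_1" in df.columns


def test_bad_config():
    with pytest.raises(ValueError):
        BAOConfig(scoring_mode="magic")
    with pytest.raises(ValueError):
        BAOConfig(scoring_priorities=0)
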