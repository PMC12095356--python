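"""Integer-programming polyclonal selection against exhaustive enumeration."""

import numpy as np
import pytest

from polyclonal import (
    PolyclonalSelection,
    ScaledGainMatrix,
    SelectionCriteria,
    brute_force_select,
    build_scaled_matrix,
)


def make_matrix(values, traits=None, directions=None, means=None):
    values = np.atleast_2d(np.asarray(values, float))
    n, p = values.shape
    traits = traits or [f"T{j}" for j in range(p)]
    return ScaledGainMatrix(
        clone_ids=[f"C{i:02d}" for i in range(n)],
        traits=traits,
        values=values,
        directions=directions or dict.fromkeys(traits, "maximize"),
        overall_means=means or dict.fromkeys(traits, 1.0),
    )


def random_matrix(rng, n, p):
    vals = rng.normal(0, 0.08, (n, p))
    vals -= vals.mean(0, keepdims=True)
    return make_matrix(vals)


class TestBuildScaledMatrix:
    class FitStub:
        def __init__(self, trait, eblups, mean, clones=None):
            import pandas as pd

            self.trait = trait
            self.overall_mean = mean
            self.genotype_eblups = pd.Series(
                eblups, index=clones or [f"C{i}" for i in range(len(eblups))])

    def test_minimize_trait_sign_flip(self):
        # an EBLUP of +0.03414 on pH (mean 3.414, minimize) scales to -0.01
        fit = self.FitStub("pH", [0.03414, -0.03414], 3.414)
        m = build_scaled_matrix([fit], {"pH": "minimize"})
        assert m.values[0, 0] == pytest.approx(-0.01)
        assert m.values[1, 0] == pytest.approx(0.01)

    def test_maximize_trait_plain_scaling(self):
        fit = self.FitStub("YD", [0.3517, 0.0], 3.517)
        m = build_scaled_matrix([fit], {"YD": "maximize"})
        assert m.values[0, 0] == pytest.approx(0.10)
        assert m.values[1, 0] == pytest.approx(0.0)

    def test_clone_intersection_across_traits(self):
        a = self.FitStub("A", [0.1, 0.2, 0.3], 1.0, clones=["C1", "C2", "C3"])
        b = self.FitStub("B", [0.4, 0.5], 1.0, clones=["C2", "C3"])
        m = build_scaled_matrix([a, b], {"A": "maximize", "B": "maximize"})
        assert m.clone_ids == ["C2", "C3"]

    def test_empty_intersection_rejected(self):
        a = self.FitStub("A", [0.1], 1.0, clones=["C1"])
        b = self.FitStub("B", [0.4], 1.0, clones=["C2"])
        with pytest.raises(ValueError, match="intersection"):
            build_scaled_matrix([a, b], {"A": "maximize", "B": "maximize"})

    def test_zero_mean_rejected(self):
        fit = self.FitStub("A", [0.1, -0.1], 0.0)
        with pytest.raises(ValueError, match="zero overall mean"):
            build_scaled_matrix([fit], {"A": "maximize"})

    def test_column_means_zero_when_eblups_sum_to_zero(self):
        fit = self.FitStub("A", [0.2, -0.1, -0.1], 2.0)
        m = build_scaled_matrix([fit], {"A": "maximize"})
        assert abs(m.values[:, 0].mean()) < 1e-12


class TestSolveSelection:
    def antagonistic_pair(self):
        return make_matrix([[0.01, -0.01], [-0.01, 0.01]], traits=["A", "B"])

    def test_every_singleton_violates_a_constraint(self):
        m = self.antagonistic_pair()
        crit = SelectionCriteria.base(["A", "B"], size_range=(1, 2))
        sol = PolyclonalSelection(m, crit).solve(1)
        assert not sol.feasible
        assert sol.selected_clones == []

    def test_whole_set_is_the_zero_gain_solution(self):
        m = self.antagonistic_pair()
        crit = SelectionCriteria.base(["A", "B"], size_range=(1, 2))
        sol = PolyclonalSelection(m, crit).solve(2)
        assert sol.feasible
        assert sol.gains_pct["A"] == pytest.approx(0.0, abs=1e-9)
        assert sol.gains_pct["B"] == pytest.approx(0.0, abs=1e-9)

    def test_min_gain_right_hand_side(self):
        # R_k = 15% at s = 7 requires a scaled sum of at least 1.05
        vals = np.zeros((8, 1))
        vals[:7, 0] = 0.15  # exactly l_k in total
        vals[7, 0] = -1.0
        m = make_matrix(vals, traits=["AC"])
        crit = SelectionCriteria(objective_traits=["AC"],
                                 min_gain_pct={"AC": 15.0}, size_range=(7, 8))
        sel = PolyclonalSelection(m, crit)
        sol = sel.solve(7)
        assert sol.feasible
        assert sum(m.values[[m.clone_ids.index(c) for c in sol.selected_clones], 0]
                   ) == pytest.approx(1.05)
        assert not sel.solve(8).feasible

    def test_agrees_with_enumeration_on_fixed_instance(self):
        rng = np.random.default_rng(42)
        m = random_matrix(rng, 12, 3)
        crit = SelectionCriteria.base(m.traits, size_range=(4, 4))
        milp_sol = PolyclonalSelection(m, crit).solve(4)
        bf_sol = brute_force_select(m, crit, 4)
        assert milp_sol.feasible == bf_sol.feasible
        assert milp_sol.objective_value == pytest.approx(bf_sol.objective_value,
                                                         abs=1e-9)
        assert set(milp_sol.selected_clones) == set(bf_sol.selected_clones)

    def test_oracle_equivalence_over_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(6, 17))
            p = int(rng.integers(1, 5))
            s = int(rng.integers(2, min(7, n)))
            m = random_matrix(rng, n, p)
            rks = {t: float(rng.choice([0.0, 1.0, 5.0, 20.0])) for t in m.traits}
            crit = SelectionCriteria(objective_traits=list(m.traits),
                                     min_gain_pct=rks, size_range=(s, s))
            a = PolyclonalSelection(m, crit).solve(s)
            b = brute_force_select(m, crit, s)
            assert a.feasible == b.feasible
            if a.feasible:
                assert a.objective_value == pytest.approx(b.objective_value,
                                                          abs=1e-9)

    def test_feasible_solution_respects_all_constraints(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 20, 3)
        crit = SelectionCriteria(objective_traits=[m.traits[0]],
                                 min_gain_pct={t: 0.5 for t in m.traits[1:]},
                                 size_range=(5, 5))
        sol = PolyclonalSelection(m, crit).solve(5)
        if sol.feasible:
            for t, rk in crit.min_gain_pct.items():
                assert sol.gains_pct[t] >= rk - 1e-6

    def test_raising_min_gain_never_improves_objective(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 14, 2)
        base = SelectionCriteria.base(m.traits, size_range=(5, 5))
        z0 = PolyclonalSelection(m, base).solve(5).objective_value
        tight = SelectionCriteria(objective_traits=m.traits,
                                  min_gain_pct={m.traits[0]: 2.0,
                                                m.traits[1]: 0.0},
                                  size_range=(5, 5))
        sol = PolyclonalSelection(m, tight).solve(5)
        if sol.feasible:
            assert sol.objective_value <= z0 + 1e-9

    def test_excluded_clone_never_selected_and_objective_never_improves(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 15, 2)
        crit = SelectionCriteria.base(m.traits, size_range=(6, 6))
        sol = PolyclonalSelection(m, crit).solve(6)
        banned = sol.selected_clones[0]
        crit2 = SelectionCriteria.base(m.traits, size_range=(6, 6),
                                       excluded_clones={banned})
        sol2 = PolyclonalSelection(m, crit2).solve(6)
        assert banned not in sol2.selected_clones
        assert sol2.objective_value <= sol.objective_value + 1e-9


class TestGainBounds:
    def test_rmax_possible_small_enumeration(self):
        m = make_matrix([[0.30], [0.10], [-0.05], [-0.20]])
        sel = PolyclonalSelection(m, SelectionCriteria.base(m.traits,
                                                            size_range=(1, 4)))
        assert sel.rmax_possible("T0", 2) == pytest.approx(20.0)
        # oracle: best over all 6 pairs
        from itertools import combinations
        best = max(np.mean([m.values[i, 0], m.values[j, 0]])
                   for i, j in combinations(range(4), 2))
        assert sel.rmax_possible("T0", 2) == pytest.approx(100 * best)

    def test_rmax_possible_degenerate_cases(self):
        m = make_matrix([[0.1]] * 5)
        sel = PolyclonalSelection(m, SelectionCriteria.base(m.traits,
                                                            size_range=(1, 5)))
        assert sel.rmax_possible("T0", 3) == pytest.approx(10.0)
        zs = make_matrix([[0.2], [0.1], [-0.3]])
        sel2 = PolyclonalSelection(zs, SelectionCriteria.base(zs.traits,
                                                              size_range=(1, 3)))
        assert sel2.rmax_possible("T0", 3) == pytest.approx(0.0, abs=1e-12)

    def test_rmax_admissible_reduces_to_possible_without_other_traits(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 10, 2)
        sel = PolyclonalSelection(m, SelectionCriteria.base(m.traits))
        for s in (2, 5):
            assert sel.rmax_admissible(m.traits[0], s, other_traits=[]) == \
                pytest.approx(sel.rmax_possible(m.traits[0], s), abs=1e-9)

    def test_rmax_admissible_antagonistic_instance(self):
        vals = np.array([[0.02, -0.02], [0.01, -0.01],
                         [-0.01, 0.01], [-0.02, 0.02]])
        m = make_matrix(vals, traits=["A", "B"])
        sel = PolyclonalSelection(m, SelectionCriteria.base(m.traits))
        assert sel.rmax_admissible("A", 2) == pytest.approx(0.0, abs=1e-9)

    def test_rmax_admissible_matches_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(99)
        m = random_matrix(rng, 14, 3)
        sel = PolyclonalSelection(m, SelectionCriteria.base(m.traits))
        s = 5
        got = sel.rmax_admissible("T0", s)
        best = -np.inf
        for subset in combinations(range(14), s):
            idx = list(subset)
            if all(m.values[idx, j].sum() >= -1e-12 for j in (1, 2)):
                best = max(best, m.values[idx, 0].mean())
        assert got == pytest.approx(100 * best, abs=1e-9)

    def test_bound_inequalities_over_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            m = random_matrix(rng, int(rng.integers(10, 26)), int(rng.integers(2, 4)))
            sel = PolyclonalSelection(m, SelectionCriteria.base(m.traits))
            for t in m.traits:
                prev = np.inf
                for s in range(2, 9):
                    rp = sel.rmax_possible(t, s)
                    ra = sel.rmax_admissible(t, s)
                    assert rp <= prev + 1e-9      # non-increasing in s
                    if np.isfinite(ra):
                        assert ra <= rp + 1e-6    # admissible <= possible
                    prev = rp


class TestSizeSweep:
    def test_base_criteria_always_feasible_with_nonnegative_gains(self):
        rng = np.random.default_rng(30)
        m = random_matrix(rng, 30, 3)
        crit = SelectionCriteria.base(m.traits)
        sweep = PolyclonalSelection(m, crit).sweep()
        assert [sol.size for sol in sweep.solutions] == list(range(7, 21))
        for sol in sweep.solutions:
            assert sol.feasible
            for t in m.traits:
                assert sol.gains_pct[t] >= -1e-6
        # spot-check the smallest size against enumeration
        bf = brute_force_select(m, crit, 7, budget=3 * 10 ** 6)
        assert sweep.solutions[0].objective_value == pytest.approx(
            bf.objective_value, abs=1e-9)

    def test_infeasible_sizes_flagged_not_dropped(self):
        # supply of positive-B clones runs out above size 10: the sweep keeps
        # reporting those sizes as infeasible rather than silently dropping them
        vals = np.zeros((20, 2))
        vals[:8] = [0.2, -0.1]     # strong A, slight B loss
        vals[8:10] = [-0.15, 0.45]  # B compensators
        vals[10:] = [-0.5, -0.5]   # poor in both
        m = make_matrix(vals, traits=["A", "B"])
        crit = SelectionCriteria.base(["A", "B"])
        sweep = PolyclonalSelection(m, crit).sweep()
        flags = {sol.size: sol.feasible for sol in sweep.solutions}
        assert set(flags) == set(range(7, 21))
        for s, feasible in flags.items():
            assert feasible == brute_force_select(m, crit, s).feasible
        assert not all(flags.values())
        assert any(flags.values())

    def test_single_trait_base_gains_equal_possible_bound(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 25, 1)
        crit = SelectionCriteria.base(m.traits, size_range=(7, 12))
        sel = PolyclonalSelection(m, crit)
        sweep = sel.sweep()
        for sol in sweep.solutions:
            assert sol.gains_pct[m.traits[0]] == pytest.approx(
                sel.rmax_possible(m.traits[0], sol.size), abs=1e-9)


class TestBruteForce:
    def test_budget_refusal(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 30, 1)
        crit = SelectionCriteria.base(m.traits, size_range=(15, 15))
        with pytest.raises(ValueError, match="budget"):
            brute_force_select(m, crit, 15, budget=1000)

    def test_full_set_subset(self):
        m = make_matrix([[0.1], [0.2], [-0.3]])
        crit = SelectionCriteria.base(m.traits, size_range=(3, 3))
        sol = brute_force_select(m, crit, 3)
        assert sol.feasible  # zero-sum column meets the R=0 floor exactly
        assert len(sol.selected_clones) == 3

    def test_infeasible_from_both_paths(self):
        m = make_matrix([[0.01, -0.01], [-0.01, 0.01]], traits=["A", "B"])
        crit = SelectionCriteria(objective_traits=["A", "B"],
                                 min_gain_pct={"A": 50.0, "B": 50.0},
                                 size_range=(2, 2))
        assert not brute_force_select(m, crit, 2).feasible
        assert not PolyclonalSelection(m, crit).solve(2).feasible
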