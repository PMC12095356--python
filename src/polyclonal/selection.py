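"""Polyclonal selection by binary integer programming.

A polyclonal group is a set of ``s`` clones (typically 7 to 20) judged by
its collective predicted performance.  For each trait ``k`` the clone-level
inputs are the direction-adjusted, mean-scaled genotypic EBLUPs

    y_ki = sign_k * EBLUP_ki / mean_k,

with ``sign_k = -1`` for traits to be decreased (e.g. pH, berry weight) so
that larger values are always gains.  The predicted genetic gain of a group
for trait ``k`` is ``R_k = 100 * mean of its y_ki`` (percent of the trait
mean, on the improving scale).

The selection problem is the binary program

    maximize    z = sum_i sum_{k in objective} y_ki x_i
    subject to  sum_i x_i = s,
                sum_i y_ki x_i >= l_k = R_k s / 100   for constrained traits,
                x_i = 0 for excluded clones,  x_i in {0, 1}.

Two per-trait bounds frame what a group of size ``s`` can achieve: the
maximum possible gain ``R_max_p`` (mean of the best ``s`` scaled EBLUPs,
ignoring all other traits) and the maximum admissible gain ``R_max_a`` (the
best gain attainable without letting any other trait of interest go
negative).  The size sweep runs bounds and the criteria program for every
group size in the requested range; infeasible sizes are reported as such,
never dropped silently.

Solved with the HiGHS branch-and-bound backend of `scipy.optimize.milp`;
an exhaustive-enumeration oracle with the same contract is provided for
verification on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from .reml import MixedModelResults

__all__ = [
    "ScaledGainMatrix",
    "SelectionCriteria",
    "SelectionResult",
    "GainBoundsTable",
    "SizeSweepResult",
    "PolyclonalSelection",
    "build_scaled_matrix",
    "brute_force_select",
]

#: tolerance on scaled constraint sums when reporting feasibility
FEAS_TOL = 1e-9


class SolverError(RuntimeError):
    """The MILP backend failed for a reason other than infeasibility."""


@dataclass
class ScaledGainMatrix:
    """Clone x trait matrix of direction-adjusted, mean-scaled EBLUPs."""

    clone_ids: list[str]
    traits: list[str]
    values: np.ndarray                      # shape (n_clones, n_traits)
    directions: dict[str, str]              # trait -> "maximize" | "minimize"
    overall_means: dict[str, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.clone_ids), len(self.traits)):
            raise ValueError("values shape does not match clone/trait lists")
        bad = set(self.directions.values()) - {"maximize", "minimize"}
        if bad:
            raise ValueError(f"unknown direction(s) {bad}")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def column(self, trait: str) -> np.ndarray:
        return self.values[:, self.traits.index(trait)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.clone_ids, name="clone"),
                            columns=self.traits)


def build_scaled_matrix(fits: list[MixedModelResults],
                        directions: dict[str, str]) -> ScaledGainMatrix:
    """Assemble the scaled gain matrix from per-trait mixed-model fits.

    Each entry is the clone's genotypic EBLUP divided by the trait's overall
    mean, multiplied by -1 for minimize-direction traits.  Clones are
    restricted to the intersection of the clone sets across traits (traits
    may be fitted on different replicate subsets).
    """
    if not fits:
        raise ValueError("no fits supplied")
    missing = [f.trait for f in fits if f.trait not in directions]
    if missing:
        raise ValueError(f"no direction given for trait(s) {missing}")
    common = fits[0].genotype_eblups.index
    for f in fits[1:]:
        common = common.intersection(f.genotype_eblups.index)
    if len(common) == 0:
        raise ValueError("empty clone intersection across traits")
    common = sorted(common)
    cols, means = [], {}
    for f in fits:
        if f.overall_mean == 0:
            raise ValueError(f"trait {f.trait!r} has zero overall mean; cannot scale")
        sign = -1.0 if directions[f.trait] == "minimize" else 1.0
        cols.append(sign * f.genotype_eblups.loc[common].to_numpy() / f.overall_mean)
        means[f.trait] = f.overall_mean
    return ScaledGainMatrix(
        clone_ids=[str(c) for c in common],
        traits=[f.trait for f in fits],
        values=np.column_stack(cols),
        directions={f.trait: directions[f.trait] for f in fits},
        overall_means=means,
    )


@dataclass
class SelectionCriteria:
    """What to optimize and what to require of the selected group.

    Parameters
    ----------
    objective_traits : list of str
        Traits summed (unweighted) in the objective ``z``.
    min_gain_pct : dict, optional
        Minimum desired gain ``R_k`` (percent of the trait mean, >= 0) per
        constrained trait.  A trait may be constrained without being in the
        objective and vice versa.
    size_range : (int, int)
        Inclusive range of group sizes for the sweep; default 7-20.
    excluded_clones : set of str
        Clones forced out of every solution.
    """

    objective_traits: list[str]
    min_gain_pct: dict[str, float] = field(default_factory=dict)
    size_range: tuple[int, int] = (7, 20)
    excluded_clones: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.objective_traits:
            raise ValueError("at least one objective trait is required")
        neg = {k: v for k, v in self.min_gain_pct.items() if v < 0}
        if neg:
            raise ValueError(f"minimum desired gains must be >= 0, got {neg}")
        lo, hi = self.size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid size range {self.size_range}")

    @property
    def constraint_traits(self) -> list[str]:
        return list(self.min_gain_pct)

    @classmethod
    def base(cls, traits: list[str], size_range: tuple[int, int] = (7, 20),
             excluded_clones: set[str] | None = None) -> "SelectionCriteria":
        """Base situation: all traits in the objective, every R_k = 0."""
        return cls(objective_traits=list(traits),
                   min_gain_pct={t: 0.0 for t in traits},
                   size_range=size_range,
                   excluded_clones=excluded_clones or set())


@dataclass
class SelectionResult:
    """Outcome of one selection program at a fixed group size."""

    size: int
    feasible: bool
    selected_clones: list[str]
    objective_value: float
    gains_pct: dict[str, float]

    def summary(self) -> str:
        if not self.feasible:
            return f"size {self.size}: infeasible"
        gains = ", ".join(f"{k}={v:+.1f}%" for k, v in self.gains_pct.items())
        return (f"size {self.size}: z={self.objective_value:.4f}; "
                f"gains {gains}; clones {', '.join(self.selected_clones)}")


@dataclass
class GainBoundsTable:
    """R_max_p / R_max_a per trait and group size (percent of trait mean)."""

    frame: pd.DataFrame  # columns: trait, size, rmax_possible, rmax_admissible

    def pivot(self, which: str = "rmax_possible") -> pd.DataFrame:
        return self.frame.pivot(index="trait", columns="size", values=which)


@dataclass
class SizeSweepResult:
    """Bounds and criteria solutions across the whole size range."""

    solutions: list[SelectionResult]
    bounds: GainBoundsTable

    @property
    def feasible_sizes(self) -> list[int]:
        return [s.size for s in self.solutions if s.feasible]

    def gains_table(self) -> pd.DataFrame:
        """Trait x size table of gains; NaN marks infeasible sizes."""
        traits = list(self.solutions[0].gains_pct) if any(
            s.feasible for s in self.solutions) else []
        data = {}
        for sol in self.solutions:
            col = {t: sol.gains_pct.get(t, np.nan) for t in traits} if sol.feasible \
                else {t: np.nan for t in traits}
            data[sol.size] = col
        return pd.DataFrame(data)

    def summary(self) -> str:
        lines = ["Polyclonal selection size sweep", "=" * 36]
        lines += [s.summary() for s in self.solutions]
        return "\n".join(lines)


class PolyclonalSelection:
    """Binary-integer-programming selection over a scaled gain matrix.

    Examples
    --------
    >>> sel = PolyclonalSelection(matrix, SelectionCriteria.base(matrix.traits))
    >>> sel.solve(7).gains_pct           # doctest: +SKIP
    >>> sweep = sel.sweep()              # doctest: +SKIP
    """

    def __init__(self, matrix: ScaledGainMatrix, criteria: SelectionCriteria):
        unknown = (set(criteria.objective_traits) | set(criteria.min_gain_pct)) \
            - set(matrix.traits)
        if unknown:
            raise ValueError(f"criteria mention unknown trait(s) {sorted(unknown)}")
        unknown_clones = criteria.excluded_clones - set(matrix.clone_ids)
        if unknown_clones:
            raise ValueError(f"excluded clone(s) not in matrix: {sorted(unknown_clones)}")
        self.matrix = matrix
        self.criteria = criteria
        self._excl_idx = [matrix.clone_ids.index(c) for c in sorted(criteria.excluded_clones)]

    @property
    def n_available(self) -> int:
        return self.matrix.n_clones - len(self._excl_idx)

    # -- single-size program --------------------------------------------------
    def solve(self, s: int) -> SelectionResult:
        """Solve the criteria program for one group size ``s`` to optimality."""
        if s > self.n_available:
            raise ValueError(f"group size {s} exceeds {self.n_available} available clones")
        Y = self.matrix.values
        obj = np.zeros(self.matrix.n_clones)
        for t in self.criteria.objective_traits:
            obj += self.matrix.column(t)
        constraints = [LinearConstraint(np.ones(self.matrix.n_clones), s, s)]
        for t, rk in self.criteria.min_gain_pct.items():
            lk = rk * s / 100.0
            constraints.append(LinearConstraint(self.matrix.column(t), lk, np.inf))
        ub = np.ones(self.matrix.n_clones)
        ub[self._excl_idx] = 0.0
        res = milp(c=-obj, constraints=constraints,
                   integrality=np.ones(self.matrix.n_clones),
                   bounds=Bounds(np.zeros(self.matrix.n_clones), ub))
        if res.status == 2:  # proven infeasible
            return SelectionResult(size=s, feasible=False, selected_clones=[],
                                   objective_value=np.nan, gains_pct={})
        if res.status != 0:
            raise SolverError(f"MILP solver failed with status {res.status}: {res.message}")
        x = res.x > 0.5
        selected = [c for c, keep in zip(self.matrix.clone_ids, x) if keep]
        gains = {t: 100.0 * float(Y[x, j].mean())
                 for j, t in enumerate(self.matrix.traits)}
        return SelectionResult(size=s, feasible=True, selected_clones=selected,
                               objective_value=float(obj[x].sum()), gains_pct=gains)

    # -- gain bounds ------------------------------------------------------------
    def rmax_possible(self, trait: str, s: int) -> float:
        """Maximum possible gain: mean of the ``s`` largest scaled EBLUPs (%)."""
        y = self._available(self.matrix.column(trait))
        if not 1 <= s <= len(y):
            raise ValueError(f"s={s} outside [1, {len(y)}]")
        top = np.sort(y)[-s:]
        return 100.0 * float(top.mean())

    def rmax_admissible(self, trait: str, s: int,
                        other_traits: list[str] | None = None,
                        min_gain_pct: dict[str, float] | None = None) -> float:
        """Maximum admissible gain for ``trait`` at size ``s`` (%).

        Maximizes the trait's scaled sum subject to the group size and to
        non-negative scaled sums for every trait in ``other_traits``
        (default: all other traits of the matrix).  ``min_gain_pct`` may
        replace the zero floor by a minimum desired gain for specific traits.
        Returns NaN when no group of size ``s`` qualifies.
        """
        if other_traits is None:
            other_traits = [t for t in self.matrix.traits if t != trait]
        floors = dict.fromkeys(other_traits, 0.0)
        if min_gain_pct:
            floors.update(min_gain_pct)
        n = self.matrix.n_clones
        constraints = [LinearConstraint(np.ones(n), s, s)]
        for t, rk in floors.items():
            constraints.append(LinearConstraint(self.matrix.column(t),
                                                rk * s / 100.0, np.inf))
        ub = np.ones(n)
        ub[self._excl_idx] = 0.0
        res = milp(c=-self.matrix.column(trait), constraints=constraints,
                   integrality=np.ones(n), bounds=Bounds(np.zeros(n), ub))
        if res.status == 2:
            return np.nan
        if res.status != 0:
            raise SolverError(f"MILP solver failed with status {res.status}: {res.message}")
        return 100.0 * float(-res.fun) / s

    # -- size sweep ---------------------------------------------------------------
    def sweep(self, traits_of_interest: list[str] | None = None) -> SizeSweepResult:
        """Run bounds and the criteria program for every size in the range.

        For each size ``s``: compute R_max_p and R_max_a per trait, then
        solve the criteria program.  Infeasible sizes are flagged in the
        result, and the sweep continues.
        """
        lo, hi = self.criteria.size_range
        hi = min(hi, self.n_available)
        traits = traits_of_interest or self.matrix.traits
        sols, rows = [], []
        for s in range(lo, hi + 1):
            for t in traits:
                rows.append({
                    "trait": t, "size": s,
                    "rmax_possible": self.rmax_possible(t, s),
                    "rmax_admissible": self.rmax_admissible(
                        t, s, [u for u in traits if u != t]),
                })
            sols.append(self.solve(s))
        return SizeSweepResult(solutions=sols,
                               bounds=GainBoundsTable(pd.DataFrame(rows)))

    # -- helpers ---------------------------------------------------------------
    def _available(self, y: np.ndarray) -> np.ndarray:
        if not self._excl_idx:
            return y
        mask = np.ones(len(y), bool)
        mask[self._excl_idx] = False
        return y[mask]


def brute_force_select(matrix: ScaledGainMatrix, criteria: SelectionCriteria,
                       s: int, budget: int = 10 ** 6) -> SelectionResult:
    """Exhaustive-enumeration oracle with the same contract as ``solve``.

    Enumerates every size-``s`` subset of the available clones; ties between
    optimal subsets are broken by lexicographic clone order (first optimum
    found in lexicographic enumeration wins).  Refuses instances with more
    than ``budget`` subsets.
    """
    avail = [i for i, c in enumerate(matrix.clone_ids)
             if c not in criteria.excluded_clones]
    if s > len(avail):
        raise ValueError(f"group size {s} exceeds {len(avail)} available clones")
    if comb(len(avail), s) > budget:
        raise ValueError(f"C({len(avail)}, {s}) exceeds enumeration budget {budget}")
    obj_cols = [matrix.traits.index(t) for t in criteria.objective_traits]
    cons = [(matrix.traits.index(t), rk * s / 100.0)
            for t, rk in criteria.min_gain_pct.items()]
    Y = matrix.values
    best_val, best_subset = -np.inf, None
    for subset in combinations(avail, s):
        idx = list(subset)
        if any(Y[idx, j].sum() < lk - FEAS_TOL for j, lk in cons):
            continue
        z = sum(Y[idx, j].sum() for j in obj_cols)
        if z > best_val + 1e-12:
            best_val, best_subset = z, idx
    if best_subset is None:
        return SelectionResult(size=s, feasible=False, selected_clones=[],
                               objective_value=np.nan, gains_pct={})
    gains = {t: 100.0 * float(Y[best_subset, j].mean())
             for j, t in enumerate(matrix.traits)}
    return SelectionResult(size=s, feasible=True,
                           selected_clones=[matrix.clone_ids[i] for i in best_subset],
                           objective_value=float(best_val), gains_pct=gains)
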