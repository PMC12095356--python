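"""Synthetic resolvable row-column trials with known genetic truth.

The generator draws, for each trait, independent normal replicate-level row
and column effects and plot-level residuals, and multivariate-normal clone
genotypic effects linked across traits by a specified genetic correlation
matrix (the only inter-trait dependence).  Observations are

    value = trait mean + genotype + row(rep) + col(rep) + residual,

with one residual per plot (x year x plant when those layers are simulated).
Clones are allocated once per replicate to random grid cells.  The true
genotypic effects are returned alongside the table so that estimation and
selection can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial import TrialTable

__all__ = ["SimulationConfig", "SimulatedTrial", "generate_trial",
           "generate_eblup_matrix"]


@dataclass
class SimulationConfig:
    """Design dimensions and stochastic structure of a synthetic trial.

    Defaults mirror a mid-sized clone-evaluation trial: 100 clones in 4
    resolvable replicates on a 10 x 10 grid, one year, one plant per plot,
    two must-quality-like traits with genotypic standard deviations giving
    CV_G near 20% and 5% and moderate positive genetic correlation.
    """

    n_clones: int = 100
    n_replicates: int = 4
    rows_per_replicate: int = 10
    columns_per_replicate: int = 10
    n_years: int = 1
    n_plants: int = 1
    trait_means: dict[str, float] = field(
        default_factory=lambda: {"YD": 3.5, "PA": 12.0})
    genetic_sd: dict[str, float] = field(
        default_factory=lambda: {"YD": 0.7, "PA": 0.55})
    genetic_correlation: np.ndarray | None = None   # identity when None
    sigma_row: dict[str, float] | float = 0.2
    sigma_col: dict[str, float] | float = 0.2
    sigma_e: dict[str, float] | float = 0.45
    seed: int = 0

    @property
    def traits(self) -> list[str]:
        return list(self.trait_means)

    def _per_trait(self, value) -> dict[str, float]:
        if isinstance(value, dict):
            return {t: float(value[t]) for t in self.traits}
        return {t: float(value) for t in self.traits}

    def validate(self) -> None:
        p = len(self.traits)
        if set(self.genetic_sd) != set(self.traits):
            raise ValueError("genetic_sd must cover exactly the traits of trait_means")
        if self.rows_per_replicate * self.columns_per_replicate < self.n_clones:
            raise ValueError("grid smaller than the number of clones")
        C = self.correlation()
        if C.shape != (p, p) or not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("genetic_correlation must be a symmetric p x p matrix")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("genetic_correlation must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("genetic_correlation is not positive semidefinite")

    def correlation(self) -> np.ndarray:
        if self.genetic_correlation is None:
            return np.eye(len(self.traits))
        return np.asarray(self.genetic_correlation, dtype=float)


@dataclass
class SimulatedTrial:
    """A generated plot table plus the clone-level genetic truth."""

    table: TrialTable
    true_effects: pd.DataFrame   # index clone, one column per trait
    config: SimulationConfig


def generate_trial(config: SimulationConfig) -> SimulatedTrial:
    """Draw one synthetic trial; identical seeds give identical tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    traits = config.traits
    p = len(traits)
    width = len(str(config.n_clones))
    clones = [f"C{i + 1:0{width}d}" for i in range(config.n_clones)]

    # multivariate-normal genotypic effects across traits
    sd = np.array([config.genetic_sd[t] for t in traits])
    cov = config.correlation() * np.outer(sd, sd)
    g = rng.multivariate_normal(np.zeros(p), cov, size=config.n_clones,
                                method="svd")
    truth = pd.DataFrame(g, index=pd.Index(clones, name="clone"), columns=traits)

    s_row = config._per_trait(config.sigma_row)
    s_col = config._per_trait(config.sigma_col)
    s_e = config._per_trait(config.sigma_e)

    rows = []
    n_cells = config.rows_per_replicate * config.columns_per_replicate
    multi = config.n_years > 1 or config.n_plants > 1
    for r in range(1, config.n_replicates + 1):
        cells = rng.permutation(n_cells)[: config.n_clones]
        row_eff = {t: rng.normal(0, s_row[t], config.rows_per_replicate)
                   for t in traits}
        col_eff = {t: rng.normal(0, s_col[t], config.columns_per_replicate)
                   for t in traits}
        for clone_i, cell in enumerate(cells):
            ri, ci = divmod(int(cell), config.columns_per_replicate)
            for year in range(1, config.n_years + 1):
                for plant in range(1, config.n_plants + 1):
                    rec = {"clone": clones[clone_i], "rep": f"R{r}",
                           "row": f"r{ri + 1}", "col": f"c{ci + 1}"}
                    if multi:
                        rec["year"] = f"Y{year}"
                        rec["plant"] = f"P{plant}"
                    for t in traits:
                        rec[t] = (config.trait_means[t] + g[clone_i, traits.index(t)]
                                  + row_eff[t][ri] + col_eff[t][ci]
                                  + rng.normal(0, s_e[t]))
                    rows.append(rec)
    df = pd.DataFrame(rows)
    return SimulatedTrial(table=TrialTable(df, traits=traits),
                          true_effects=truth, config=config)


def generate_eblup_matrix(n_clones: int, trait_specs: dict[str, float],
                          correlation: np.ndarray | None = None,
                          seed: int = 0) -> tuple[pd.DataFrame, dict[str, float]]:
    """Zero-mean clone x trait EBLUP-like matrix plus trait means.

    A fixture for the selection layer alone: draws multivariate-normal
    vectors with the requested inter-trait ``correlation`` and centers each
    column to sum exactly to zero, matching the sum-to-zero property of
    genotypic EBLUPs from models with an intercept.

    Parameters
    ----------
    trait_specs : dict
        trait -> (mean, sd) tuple, or trait -> sd with a unit mean.
    """
    rng = np.random.default_rng(seed)
    traits = list(trait_specs)
    means, sds = {}, []
    for t, spec in trait_specs.items():
        if isinstance(spec, (tuple, list)):
            means[t], sd = float(spec[0]), float(spec[1])
        else:
            means[t], sd = 1.0, float(spec)
        sds.append(sd)
    p = len(traits)
    C = np.eye(p) if correlation is None else np.asarray(correlation, float)
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("correlation is not positive semidefinite")
    cov = C * np.outer(sds, sds)
    E = rng.multivariate_normal(np.zeros(p), cov, size=n_clones, method="svd")
    E -= E.mean(axis=0, keepdims=True)
    width = len(str(n_clones))
    clones = [f"C{i + 1:0{width}d}" for i in range(n_clones)]
    return (pd.DataFrame(E, index=pd.Index(clones, name="clone"), columns=traits),
            means)
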