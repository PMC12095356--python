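import numpy as np
import pandas as pd
import pytest

from polyclonal import (
    CloneMixedModel,
    ModelSpec,
    SimulationConfig,
    TrialTable,
    aggregate_plots,
    generate_trial,
)


def one_way_table(n_clones=4, n_reps=3, sigma_g=1.2, sigma_e=0.6, mu=5.0, seed=3):
    """Balanced one-way layout: every clone once per replicate, no row/col."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, sigma_g, n_clones)
    rows = []
    for i in range(n_clones):
        for r in range(n_reps):
            rows.append({"clone": f"G{i + 1}", "rep": f"R{r + 1}",
                         "row": f"r{i + 1}", "col": "c1",
                         "Y": mu + g[i] + rng.normal(0, sigma_e)})
    return TrialTable(pd.DataFrame(rows), traits=["Y"])


GENOTYPE_ONLY = ModelSpec("Y", include_replicate=False,
                          include_row=False, include_col=False)


@pytest.fixture(scope="session")
def small_sim():
    """A 40-clone, 3-replicate synthetic trial with two correlated traits."""
    cfg = SimulationConfig(
        n_clones=40, n_replicates=3, rows_per_replicate=5,
        columns_per_replicate=8, seed=7,
        trait_means={"YD": 3.5, "PA": 12.0},
        genetic_sd={"YD": 0.7, "PA": 0.55},
        genetic_correlation=np.array([[1.0, 0.5], [0.5, 1.0]]),
    )
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """REML fit of the YD trait of the small synthetic trial."""
    table = aggregate_plots(small_sim.table)
    return CloneMixedModel(table, "YD").fit()
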