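"""Exchange formats between the model-fitting and selection stages.

All files are plain comma-separated text (header row, UTF-8, '.' decimals):

* per-trait EBLUP files ``eblups_<trait>.csv`` with columns
  ``clone, eblup, pev, eblup_pct_of_mean``;
* a wide ``eblups.csv`` (clone x trait) plus ``means.csv`` (trait, mean)
  consumed by the selection layer;
* a ``fit_summary.csv`` with one row per trait (variance components,
  CV_G, H2, REMLRT);
* selection criteria as a YAML document, e.g.::

      traits:
        YD:  {direction: maximize, in_objective: true, min_gain_pct: 0}
        pH:  {direction: minimize, in_objective: true, min_gain_pct: 1.0}
      sizes: "7:20"
      exclude: [C012]

  Every trait listed is constrained at its ``min_gain_pct`` (default 0);
  ``in_objective`` defaults to true; ``direction`` defaults to maximize.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reml import MixedModelResults, UndefinedHeritabilityError
from .selection import ScaledGainMatrix, SelectionCriteria

__all__ = [
    "write_fit_exchange",
    "read_eblup_tables",
    "scaled_matrix_from_tables",
    "load_criteria",
]


def write_fit_exchange(fits: list[MixedModelResults], outdir) -> dict[str, Path]:
    """Write the per-trait fit artifacts consumed by the selection stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    wide = None
    means_rows, summary_rows = [], []
    for fit in fits:
        frame = fit.eblup_frame()
        p = outdir / f"eblups_{fit.trait}.csv"
        frame.to_csv(p, index=False, float_format="%.10g")
        paths[f"eblups_{fit.trait}"] = p
        col = frame.set_index("clone")["eblup"].rename(fit.trait)
        wide = col.to_frame() if wide is None else wide.join(col, how="inner")
        means_rows.append({"trait": fit.trait, "mean": fit.overall_mean})
        c = fit.components
        try:
            h2 = fit.h2
        except UndefinedHeritabilityError:
            h2 = np.nan
        summary_rows.append({
            "trait": fit.trait, "n_obs": fit.nobs, "overall_mean": fit.overall_mean,
            "sigma2_g": c.sigma2_g,
            "sigma2_g_se": c.standard_errors.get("genotype", np.nan),
            "sigma2_row": c.sigma2_row, "sigma2_col": c.sigma2_col,
            "sigma2_e": c.sigma2_e, "cv_g_pct": fit.cv_g, "h2": h2,
            "log_reml": fit.log_reml,
        })
    wide.reset_index().to_csv(outdir / "eblups.csv", index=False, float_format="%.10g")
    pd.DataFrame(means_rows).to_csv(outdir / "means.csv", index=False,
                                    float_format="%.10g")
    pd.DataFrame(summary_rows).to_csv(outdir / "fit_summary.csv", index=False,
                                      float_format="%.6g")
    paths["eblups"] = outdir / "eblups.csv"
    paths["means"] = outdir / "means.csv"
    paths["fit_summary"] = outdir / "fit_summary.csv"
    return paths


def read_eblup_tables(eblups_path, means_path) -> tuple[pd.DataFrame, dict[str, float]]:
    """Read a wide clone x trait EBLUP table and the trait means."""
    eblups = pd.read_csv(eblups_path).set_index("clone")
    means_df = pd.read_csv(means_path)
    means = dict(zip(means_df["trait"].astype(str), means_df["mean"].astype(float)))
    missing = [t for t in eblups.columns if t not in means]
    if missing:
        raise ValueError(f"means file lacks trait(s) {missing}")
    return eblups, means


def scaled_matrix_from_tables(eblups: pd.DataFrame, means: dict[str, float],
                              directions: dict[str, str]) -> ScaledGainMatrix:
    """Build the scaled gain matrix from precomputed EBLUPs and trait means."""
    traits = [t for t in eblups.columns]
    unknown = [t for t in traits if t not in directions]
    if unknown:
        raise ValueError(f"no direction for trait(s) {unknown}")
    zero = [t for t in traits if means[t] == 0]
    if zero:
        raise ValueError(f"zero overall mean for trait(s) {zero}; cannot scale")
    cols = []
    for t in traits:
        sign = -1.0 if directions[t] == "minimize" else 1.0
        cols.append(sign * eblups[t].to_numpy(float) / means[t])
    return ScaledGainMatrix(
        clone_ids=[str(c) for c in eblups.index],
        traits=traits,
        values=np.column_stack(cols),
        directions={t: directions[t] for t in traits},
        overall_means={t: float(means[t]) for t in traits},
    )


def _parse_sizes(spec) -> tuple[int, int]:
    if isinstance(spec, (list, tuple)) and len(spec) == 2:
        return int(spec[0]), int(spec[1])
    lo, _, hi = str(spec).partition(":")
    return int(lo), int(hi or lo)


def load_criteria(path) -> tuple[dict[str, str], SelectionCriteria]:
    """Load a criteria YAML file; returns (directions, criteria)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "traits" not in doc:
        raise ValueError(f"criteria file {path} needs a top-level 'traits' mapping")
    directions, objective, min_gain = {}, [], {}
    for trait, opts in doc["traits"].items():
        opts = opts or {}
        directions[trait] = str(opts.get("direction", "maximize"))
        if opts.get("in_objective", True):
            objective.append(trait)
        min_gain[trait] = float(opts.get("min_gain_pct", 0.0))
    criteria = SelectionCriteria(
        objective_traits=objective,
        min_gain_pct=min_gain,
        size_range=_parse_sizes(doc.get("sizes", "7:20")),
        excluded_clones={str(c) for c in doc.get("exclude", []) or []},
    )
    return directions, criteria
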