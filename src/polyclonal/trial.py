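"""Plot-level field-trial tables for resolvable row-column designs.

A trial evaluates a random sample of clones of one variety in a resolvable
row-column design: each resolvable replicate contains every clone (at most
once) on a grid of rows x columns nested within the replicate.  Plot
observations may be repeated over years and over plants within a plot; the
mixed models consume one multi-year average per experimental unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mandatory identifier roles in a plot table
ID_ROLES = ("clone", "replicate", "row", "column")
#: optional identifier roles
OPTIONAL_ROLES = ("year", "plant")

DEFAULT_COLUMN_MAP = {
    "clone": "clone",
    "replicate": "rep",
    "row": "row",
    "column": "col",
    "year": "year",
    "plant": "plant",
}


class TrialFormatError(ValueError):
    """A plot table violates the expected schema or design invariants."""


@dataclass
class TrialTable:
    """Plot-level observations of one field trial.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per plot observation with identifier columns
        ``clone, rep, row, col`` (plus optional ``year``/``plant``) and one
        numeric column per trait.  Identifiers are opaque labels; no ordering
        of rows/columns is assumed.
    traits : list of str
        Names of the trait columns in ``data``.
    """

    data: pd.DataFrame
    traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in ("clone", "rep", "row", "col") if c not in self.data.columns]
        if missing:
            raise TrialFormatError(f"missing mandatory column(s): {missing}")
        if not self.traits:
            raise TrialFormatError("a trial table needs at least one trait column")
        for t in self.traits:
            if t not in self.data.columns:
                raise TrialFormatError(f"trait column {t!r} not in table")
        self._check_unique_cells()

    def _check_unique_cells(self) -> None:
        # within a replicate, a (row, col) cell holds at most one clone
        cells = self.data.groupby(["rep", "row", "col"], sort=False)["clone"].nunique()
        bad = cells[cells > 1]
        if len(bad):
            key = bad.index[0]
            raise TrialFormatError(
                f"cell rep={key[0]!r} row={key[1]!r} col={key[2]!r} is assigned "
                f"to {bad.iloc[0]} different clones"
            )

    # -- descriptive counts -------------------------------------------------
    @property
    def n_clones(self) -> int:
        return self.data["clone"].nunique()

    @property
    def n_replicates(self) -> int:
        return self.data["rep"].nunique()

    @property
    def rows_per_replicate(self) -> int:
        return int(self.data.groupby("rep")["row"].nunique().max())

    @property
    def columns_per_replicate(self) -> int:
        return int(self.data.groupby("rep")["col"].nunique().max())

    @property
    def is_aggregated(self) -> bool:
        """True when the table holds one record per experimental unit."""
        if any(c in self.data.columns for c in OPTIONAL_ROLES):
            return False
        return not self.data.duplicated(subset=["rep", "row", "col"]).any()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        if self.traits != other.traits:
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        if len(self.data) != len(other.data):
            return False
        cols = ["clone", "rep", "row", "col"]
        cols += [c for c in OPTIONAL_ROLES if c in self.data.columns]
        a = self.data.sort_values(cols, kind="stable").reset_index(drop=True)
        b = other.data.sort_values(cols, kind="stable").reset_index(drop=True)
        for c in a.columns:
            if c in self.traits:
                if not np.allclose(a[c].to_numpy(float), b[c].to_numpy(float),
                                   equal_nan=True, rtol=0, atol=1e-12):
                    return False
            elif not (a[c].astype(str) == b[c].astype(str)).all():
                return False
        return True

    def to_csv(self, path) -> None:
        """Write the table as a comma-separated file (header row, '.' decimals)."""
        self.data.to_csv(path, index=False)


def read_plot_table(path, column_map: dict[str, str] | None = None,
                    traits: list[str] | None = None) -> TrialTable:
    """Read and validate a plot-level CSV file.

    Parameters
    ----------
    path : path-like
        Comma-separated file with a header row, UTF-8, '.' decimal separator.
    column_map : dict, optional
        Mapping of role (``clone``/``replicate``/``row``/``column``/``year``/
        ``plant``) to the column name used in the file.  Defaults to
        ``clone, rep, row, col, year, plant``.
    traits : list of str, optional
        Which columns to treat as traits.  By default every column that is not
        an identifier is taken as a trait if numeric; non-numeric leftovers are
        ignored with a warning.

    Returns
    -------
    TrialTable
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)

    missing = [role for role in ID_ROLES if cmap[role] not in raw.columns]
    if missing:
        raise TrialFormatError(
            f"file {path} lacks mandatory column(s) "
            f"{[cmap[m] for m in missing]} (roles {missing})"
        )

    out = pd.DataFrame()
    rename_to = {"clone": "clone", "replicate": "rep", "row": "row",
                 "column": "col", "year": "year", "plant": "plant"}
    used = []
    for role in ID_ROLES + OPTIONAL_ROLES:
        col = cmap.get(role)
        if col in raw.columns:
            out[rename_to[role]] = raw[col].astype(str)
            used.append(col)

    candidates = traits if traits is not None else [c for c in raw.columns if c not in used]
    if traits is not None:
        absent = [t for t in traits if t not in raw.columns]
        if absent:
            raise TrialFormatError(f"trait column(s) {absent} not found in {path}")
    kept: list[str] = []
    for c in candidates:
        vals = raw[c].str.strip()
        empty = vals.isna() | (vals == "") | (vals.str.upper() == "NA")
        parsed = pd.to_numeric(vals.where(~empty), errors="coerce")
        bad = parsed.isna() & ~empty
        if bad.any():
            if traits is not None:
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise TrialFormatError(
                    f"non-numeric value {vals.iloc[i]!r} for trait {c!r} "
                    f"in data row {i + 2} of {path}"
                )
            logger.warning("ignoring non-numeric column %r in %s", c, path)
            continue
        out[c] = parsed
        kept.append(c)
    if not kept:
        raise TrialFormatError(f"no numeric trait column found in {path}")
    return TrialTable(out, traits=kept)


def aggregate_plots(table: TrialTable) -> TrialTable:
    """Average repeated observations down to one record per experimental unit.

    The multi-year plot value is the mean over years of the within-year mean
    over plants, so years with different plant counts carry equal weight.
    Missing plant/year observations are skipped; a unit with no observation at
    all for a trait keeps an explicit missing marker (NaN), never zero.
    Idempotent: aggregating an aggregated table returns it unchanged.
    """
    df = table.data
    keys = ["clone", "rep", "row", "col"]
    if "year" in df.columns:
        within = df.groupby(keys + ["year"], sort=False, dropna=False)[table.traits].mean()
        unit = within.groupby(keys, sort=False, dropna=False).mean().reset_index()
    else:
        unit = df.groupby(keys, sort=False, dropna=False)[table.traits].mean().reset_index()
    return TrialTable(unit, traits=list(table.traits))


@dataclass
class ValidationReport:
    """Design anomalies found in an aggregated trial table (report only)."""

    absent: pd.DataFrame        # columns: rep, clone  (clone missing from replicate)
    duplicated: pd.DataFrame    # columns: rep, clone, count
    empty_cells_per_replicate: pd.Series  # index rep -> count of unfilled grid cells
    missing_by_trait: pd.Series          # trait -> number of units with missing value

    @property
    def n_anomalies(self) -> int:
        return int(len(self.absent) + len(self.duplicated))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"clones absent from a replicate : {len(self.absent)}",
            f"clones duplicated in a replicate: {len(self.duplicated)}",
            f"empty grid cells per replicate : "
            f"{dict(self.empty_cells_per_replicate)}",
            f"units with missing trait values: {dict(self.missing_by_trait)}",
        ]
        return "\n".join(lines)


def validate_design(table: TrialTable) -> ValidationReport:
    """Check an aggregated table against its resolvable row-column layout.

    Reports, per replicate, clones that are absent or appear more than once,
    the number of empty grid cells (rows x columns minus occupied cells), and
    per-trait counts of units with missing values.  Never mutates the data.
    """
    df = table.data
    clones = pd.Index(sorted(df["clone"].unique()))
    reps = sorted(df["rep"].unique())

    counts = df.groupby(["rep", "clone"], sort=False).size()
    absent_rows, dup_rows = [], []
    for rep in reps:
        c = counts.loc[rep] if rep in counts.index.get_level_values(0) else pd.Series(dtype=int)
        for clone in clones.difference(c.index):
            absent_rows.append((rep, clone))
        for clone, k in c[c > 1].items():
            dup_rows.append((rep, clone, int(k)))

    grid = df.groupby("rep").agg(rows=("row", "nunique"), cols=("col", "nunique"),
                                 filled=("clone", "size"))
    empty = (grid["rows"] * grid["cols"] - grid["filled"]).rename("empty_cells")

    missing = df[table.traits].isna().sum()

    return ValidationReport(
        absent=pd.DataFrame(absent_rows, columns=["rep", "clone"]),
        duplicated=pd.DataFrame(dup_rows, columns=["rep", "clone", "count"]),
        empty_cells_per_replicate=empty,
        missing_by_trait=missing,
    )
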