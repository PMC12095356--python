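"""Per-trait genetic-variability summaries and EBLUP correlation analysis.

The variability summary lists, per trait, the overall mean, the genotypic
variance with its standard error, the coefficient of genotypic variation
CV_G, the generalized heritability H2, the extremes of the genotypic EBLUPs
as percentages of the mean, and whether the trait qualifies for selection
(H2 above a threshold, default 0.30, and a significant genotypic variance).

Correlations between traits are plain Pearson correlations of the genotypic
EBLUP vectors, tested with the t approximation on n-2 degrees of freedom and
classified by absolute value: very weak (< 0.40), weak ([0.40, 0.60)),
moderate ([0.60, 0.80)) and strong (>= 0.80); intervals closed on the left.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .reml import MixedModelResults, UndefinedHeritabilityError

__all__ = [
    "TraitSummary",
    "CorrelationEntry",
    "summarize_traits",
    "eblup_correlations",
    "classify_correlation",
    "correlation_matrix",
]

STRENGTH_LABELS = ("not significant", "very weak", "weak", "moderate", "strong")


@dataclass
class TraitSummary:
    trait: str
    overall_mean: float
    sigma2_g: float
    sigma2_g_se: float
    cv_g: float
    h2: float
    eblup_min_pct: float
    eblup_max_pct: float
    eblup_range_pct: float
    remlrt_p: float
    selectable: bool


def summarize_traits(fits: list[MixedModelResults], h2_threshold: float = 0.30,
                     alpha: float = 0.05, test_sigma_g: bool = True) -> pd.DataFrame:
    """Build the per-trait variability table from a list of fitted models.

    A trait is flagged ``selectable`` when its generalized heritability
    exceeds ``h2_threshold`` and (if ``test_sigma_g``) the genotypic variance
    is significant at level ``alpha`` by the restricted likelihood-ratio test.
    """
    rows = []
    for fit in fits:
        e_pct = 100.0 * fit.genotype_eblups.to_numpy() / fit.overall_mean
        try:
            h2 = fit.h2
        except UndefinedHeritabilityError:
            h2 = np.nan
        if test_sigma_g:
            rep = fit.test_genotypic_variance()
            p = rep.remlrt_p
        else:
            p = np.nan
        selectable = bool(np.isfinite(h2) and h2 > h2_threshold
                          and (not test_sigma_g or p < alpha))
        rows.append(TraitSummary(
            trait=fit.trait,
            overall_mean=fit.overall_mean,
            sigma2_g=fit.components.sigma2_g,
            sigma2_g_se=fit.components.standard_errors.get("genotype", np.nan),
            cv_g=fit.cv_g,
            h2=h2,
            eblup_min_pct=float(e_pct.min()),
            eblup_max_pct=float(e_pct.max()),
            eblup_range_pct=float(e_pct.max() - e_pct.min()),
            remlrt_p=p,
            selectable=selectable,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


def classify_correlation(r: float, significant: bool) -> str:
    """Strength label for a correlation coefficient.

    Non-significant correlations are labelled ``"not significant"``
    regardless of magnitude; otherwise the class depends only on ``|r|``,
    with left-closed boundaries at 0.40, 0.60 and 0.80.
    """
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"|r| = {abs(r)} exceeds 1")
    if not significant:
        return "not significant"
    a = abs(r)
    if a < 0.40:
        return "very weak"
    if a < 0.60:
        return "weak"
    if a < 0.80:
        return "moderate"
    return "strong"


@dataclass
class CorrelationEntry:
    trait_a: str
    trait_b: str
    r: float
    p_value: float
    significant: bool
    strength: str


def _pair_correlation(x: np.ndarray, y: np.ndarray, alpha: float) -> CorrelationEntry:
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant EBLUP vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    sig = p < alpha
    return CorrelationEntry("", "", r, p, sig, classify_correlation(r, sig))


def eblup_correlations(fits: list[MixedModelResults],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlations between genotypic EBLUP vectors of trait pairs.

    Clones are matched by identifier; each unordered pair needs at least
    three shared clones.  Returns one row per pair with the coefficient, the
    two-sided p-value (t approximation, n-2 df) and the strength class.
    """
    series = {f.trait: f.genotype_eblups for f in fits}
    rows = []
    for a, b in combinations(series, 2):
        common = series[a].index.intersection(series[b].index)
        if len(common) < 3:
            raise ValueError(f"traits {a!r}/{b!r} share fewer than 3 clones")
        ent = _pair_correlation(series[a].loc[common].to_numpy(),
                                series[b].loc[common].to_numpy(), alpha)
        ent.trait_a, ent.trait_b = a, b
        rows.append(ent)
    return pd.DataFrame([r.__dict__ for r in rows])


def correlation_matrix(entries: pd.DataFrame) -> pd.DataFrame:
    """Symmetric correlation matrix (unit diagonal) from pairwise entries."""
    traits = sorted(set(entries["trait_a"]) | set(entries["trait_b"]))
    M = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for _, row in entries.iterrows():
        M.loc[row["trait_a"], row["trait_b"]] = row["r"]
        M.loc[row["trait_b"], row["trait_a"]] = row["r"]
    return M


def strength_shares(entries: pd.DataFrame) -> dict[str, float]:
    """Percentage of each strength class among the significant pairs,
    plus the share of non-significant pairs among all pairs."""
    n_all = len(entries)
    sig = entries[entries["significant"]]
    out = {"not significant": 100.0 * (n_all - len(sig)) / n_all if n_all else np.nan}
    for label in STRENGTH_LABELS[1:]:
        out[label] = 100.0 * (sig["strength"] == label).mean() if len(sig) else np.nan
    return out
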