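"""Published reference tables from large polyclonal-selection field trials.

Summary statistics reported for four ancient Portuguese grapevine varieties
(Encruzado, Gouveio, Grenache, Rufete) evaluated in resolvable row-column
trials: per-trait variability summaries and pairwise correlations between
genotypic-effect EBLUPs.  The underlying plot data are not public; these
printed summaries serve as worked-example inputs and cross-checks for the
formulas in this package (e.g. CV_G = 100 * sqrt(s2_g) / mean and the
correlation-strength classification).

Trait codes: YD yield (kg/plant), PA potential alcohol (%v/v), TA total
acidity (g tartaric acid/l), pH, BW berry weight (g/berry), AC anthocyanin
content (mg/l), TP total phenols index.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_trait_summaries", "load_eblup_correlations"]

_TRAIT_SUMMARIES = """\
variety,trait,overall_mean,sigma2_g,sigma2_g_se,cv_g_pct,h2,eblup_min_pct,eblup_max_pct,eblup_range_pct,sigma_g_significant
Encruzado,YD,2.921,0.273,0.042,17.89,0.695,-41.70,30.23,71.93,True
Encruzado,PA,11.385,0.173,0.028,4.48,0.672,-8.39,9.34,17.73,True
Encruzado,TA,7.785,0.178,0.040,3.71,0.500,-13.83,11.16,24.99,True
Encruzado,pH,3.414,0.001,0.000,0.78,0.463,-1.44,1.44,2.88,True
Gouveio,YD,3.517,0.692,0.096,23.65,0.836,-42.82,56.90,99.72,True
Gouveio,PA,12.760,0.321,0.043,4.44,0.865,-13.47,8.44,21.91,True
Gouveio,TA,4.495,0.088,0.018,6.60,0.593,-10.28,19.09,29.37,True
Gouveio,pH,3.927,0.006,0.001,1.97,0.845,-3.97,3.72,7.69,True
Gouveio,BW,1.653,0.012,0.002,6.63,0.713,-14.16,14.82,28.98,True
Grenache,YD,5.213,1.165,0.184,20.71,0.808,-56.88,39.06,95.94,True
Grenache,PA,13.979,0.650,0.111,5.77,0.759,-17.15,6.87,24.02,True
Grenache,TA,3.300,0.086,0.015,8.89,0.728,-14.79,30.15,44.94,True
Grenache,pH,3.817,0.008,0.002,2.34,0.715,-5.74,3.56,9.30,True
Grenache,BW,1.712,0.010,0.002,5.84,0.624,-23.36,11.39,34.75,True
Grenache,AC,179.091,1222.12,258.38,19.52,0.623,-42.88,42.15,85.03,True
Grenache,TP,458.400,1981.33,896.35,9.71,0.316,-13.00,21.96,34.96,True
Rufete,YD,3.840,0.274,0.036,13.63,0.713,-41.07,28.70,69.77,True
Rufete,PA,13.470,0.163,0.026,3.00,0.601,-8.46,6.17,14.63,True
Rufete,TA,3.282,0.021,0.007,4.41,0.296,-5.61,13.07,18.68,True
Rufete,pH,4.109,0.002,0.000,1.09,0.603,-2.24,1.90,4.14,True
Rufete,BW,2.449,0.039,0.006,8.06,0.655,-18.17,15.39,33.56,True
Rufete,AC,252.900,1034.71,376.09,12.72,0.288,-18.24,25.03,43.27,True
Rufete,TP,571.600,1189.70,1105.26,6.03,0.117,-5.54,8.58,14.12,False
"""

_EBLUP_CORRELATIONS = """\
variety,trait_a,trait_b,r,significant
Encruzado,YD,PA,-0.46,True
Encruzado,YD,TA,0.05,False
Encruzado,YD,pH,-0.23,True
Encruzado,PA,TA,-0.48,True
Encruzado,PA,pH,0.51,True
Encruzado,TA,pH,-0.61,True
Gouveio,YD,PA,-0.04,False
Gouveio,YD,TA,0.03,False
Gouveio,YD,pH,-0.43,True
Gouveio,YD,BW,-0.09,False
Gouveio,PA,TA,-0.18,True
Gouveio,PA,pH,0.50,True
Gouveio,PA,BW,0.26,True
Gouveio,TA,pH,-0.52,True
Gouveio,TA,BW,0.03,False
Gouveio,pH,BW,0.16,False
Grenache,YD,PA,0.33,True
Grenache,YD,TA,-0.30,True
Grenache,YD,pH,0.29,True
Grenache,YD,BW,0.05,False
Grenache,YD,AC,0.23,True
Grenache,YD,TP,0.22,True
Grenache,PA,TA,-0.74,True
Grenache,PA,pH,0.73,True
Grenache,PA,BW,0.18,True
Grenache,PA,AC,0.83,True
Grenache,PA,TP,0.67,True
Grenache,TA,pH,-0.55,True
Grenache,TA,BW,-0.02,False
Grenache,TA,AC,-0.69,True
Grenache,TA,TP,-0.56,True
Grenache,pH,BW,0.28,True
Grenache,pH,AC,0.44,True
Grenache,pH,TP,0.32,True
Grenache,BW,AC,-0.02,False
Grenache,BW,TP,-0.03,False
Grenache,AC,TP,0.84,True
Rufete,YD,PA,-0.09,False
Rufete,YD,pH,-0.43,True
Rufete,YD,BW,0.09,False
Rufete,PA,pH,0.30,True
Rufete,PA,BW,0.25,True
Rufete,pH,BW,0.27,True
"""


def load_trait_summaries() -> pd.DataFrame:
    """Per-variety, per-trait published variability summaries.

    Columns: variety, trait, overall_mean, sigma2_g (with SE), cv_g_pct, h2,
    EBLUP extremes as % of the mean, and whether the genotypic variance was
    reported significant at the 0.05 level.
    """
    return pd.read_csv(io.StringIO(_TRAIT_SUMMARIES))


def load_eblup_correlations() -> pd.DataFrame:
    """Published pairwise correlations between genotypic EBLUPs (43 pairs).

    Columns: variety, trait_a, trait_b, r, significant (at the 0.05 level,
    as marked in the published table).
    """
    df = pd.read_csv(io.StringIO(_EBLUP_CORRELATIONS))
    df["significant"] = df["significant"].astype(bool)
    return df
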