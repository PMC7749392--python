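"""Spearman rank screening of quality predictors.

Every candidate feature is rank-correlated with the specific volumes of
both baking recipes.  A feature is retained for scoring when it is
significantly correlated (p <= alpha) with *both* recipes and belongs
to one of the instrumental test families (aggregation or extension; the
protein-composition features correlate only weakly and are excluded
from scoring).  Each retained feature gets a weight equal to the mean
of its two absolute coefficients and a direction equal to their common
sign.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import DataQualityWarning

__all__ = [
    "spearman",
    "correlation_table",
    "select_scored_parameters",
    "load_published_correlations",
    "PARAMETER_FAMILIES",
    "SCORED_FAMILIES",
]

#: family of each feature column produced by the extraction modules
PARAMETER_FAMILIES: dict[str, str] = {
    **{p: "aggregation" for p in
       ("pmt", "bem", "peak30", "peak180", "ratio30_180",
        "y0", "xc1", "a", "w", "k2", "xc2", "b", "k3", "xc3")},
    **{p: "extension" for p in
       ("r_max", "e_rmax", "a_rmax", "e_max", "a_max",
        "ratio_ermax_rmax", "ratio_emax_rmax")},
    **{p: "protein" for p in
       ("hmw_gliadins", "mmw_gliadins", "lmw_gliadins", "gliadins",
        "hmw_glutenins", "mmw_glutenins", "lmw_glutenins", "glutenins",
        "glia_glut_ratio")},
}

#: families whose significant features enter the scoring system
SCORED_FAMILIES = ("aggregation", "extension")


def spearman(x, y, *, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    The coefficient is the Pearson correlation of mid-ranks (average
    ranks on ties).  ``method='t'`` derives p from the t-distribution
    with n - 2 degrees of freedom; ``method='permutation'`` enumerates
    all permutations (exact; feasible for n <= 8).  Constant input
    yields ``(nan, nan)`` with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined",
                      DataQualityWarning, stacklevel=2)
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        # identical to the t-approximation with n - 2 df
        p = float(stats.pearsonr(rx, ry).pvalue)
    elif method == "permutation":
        if n > 8:
            raise ValueError("exact permutation p-value only supported for "
                             f"n <= 8 ({math.factorial(n)} permutations at n={n})")
        count = 0
        total = 0
        for perm in permutations(ry):
            rp = float(np.corrcoef(rx, perm)[0, 1])
            count += abs(rp) >= abs(r) - 1e-12
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return r, p


def correlation_table(features: pd.DataFrame, volumes: pd.DataFrame, *,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlations of every feature with both recipe volumes.

    ``features`` is indexed by sample id with one column per feature;
    ``volumes`` has columns ``volume_A_ml_per_g`` and
    ``volume_B_ml_per_g`` on the same index.  Missing values are
    dropped pairwise and the effective n is reported per recipe.
    """
    common = features.index.intersection(volumes.index)
    if len(common) == 0:
        raise ValueError("no shared sample ids between features and volumes")
    feats = features.loc[common]
    vols = volumes.loc[common]
    rows = []
    for col in feats.columns:
        entry = {"parameter": col,
                 "family": PARAMETER_FAMILIES.get(col, "other")}
        for recipe, vcol in (("A", "volume_A_ml_per_g"), ("B", "volume_B_ml_per_g")):
            pair = pd.concat([feats[col], vols[vcol]], axis=1).dropna()
            if len(pair) < 4 or pair[col].nunique() == 1:
                r, p = float("nan"), float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DataQualityWarning)
                    r, p = spearman(pair[col].to_numpy(), pair[vcol].to_numpy())
            entry[f"r_{recipe}"] = r
            entry[f"p_{recipe}"] = p
            entry[f"n_{recipe}"] = len(pair)
        entry["significant_both"] = bool(
            entry["p_A"] <= alpha and entry["p_B"] <= alpha)
        rows.append(entry)
    return pd.DataFrame(rows)


def select_scored_parameters(entries: pd.DataFrame, *, alpha: float = 0.05,
                             rule: str = "both",
                             families: tuple[str, ...] = SCORED_FAMILIES,
                             ) -> pd.DataFrame:
    """Weight table of the parameters retained for scoring.

    ``entries`` is a correlation table with columns ``parameter``,
    ``family``, ``r_A``, ``p_A``, ``r_B``, ``p_B`` (missing p-values
    count as not significant).  ``rule='both'`` keeps parameters
    significant in both recipes; ``rule='either'`` in at least one.
    Weight = mean of |r_A| and |r_B|; direction = their common sign.
    Parameters whose coefficients disagree in sign are dropped with a
    warning.
    """
    pa = entries["p_A"].fillna(np.inf)
    pb = entries["p_B"].fillna(np.inf)
    if rule == "both":
        sig = (pa <= alpha) & (pb <= alpha)
    elif rule == "either":
        sig = (pa <= alpha) | (pb <= alpha)
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    fam = entries["family"] if "family" in entries else entries["parameter"].map(
        lambda p: PARAMETER_FAMILIES.get(p, "other"))
    keep = entries[sig & fam.isin(families)]
    rows = []
    for _, e in keep.iterrows():
        sa, sb = np.sign(e["r_A"]), np.sign(e["r_B"])
        if sa != sb:
            warnings.warn(f"{e['parameter']}: correlation signs disagree "
                          "between recipes; excluded from scoring",
                          DataQualityWarning, stacklevel=2)
            continue
        rows.append({"parameter": e["parameter"],
                     "weight": (abs(e["r_A"]) + abs(e["r_B"])) / 2.0,
                     "direction": int(sa)})
    return pd.DataFrame(rows, columns=["parameter", "weight", "direction"])


def load_published_correlations() -> pd.DataFrame:
    """The packaged published correlation table for the 46-sample panel
    (coefficients and p-values for both recipes; blank p = not
    significant at the 0.05 level)."""
    from importlib import resources
    with resources.files("vitalgluten.data").joinpath(
            "published_correlations.csv").open() as fh:
        return pd.read_csv(fh)
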