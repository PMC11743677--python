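"""Cohort-level statistics and group-difference maps.

Two small analysis utilities that sit beside the classifier protocol:

* :func:`cohort_statistics` reproduces a demographics table — pooled-
  variance two-sample t statistics for continuous variables given as
  (mean, SD, n) summaries, and Pearson chi-square statistics (no
  continuity correction) for categorical contingency counts;
* :func:`group_difference_map` screens every feature with a Wilcoxon
  rank-sum test between the two groups and organizes the p-values by
  channel (or channel pair), the tabular counterpart of a p-value
  topography.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

__all__ = [
    "pooled_t_from_summary",
    "pearson_chi2",
    "cohort_statistics",
    "group_difference_map",
    "top_connections",
]


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> Tuple[float, int, float]:
    """Two-sample t with pooled variance from summary statistics.

    Returns ``(t, df, p)`` with ``df = n1 + n2 - 2`` and a two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = 0.0 if se == 0 else (mean1 - mean2) / se
    p = 2 * stats.t.sf(abs(t), df) if se > 0 else 1.0
    return t, df, p


def pearson_chi2(counts: Sequence[Sequence[int]]) -> Tuple[float, int, float]:
    """Pearson chi-square for a contingency table, without continuity
    correction.  Returns ``(chi2, dof, p)``."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("counts must be a nonnegative 2-D table")
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def cohort_statistics(
    continuous: Optional[Mapping[str, Tuple[float, float, int, float, float, int]]] = None,
    categorical: Optional[Mapping[str, Sequence[Sequence[int]]]] = None,
) -> pd.DataFrame:
    """Demographics-table statistics for a two-group cohort.

    ``continuous`` maps a variable name to
    ``(mean1, sd1, n1, mean2, sd2, n2)``; ``categorical`` maps a name to
    a groups-x-levels contingency table.  Returns one row per variable
    with the test name, statistic, degrees of freedom and p-value.
    """
    rows = []
    for name, (m1, s1, n1, m2, s2, n2) in (continuous or {}).items():
        t, df, p = pooled_t_from_summary(m1, s1, n1, m2, s2, n2)
        rows.append({"variable": name, "test": "t", "statistic": t, "df": df, "p": p})
    for name, table in (categorical or {}).items():
        chi2, dof, p = pearson_chi2(table)
        rows.append({"variable": name, "test": "chi2", "statistic": chi2,
                     "df": dof, "p": p})
    if not rows:
        raise ValueError("no variables given")
    return pd.DataFrame(rows).set_index("variable")


def _feature_location(column: str) -> str:
    """Channel or channel-pair part of a feature name (after '__')."""
    return column.rsplit("__", 1)[1] if "__" in column else column


def group_difference_map(
    matrix: FeatureMatrix,
    feature_prefix: str = "",
) -> pd.DataFrame:
    """Wilcoxon rank-sum p-value for every feature, PMCI vs SMCI.

    ``feature_prefix`` restricts the screen to one feature family (e.g.
    ``"ratio1"`` or ``"pli_full"``).  The result has one row per feature
    with its location (channel or channel pair) split out, sorted by
    ascending p — a tabular p-value topography.
    """
    columns = [c for c in matrix.values.columns if c.startswith(feature_prefix)]
    if not columns:
        raise ValueError(f"no features match prefix {feature_prefix!r}")
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be present")
    a = matrix.values.loc[:, columns].to_numpy(dtype=float)[y == 1]
    b = matrix.values.loc[:, columns].to_numpy(dtype=float)[y == 0]
    with np.errstate(all="ignore"):
        res = stats.ranksums(a, b, axis=0, nan_policy="omit")
    out = pd.DataFrame({
        "feature": columns,
        "location": [_feature_location(c) for c in columns],
        "statistic": np.asarray(res.statistic, dtype=float),
        "p": np.asarray(res.pvalue, dtype=float),
    }).set_index("feature")
    return out.sort_values("p")


def top_connections(pmap: pd.DataFrame, n: int = 15) -> pd.DataFrame:
    """The ``n`` connections (or channels) with the smallest p-values,
    sorted ascending — e.g. the 15 strongest group-difference edges of a
    connectivity measure."""
    return pmap.nsmallest(n, "p")
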