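"""Inferential tests applied to pipeline outputs.

The proportions contrast uses the pooled two-proportion z-test (normal
approximation, no continuity correction), signed as group2 − group1 so a
lower experimental fraction yields a negative statistic.  Its squared value
is identically the 2x2 Pearson chi-square, which is provided as a
cross-check.  Paired t and Kruskal-Wallis delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import AnalysisError


@dataclass
class PropTestResult:
    k1: int
    n1: int
    k2: int
    n2: int
    z: float
    p: float


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> PropTestResult:
    """Pooled-variance two-proportion z-test, statistic signed as p2 − p1.

    z = (p2 − p1) / sqrt(p̂(1 − p̂)(1/n1 + 1/n2)), p̂ = (k1 + k2)/(n1 + n2);
    two-sided normal p-value, no continuity correction.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise AnalysisError(f"invalid counts k={k}, n={n}")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        raise AnalysisError("degenerate pooled proportion (0 or 1): z undefined")
    z = (p2 - p1) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return PropTestResult(k1=k1, n1=n1, k2=k2, n2=n2, z=float(z), p=float(p))


def pearson_chi2_2x2(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Pearson chi-square on the 2x2 table, no continuity correction.

    Identically equals z² of :func:`two_proportion_z`.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise AnalysisError(f"invalid counts k={k}, n={n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.sum(axis=0).min() == 0:
        raise AnalysisError("degenerate margin: chi-square undefined")
    res = sps.chi2_contingency(table, correction=False)
    return {"chi2": float(res.statistic), "p": float(res.pvalue)}


def paired_t(x, y) -> dict:
    """Two-sided paired t-test (sample SD of differences, df = n − 1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise AnalysisError("paired samples must have equal length >= 2")
    d = x - y
    if d.std(ddof=1) == 0:
        raise AnalysisError("zero-variance differences: t undefined")
    res = sps.ttest_rel(x, y)
    return {"t": float(res.statistic), "df": int(res.df), "p": float(res.pvalue)}


def kruskal_wallis(groups) -> dict:
    """Rank-based Kruskal-Wallis H (tie-corrected), chi-square p with k−1 df."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise AnalysisError("need >= 2 groups, each with >= 1 observation")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(flat == flat[0]):
        return {"H": 0.0, "p": 1.0}
    res = sps.kruskal(*groups)
    return {"H": float(res.statistic), "p": float(res.pvalue)}


__all__ = [
    "PropTestResult", "two_proportion_z", "pearson_chi2_2x2",
    "paired_t", "kruskal_wallis",
]
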