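"""Replication enrichment of an external PRS variant list in a GWAS.

Under a null of no replication, the GWAS p-values of previously
ascertained polygenic-risk-score variants are uniform; enrichment of
small p-values is quantified as the fold excess of variants below a
threshold and tested with an exact binomial upper tail.  Feature
stratification (effect size, LD-score difference, MAF, F_ST, allele
age, ...) uses two-sided Wilcoxon rank-sum tests between replicating
and non-replicating variants.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError

__all__ = [
    "EnrichmentResult",
    "replication_enrichment",
    "pvalue_histogram",
    "feature_stratified_test",
]


class EnrichmentResult(NamedTuple):
    m: int          # variants tested
    k: int          # variants with p < alpha
    expected: float  # m * alpha
    fold: float      # (k/m) / alpha
    p: float         # exact binomial upper tail P(X >= k)


def replication_enrichment(p_values, alpha: float = 0.05) -> EnrichmentResult:
    """Fold enrichment of small GWAS p-values among PRS variants.

    ``fold = (k/m)/alpha`` where ``k`` counts p-values below ``alpha``,
    so ``fold * alpha * m = k`` exactly and ``fold <= 1/alpha``.
    Significance is the exact upper binomial tail of ``k`` out of ``m``
    at success probability ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("need at least one p-value")
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must lie in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    k = int(np.sum(p < alpha))
    m = int(p.size)
    tail = float(stats.binomtest(k, m, alpha, alternative="greater").pvalue)
    return EnrichmentResult(m=m, k=k, expected=m * alpha,
                            fold=(k / m) / alpha, p=tail)


def pvalue_histogram(p_values, bin_width: float = 0.05) -> pd.DataFrame:
    """Histogram of p-values on [0, 1] with a low-p flag per bin.

    ``bin_width`` must divide 1 evenly.  Bins are left-closed and
    right-open except the last, which is closed, so counts always sum
    to the number of p-values.  ``low_p`` flags bins lying entirely at
    or below 0.05 (the conventional replication threshold).
    """
    p = np.asarray(p_values, dtype=float)
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9 or n_bins < 1:
        raise ParameterError("bin_width must divide 1 evenly")
    if p.size and np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "low_p": edges[1:] <= 0.05 + 1e-12,
    })


def feature_stratified_test(replicating, non_replicating) -> tuple[float, float, str]:
    """Wilcoxon rank-sum comparison of a feature between replicating
    and non-replicating variants.

    Returns ``(statistic, two-sided p, direction)`` where direction
    names the group with the larger median ("replicating",
    "non_replicating", or "tied").
    """
    x = np.asarray(replicating, dtype=float)
    y = np.asarray(non_replicating, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both groups must be non-empty")
    stat, p = stats.ranksums(x, y)
    mx, my = np.median(x), np.median(y)
    if mx > my:
        direction = "replicating"
    elif mx < my:
        direction = "non_replicating"
    else:
        direction = "tied"
    return float(stat), float(p), direction
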