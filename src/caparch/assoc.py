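"""Allelic association statistics and fixed-effect meta-analysis.

Per-variant association comes from the 2x2 allele-count table (Woolf
log-odds estimator with Haldane-Anscombe continuity correction),
regional estimates are combined by inverse-variance fixed-effect
meta-analysis with Cochran's Q and the I^2 heterogeneity percentage,
and the module also provides the genomic inflation factor, pairwise
LD (r^2 and D'), and greedy LD pruning of ranked association lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError, UndefinedStatisticError

__all__ = [
    "GENOME_WIDE_P",
    "MARGINAL_P",
    "MetaResult",
    "allelic_log_or",
    "regional_association",
    "fixed_effect_meta",
    "meta_analysis_table",
    "genomic_lambda",
    "ld_r2",
    "greedy_ld_prune",
]

#: Conventional genome-wide and marginal significance thresholds.
GENOME_WIDE_P = 5e-8
MARGINAL_P = 1e-5

#: Median of the chi-square distribution with 1 df (null median of the
#: association chi-square; denominator of the inflation factor).
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effect meta-analysis of one variant across k studies."""

    beta: float
    se: float
    p: float
    q: float          # Cochran heterogeneity statistic
    df: int           # k - 1
    i2: float         # percent heterogeneity, in [0, 100]


def _woolf_arrays(case_eff, case_other, ctrl_eff, ctrl_other):
    """Vectorised Woolf estimator.

    Adds 0.5 to every cell of a table containing a zero cell; tables
    with an all-zero margin yield NaN (the statistic is undefined).
    Returns (beta, se, p) float arrays.
    """
    a = np.asarray(case_eff, dtype=float)
    b = np.asarray(case_other, dtype=float)
    c = np.asarray(ctrl_eff, dtype=float)
    d = np.asarray(ctrl_other, dtype=float)
    bad_margin = ((a + b == 0) | (c + d == 0) | (a + c == 0) | (b + d == 0))
    correct = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (x + 0.5 * correct for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(a * d) - np.log(b * c)
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
    beta = np.where(bad_margin, np.nan, beta)
    se = np.where(bad_margin, np.nan, se)
    p = np.where(bad_margin, np.nan, p)
    return beta, se, p


def allelic_log_or(case_eff: int, case_other: int, ctrl_eff: int, ctrl_other: int
                   ) -> tuple[float, float, float]:
    """Log odds ratio, standard error and Wald p from a 2x2 allele table.

    ``beta = ln[(case_eff * ctrl_other) / (case_other * ctrl_eff)]``,
    ``SE = sqrt(sum of reciprocal cells)`` and ``p`` is the two-sided
    normal tail of ``beta/SE``.  If any cell is zero, 0.5 is added to
    every cell (Haldane-Anscombe) before estimation.

    Raises
    ------
    ParameterError
        If any count is negative.
    UndefinedStatisticError
        If a margin of the table is entirely zero.
    """
    counts = (case_eff, case_other, ctrl_eff, ctrl_other)
    if any(x < 0 for x in counts):
        raise ParameterError("allele counts must be non-negative")
    beta, se, p = _woolf_arrays(*counts)
    if np.isnan(beta):
        raise UndefinedStatisticError(
            "2x2 table has an all-zero margin; the log odds ratio is undefined")
    return float(beta), float(se), float(p)


def regional_association(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-variant, per-region association from a tidy allele-count table.

    Expects the columns written by the simulator (``VariantID, Region,
    CaseEffCount, CaseTotal, CtrlEffCount, CtrlTotal``) and appends
    ``FREQ`` (control effect-allele frequency), ``BETA``, ``SE`` and
    ``P``.  Variants with an all-zero table margin get NaN statistics.
    """
    out = counts.copy()
    a = out["CaseEffCount"].to_numpy(float)
    b = out["CaseTotal"].to_numpy(float) - a
    c = out["CtrlEffCount"].to_numpy(float)
    d = out["CtrlTotal"].to_numpy(float) - c
    beta, se, p = _woolf_arrays(a, b, c, d)
    out["FREQ"] = c / out["CtrlTotal"].to_numpy(float)
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = p
    return out


def fixed_effect_meta(betas, ses) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis.

    Weights are ``w = 1/SE^2``; the pooled estimate is
    ``sum(w beta)/sum(w)`` with ``SE = 1/sqrt(sum w)``.  Heterogeneity:
    ``Q = sum w (beta - pooled)^2`` on ``k - 1`` df and
    ``I^2 = max(0, (Q - df)/Q) * 100``.
    """
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    ses = np.atleast_1d(np.asarray(ses, dtype=float))
    if betas.size == 0:
        raise ParameterError("meta-analysis needs at least one estimate")
    if betas.shape != ses.shape:
        raise ParameterError("betas and ses must have the same length")
    if np.any(ses <= 0) or np.any(~np.isfinite(ses)) or np.any(~np.isfinite(betas)):
        raise ParameterError("all standard errors must be finite and positive")
    w = 1.0 / ses ** 2
    pooled = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(pooled / se)))
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = int(betas.size - 1)
    i2 = 0.0 if q == 0.0 else max(0.0, (q - df) / q) * 100.0
    return MetaResult(beta=pooled, se=se, p=p, q=q, df=df, i2=i2)


def meta_analysis_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Combine per-region association rows into one pooled row per variant.

    Input is the output of :func:`regional_association` for several
    regions.  Regions with undefined (NaN) estimates for a variant are
    dropped from that variant's meta-analysis.  The result has one row
    per variant: pooled ``BETA, SE, P``, heterogeneity ``Q, DF, I2``
    and one ``FREQ_<region>`` column per region.
    """
    rows = []
    regions = list(dict.fromkeys(assoc["Region"]))
    for vid, grp in assoc.groupby("VariantID", sort=True):
        ok = grp[np.isfinite(grp["BETA"]) & np.isfinite(grp["SE"])]
        if len(ok) == 0:
            continue
        res = fixed_effect_meta(ok["BETA"].to_numpy(), ok["SE"].to_numpy())
        row = {"VariantID": vid, "BETA": res.beta, "SE": res.se, "P": res.p,
               "Q": res.q, "DF": res.df, "I2": res.i2}
        freq = dict(zip(grp["Region"], grp["FREQ"]))
        for region in regions:
            row[f"FREQ_{region}"] = freq.get(region, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: the median association chi-square
    divided by the null chi-square(1) median (~0.4549)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("genomic lambda needs at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, 1)
    return float(np.median(chisq) / CHI2_1DF_MEDIAN)


def ld_r2(hap_a, hap_b) -> tuple[float, float]:
    """Pairwise LD between two 0/1 haplotype vectors.

    Returns ``(r^2, D')`` where ``D = f11 - pA pB``,
    ``r^2 = D^2 / (pA (1-pA) pB (1-pB))`` and ``D' = D / Dmax``.
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("haplotype vectors must be 1-D and of equal length")
    pa = float(np.mean(a))
    pb = float(np.mean(b))
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise UndefinedStatisticError("LD is undefined at a monomorphic site")
    f11 = float(np.mean((a == 1) & (b == 1)))
    d = f11 - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return 0.0, 0.0
    return r2, d / dmax


def greedy_ld_prune(p_values, r2_matrix, threshold: float = 0.2,
                    ids: Sequence | None = None) -> list:
    """Greedy LD pruning of an association list.

    Variants are visited in order of ascending p-value (stable sort,
    so input order breaks ties); a variant is retained iff its r^2
    with every already-retained variant is below ``threshold``.

    Parameters
    ----------
    p_values : array-like, shape (m,)
    r2_matrix : array-like, shape (m, m)
        Pairwise r^2 aligned with ``p_values``.
    threshold : float
        r^2 threshold in (0, 1]; the conventional default is 0.2.
    ids : sequence, optional
        Labels to return; defaults to integer indices.
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError("r^2 threshold must lie in (0, 1]")
    p = np.asarray(p_values, dtype=float)
    r2 = np.asarray(r2_matrix, dtype=float)
    if r2.shape != (p.size, p.size):
        raise ParameterError("r2_matrix must be square and match p_values")
    labels = list(ids) if ids is not None else list(range(p.size))
    retained: list[int] = []
    for i in np.argsort(p, kind="stable"):
        if all(r2[i, j] < threshold for j in retained):
            retained.append(int(i))
    return [labels[i] for i in retained]
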