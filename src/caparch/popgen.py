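"""Population-genetic scoring of disease-associated variants.

Hudson's two-population F_ST, population branch statistics (PBS) with
empirical outlier percentiles, private-allele classification, and
haplotype-based selection scans (EHH and the integrated haplotype
score iHS with within-frequency-bin standardisation and a normality
check).  These statistics ask whether trait-associated variants show
unusual allele-frequency differentiation or haplotype structure
relative to neutral expectations -- i.e. whether drift or selection
shaped them.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError, UndefinedStatisticError

__all__ = [
    "hudson_fst",
    "pbs",
    "pbs_outlier_percentile",
    "classify_private",
    "ehh",
    "ihs",
    "ihs_unstandardized",
    "standardize_ihs",
    "NormalityReport",
    "normality_check",
]

#: EHH level below which integration stops (conventional iHS setting).
EHH_CUTOFF = 0.05

#: Default derived-allele-frequency bin width for iHS standardisation.
IHS_BIN_WIDTH = 0.05

#: Default "effectively monomorphic" minor-allele-frequency threshold.
PRIVATE_MAF_THRESHOLD = 0.01


def hudson_fst(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson's single-SNP F_ST estimator for two populations.

    ``N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and
    ``D = p1(1-p2) + p2(1-p1)``; the estimate ``N/D`` may be slightly
    negative at low true differentiation (an unbiasedness artefact).

    ``n1, n2`` are allele sample sizes (>= 2).
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("allele sample sizes must be at least 2")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ParameterError("allele frequencies must lie in [0, 1]")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0.0:
        raise UndefinedStatisticError(
            "both populations are monomorphic for the same allele; F_ST undefined")
    return num / den


def pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> float:
    """Population branch statistic for population A.

    Branch lengths are ``T = -ln(1 - F_ST)``;
    ``PBS_A = (T_AB + T_AC - T_BC) / 2``.  Negative single-SNP F_ST is
    clamped to 0 (branch lengths stay non-negative) and F_ST is capped
    at ``1 - 1e-9`` before the log.
    """
    ts = []
    for f in (fst_ab, fst_ac, fst_bc):
        if f >= 1.0 + 1e-12:
            raise ParameterError(f"F_ST must be below 1, got {f}")
        f = min(max(f, 0.0), 1.0 - 1e-9)
        ts.append(-np.log1p(-f))
    t_ab, t_ac, t_bc = ts
    return (t_ab + t_ac - t_bc) / 2.0


def pbs_outlier_percentile(focal, background) -> np.ndarray:
    """Empirical percentile of focal PBS values within a background.

    A focal value gets the midrank it would take inside the background
    (``#less + (#equal + 1)/2``, i.e. ``#less + 0.5`` between
    background points) mapped onto 0-100 via ``100 (rank-1)/(n-1)``
    and clipped to [0, 100].  The background minimum scores 0, the
    maximum 100, and the median of an odd-sized background 50.
    """
    bg = np.sort(np.asarray(background, dtype=float))
    if bg.size == 0:
        raise ParameterError("background must be non-empty")
    focal = np.atleast_1d(np.asarray(focal, dtype=float))
    less = np.searchsorted(bg, focal, side="left")
    less_eq = np.searchsorted(bg, focal, side="right")
    rank = less + (less_eq - less + 1) / 2.0
    if bg.size == 1:
        pct = np.where(rank >= 1.0, 100.0, 0.0)
    else:
        pct = 100.0 * (rank - 1.0) / (bg.size - 1.0)
    return np.clip(pct, 0.0, 100.0)


def classify_private(freqs_by_population: Mapping[str, float], target: str,
                     maf_threshold: float = PRIVATE_MAF_THRESHOLD) -> str:
    """Classify a variant's geographic breadth from per-population
    effect-allele frequencies.

    Returns ``"private_to_target"`` when the variant is polymorphic in
    the target (minor-allele frequency above ``maf_threshold``) but
    effectively monomorphic everywhere else, ``"absent_in_target"``
    when the target itself is effectively monomorphic, and
    ``"shared"`` otherwise.  The classification uses
    ``min(f, 1-f)`` throughout, so it is invariant to allele-label
    flips.
    """
    if not (0.0 <= maf_threshold < 0.5):
        raise ParameterError("maf_threshold must lie in [0, 0.5)")
    if target not in freqs_by_population:
        raise ParameterError(f"target population {target!r} not present")
    maf = {pop: min(f, 1.0 - f) for pop, f in freqs_by_population.items()}
    if maf[target] <= maf_threshold:
        return "absent_in_target"
    others = [pop for pop in freqs_by_population if pop != target]
    if others and all(maf[pop] <= maf_threshold for pop in others):
        return "private_to_target"
    return "shared"


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------

def _ehh_walk(carriers: np.ndarray, site_order: np.ndarray) -> np.ndarray:
    """EHH over a sequence of sites for a fixed carrier set.

    ``EHH(s)`` is the fraction of carrier pairs identical over every
    site visited so far; it starts at 1 and is non-increasing.
    """
    k = carriers.shape[0]
    pairs_total = k * (k - 1) // 2
    group = np.zeros(k, dtype=np.int64)
    out = np.empty(site_order.size + 1)
    out[0] = 1.0
    for step, s in enumerate(site_order, start=1):
        group = np.unique(group * 2 + carriers[:, s], return_inverse=True)[1]
        counts = np.bincount(group)
        out[step] = (counts * (counts - 1) // 2).sum() / pairs_total
    return out


def ehh(haplotypes, core_site: int, core_allele: int, direction: str
        ) -> tuple[np.ndarray, np.ndarray]:
    """Extended haplotype homozygosity away from a core site.

    Among haplotypes carrying ``core_allele`` at ``core_site``, EHH at
    site ``s`` is the fraction of carrier pairs that are identical over
    the whole interval from the core to ``s``.  Returns
    ``(site_indices, ehh_values)`` starting at the core (EHH = 1) and
    walking to the ``"left"`` or ``"right"`` chromosome end.

    Raises
    ------
    UndefinedStatisticError
        If fewer than two haplotypes carry the core allele.
    """
    h = np.asarray(haplotypes)
    if h.ndim != 2:
        raise ParameterError("haplotypes must be a 2-D (haplotype x site) matrix")
    if direction not in ("left", "right"):
        raise ParameterError("direction must be 'left' or 'right'")
    carriers = h[h[:, core_site] == core_allele]
    if carriers.shape[0] < 2:
        raise UndefinedStatisticError(
            "EHH needs at least two carriers of the core allele")
    if direction == "right":
        order = np.arange(core_site + 1, h.shape[1])
    else:
        order = np.arange(core_site - 1, -1, -1)
    sites = np.concatenate([[core_site], order])
    return sites, _ehh_walk(carriers, order)


def _ihh(h: np.ndarray, positions: np.ndarray, core: int, allele: int,
         cutoff: float) -> float:
    """Integrated EHH (both directions, trapezoid rule) for one allele.

    Integration runs over consecutive sites while EHH stays at or above
    ``cutoff``, or to the chromosome end."""
    total = 0.0
    for direction in ("left", "right"):
        sites, curve = ehh(h, core, allele, direction)
        below = np.nonzero(curve < cutoff)[0]
        stop = below[0] if below.size else curve.size
        if stop < 2:
            continue
        x = np.abs(positions[sites[:stop]] - positions[core])
        total += float(np.trapezoid(curve[:stop], x))
    return total


def ihs_unstandardized(haplotypes, positions, derived_allele: int = 1,
                       maf_min: float = 0.01, ehh_cutoff: float = EHH_CUTOFF
                       ) -> pd.DataFrame:
    """Unstandardised iHS for every qualifying site of one chromosome.

    Sites with minor-allele frequency below ``maf_min`` are excluded.
    For each remaining site, ``iHH`` integrates EHH against genetic
    position separately for ancestral and derived carriers (truncated
    where EHH drops below ``ehh_cutoff``), and the unstandardised score
    is ``ln(iHH_ancestral / iHH_derived)``.  Sites where either
    integral is zero (or an allele has fewer than two carriers) are
    dropped.

    Returns columns ``site, derived_freq, ihh_a, ihh_d, ihs_unstd``.
    """
    h = np.asarray(haplotypes)
    if h.ndim != 2:
        raise ParameterError("haplotypes must be a 2-D (haplotype x site) matrix")
    if derived_allele not in (0, 1):
        raise ParameterError("derived_allele must be 0 or 1")
    pos = np.asarray(positions, dtype=float)
    if pos.size != h.shape[1]:
        raise ParameterError("positions must match the number of sites")
    ancestral = 1 - derived_allele
    rows = []
    for site in range(h.shape[1]):
        p_der = float(np.mean(h[:, site] == derived_allele))
        if min(p_der, 1.0 - p_der) < maf_min:
            continue
        if min(p_der, 1.0 - p_der) * h.shape[0] < 2:
            continue
        ihh_d = _ihh(h, pos, site, derived_allele, ehh_cutoff)
        ihh_a = _ihh(h, pos, site, ancestral, ehh_cutoff)
        if ihh_d <= 0.0 or ihh_a <= 0.0:
            continue
        rows.append({"site": site, "derived_freq": p_der,
                     "ihh_a": ihh_a, "ihh_d": ihh_d,
                     "ihs_unstd": float(np.log(ihh_a / ihh_d))})
    return pd.DataFrame(rows, columns=["site", "derived_freq", "ihh_a",
                                       "ihh_d", "ihs_unstd"])


def standardize_ihs(table: pd.DataFrame, bin_width: float = IHS_BIN_WIDTH
                    ) -> pd.DataFrame:
    """Z-score unstandardised iHS within derived-frequency bins.

    Bins are ``[k w, (k+1) w)``.  Bins with fewer than two variants
    get NaN standardised scores.  The standardised iHS has mean 0 and
    (sample) sd 1 within every populated bin by construction; its
    approximate standard normality across variants is the neutral-null
    property that :func:`normality_check` assesses.
    """
    if not (0.0 < bin_width <= 1.0):
        raise ParameterError("bin_width must lie in (0, 1]")
    out = table.reset_index(drop=True).copy()
    out["freq_bin"] = np.minimum((out["derived_freq"] // bin_width).astype(int),
                                 int(np.ceil(1.0 / bin_width)) - 1)
    z = np.full(len(out), np.nan)
    for _, idx in out.groupby("freq_bin").groups.items():
        vals = out.loc[idx, "ihs_unstd"].to_numpy()
        if vals.size >= 2 and np.std(vals, ddof=1) > 0:
            z[out.index.get_indexer(idx)] = ((vals - vals.mean())
                                             / np.std(vals, ddof=1))
    out["ihs"] = z
    return out


def ihs(haplotypes, positions, derived_allele: int = 1, maf_min: float = 0.01,
        bin_width: float = IHS_BIN_WIDTH, ehh_cutoff: float = EHH_CUTOFF
        ) -> pd.DataFrame:
    """Standardised integrated haplotype scores for one phased matrix.

    Convenience wrapper: :func:`ihs_unstandardized` followed by
    :func:`standardize_ihs`.  For multi-chromosome scans, compute the
    unstandardised tables per chromosome and pool them before
    standardising.
    """
    table = ihs_unstandardized(haplotypes, positions, derived_allele,
                               maf_min, ehh_cutoff)
    return standardize_ihs(table, bin_width)


class NormalityReport(NamedTuple):
    w: float               # Shapiro-Wilk statistic
    p: float               # Shapiro-Wilk p-value
    n: int
    n_extreme: int         # scores with |z| >= 2
    extreme_p: float       # binomial tail against the normal expectation


#: P(|Z| >= 2) under the standard normal, the expected extreme fraction.
EXTREME_Z_EXPECTATION = 0.0455


def normality_check(z_scores) -> NormalityReport:
    """Shapiro-Wilk normality test plus an extreme-score census.

    Intended for standardised iHS: under neutral evolution the scores
    are approximately standard normal, so besides the W test the report
    counts scores with ``|z| >= 2`` and tests that count against the
    normal expectation (0.0455) with a one-sided (enrichment) binomial
    test.  Requires ``3 <= n <= 5000``.
    """
    z = np.asarray(z_scores, dtype=float)
    z = z[np.isfinite(z)]
    if not (3 <= z.size <= 5000):
        raise ParameterError("normality check requires 3 <= n <= 5000 finite scores")
    if np.ptp(z) == 0.0:
        raise UndefinedStatisticError("constant input; normality test is degenerate")
    w, p = stats.shapiro(z)
    n_extreme = int(np.sum(np.abs(z) >= 2.0))
    extreme_p = float(stats.binomtest(n_extreme, z.size, EXTREME_Z_EXPECTATION,
                                      alternative="greater").pvalue)
    return NormalityReport(w=float(w), p=float(p), n=int(z.size),
                           n_extreme=n_extreme, extreme_p=extreme_p)
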