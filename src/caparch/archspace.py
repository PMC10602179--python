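"""Architecture clouds, ANOSIM, and the effect-vs-frequency decomposition.

A region's genetic architecture is summarised by its gvp vector, a
point on the simplex.  Estimation noise in allele frequencies and
effect sizes is propagated by resampling: frequency noise as binomial
sampling of the control allele counts, effect noise as
``Normal(beta_hat, SE)``.  Each region then becomes a *cloud* of gvp
points in the same m-dimensional space.

Separation of the regional clouds is tested with ANOSIM (analysis of
similarities), a rank-based permutation test on the pairwise distance
matrix, and the heterogeneity is decomposed into an effect-size and an
allele-frequency component by rebuilding the clouds with only one
noise source active at a time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .exceptions import DataError, ParameterError, UndefinedStatisticError
from .gvp import variance_contribution
from .synthetic import (FREQ_EPS, ScenarioConfig, case_freq_from_or,
                        regional_control_freqs)
from .assoc import _woolf_arrays

__all__ = [
    "ArchitectureCloud",
    "RegionEstimates",
    "AnosimResult",
    "resample_gvp_cloud",
    "simulated_gvp_cloud",
    "pairwise_distances",
    "anosim",
    "sensitivity_decomposition",
    "dominant_component",
]

_MODES = ("both", "beta_only", "freq_only")

#: One-sided z threshold (5% level) above which a noise source is
#: declared to contribute real between-region separation.
_Z_SIGNIFICANT = 1.6448536269514722


@dataclass(frozen=True)
class ArchitectureCloud:
    """B resampled gvp vectors for one region.

    ``matrix`` has shape (B, m); every row sums to 1.
    """

    region: str
    matrix: np.ndarray
    mode: str

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] < 2:
            raise ParameterError("a cloud needs at least B = 2 resampled rows")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("every cloud row must sum to 1")

    @property
    def b_resamples(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def centroid(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


class RegionEstimates(NamedTuple):
    """Per-region summary statistics feeding the uncertainty propagation."""

    freqs: np.ndarray          # control effect-allele frequencies
    allele_totals: np.ndarray  # control allele counts 2N (per variant)
    betas: np.ndarray          # log odds ratios
    ses: np.ndarray            # standard errors of the betas


class AnosimResult(NamedTuple):
    r: float
    p: float
    n_perm: int
    method: str


def _gvp_rows(p: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Row-normalise variance contributions; p, beta have shape (B, m)."""
    v = variance_contribution(p, beta)
    totals = v.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise UndefinedStatisticError("a resampled gvp row has zero total variance")
    return v / totals


def _resampled_p_beta(est: RegionEstimates, b_resamples: int, mode: str,
                      rng: np.random.Generator,
                      shared_freqs: np.ndarray | None = None,
                      shared_betas: np.ndarray | None = None):
    """Draw (B, m) frequency and effect matrices for one cloud.

    ``shared_freqs`` / ``shared_betas`` replace the region's own point
    estimates for whichever component is *not* resampled; the
    sensitivity decomposition uses this to isolate one component.
    """
    m = est.freqs.size
    totals = np.asarray(est.allele_totals, dtype=float)
    if mode in ("both", "freq_only") and np.all(np.isfinite(totals)):
        n = totals.astype(np.int64)
        p = rng.binomial(n, est.freqs, size=(b_resamples, m)) / n
        p = np.clip(p, FREQ_EPS, 1.0 - FREQ_EPS)
    elif mode in ("both", "freq_only"):
        # infinite allele totals: the no-noise limit of the binomial
        p = np.broadcast_to(est.freqs, (b_resamples, m))
    else:
        base = est.freqs if shared_freqs is None else shared_freqs
        p = np.broadcast_to(base, (b_resamples, m))
    if mode in ("both", "beta_only"):
        beta = rng.normal(est.betas, est.ses, size=(b_resamples, m))
    else:
        base = est.betas if shared_betas is None else shared_betas
        beta = np.broadcast_to(base, (b_resamples, m))
    return p, beta


def resample_gvp_cloud(freqs, freq_counts, betas, ses, b_resamples: int = 1000,
                       mode: str = "both", rng: np.random.Generator | None = None,
                       region: str = "") -> ArchitectureCloud:
    """Propagate estimation noise into a cloud of gvp vectors.

    Per resample, ``p* = Binomial(2N, p)/(2N)`` when ``mode`` includes
    frequency noise (else the point estimate ``p``), and
    ``beta* = Normal(beta, SE)`` when ``mode`` includes effect noise
    (else ``beta``); each row is the gvp vector of ``(p*, beta*)``.

    Parameters
    ----------
    freqs, freq_counts, betas, ses : array-like, shape (m,)
        Control frequencies, control allele totals (2N), log odds
        ratios and their standard errors.
    b_resamples : int
        Number of cloud points B (>= 2).
    mode : {"both", "beta_only", "freq_only"}
    """
    if mode not in _MODES:
        raise ParameterError(f"mode must be one of {_MODES}, got {mode!r}")
    if b_resamples < 2:
        raise ParameterError("b_resamples must be at least 2")
    est = RegionEstimates(
        freqs=np.atleast_1d(np.asarray(freqs, dtype=float)),
        allele_totals=np.atleast_1d(np.asarray(freq_counts)),
        betas=np.atleast_1d(np.asarray(betas, dtype=float)),
        ses=np.atleast_1d(np.asarray(ses, dtype=float)),
    )
    if np.any(est.ses < 0):
        raise ParameterError("standard errors must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    p, beta = _resampled_p_beta(est, b_resamples, mode, rng)
    return ArchitectureCloud(region=region, matrix=_gvp_rows(p, beta), mode=mode)


def simulated_gvp_cloud(config: ScenarioConfig, b_resamples: int = 1000,
                        rng: np.random.Generator | None = None
                        ) -> dict[str, ArchitectureCloud]:
    """Clouds built from independent cohort re-simulations.

    Instead of resampling around one realised set of estimates, each
    cloud row re-draws an entire cohort from the scenario's generative
    model (fixed regional frequencies, fresh binomial counts) and
    re-estimates frequencies and effects.  Rows are therefore genuinely
    independent, which makes ANOSIM on the pooled clouds a calibrated
    test of the scenario's architecture differences.
    """
    if b_resamples < 2:
        raise ParameterError("b_resamples must be at least 2")
    rng = np.random.default_rng(config.seed + 10_000) if rng is None else rng
    freqs = regional_control_freqs(config)
    clouds = {}
    for i, region in enumerate(config.regions):
        p_ctrl = freqs[region]
        p_case = np.clip(case_freq_from_or(p_ctrl, np.exp(config.beta[i])),
                         FREQ_EPS, 1.0 - FREQ_EPS)
        n_case = 2 * int(config.n_cases[i])
        n_ctrl = 2 * int(config.n_controls[i])
        a = rng.binomial(n_case, p_case, size=(b_resamples, config.m_variants))
        c = rng.binomial(n_ctrl, p_ctrl, size=(b_resamples, config.m_variants))
        beta_hat, _, _ = _woolf_arrays(a, n_case - a, c, n_ctrl - c)
        p_hat = np.clip(c / n_ctrl, FREQ_EPS, 1.0 - FREQ_EPS)
        beta_hat = np.where(np.isfinite(beta_hat), beta_hat, 0.0)
        clouds[region] = ArchitectureCloud(region=region,
                                           matrix=_gvp_rows(p_hat, beta_hat),
                                           mode="data_resample")
    return clouds


def pairwise_distances(points, metric: str = "euclidean") -> np.ndarray:
    """Condensed pairwise distance matrix over cloud points.

    Euclidean distance on gvp vectors is the supported and tested
    default; any other scipy ``pdist`` metric string is passed through.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DataError("need at least two points of equal dimension")
    try:
        return pdist(pts, metric=metric)
    except ValueError as exc:
        raise DataError(str(exc)) from exc


def _anosim_r_for_masks(within: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """R for each row of a (P, n_pairs) boolean within-group mask."""
    m_pairs = ranks.size
    n_within = within.sum(axis=1)
    sum_within = within @ ranks
    r_within = sum_within / n_within
    r_between = (ranks.sum() - sum_within) / (m_pairs - n_within)
    return (r_between - r_within) / (m_pairs / 2.0)


def anosim(distances, labels, n_perm: int = 999,
           rng: np.random.Generator | None = None,
           method: str = "sampled") -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    All pairwise distances are ranked (average ranks on ties) and

    ``R = (mean between-group rank - mean within-group rank) / (M/2)``

    with ``M`` the number of pairs, so ``R`` lies in [-1, 1] and is
    invariant to any strictly monotone transform of the distances.
    Significance comes from permuting labels across points:
    ``p = (1 + #{permuted R >= observed R}) / (1 + n_perm)`` (one-sided,
    the standard ANOSIM convention), so ``p >= 1/(1 + n_perm)`` always.

    Parameters
    ----------
    distances : condensed (1-D) or square (2-D) distance matrix.
    labels : group label per point; every group needs >= 2 points.
    method : {"sampled", "exact"}
        "exact" enumerates all label permutations (intended for small
        point sets) and ignores ``n_perm`` and ``rng``.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim == 2:
        d = squareform(d, checks=False)
    labels = np.asarray(labels)
    n = labels.size
    if d.size != n * (n - 1) // 2:
        raise ParameterError("distance matrix does not match the number of labels")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ParameterError("ANOSIM needs at least two groups")
    if np.any(counts < 2):
        raise ParameterError("every group needs at least two points")
    if method not in ("sampled", "exact"):
        raise ParameterError("method must be 'sampled' or 'exact'")
    if n_perm < 1:
        raise ParameterError("n_perm must be at least 1")

    i_idx, j_idx = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d)
    obs = float(_anosim_r_for_masks((labels[i_idx] == labels[j_idx])[None, :], ranks)[0])

    if method == "exact":
        perms = np.array(list(itertools.permutations(range(n))))
        perm_labels = labels[perms]                      # (n!, n)
        within = perm_labels[:, i_idx] == perm_labels[:, j_idx]
        r_perm = _anosim_r_for_masks(within, ranks)
        p = float(np.mean(r_perm >= obs - 1e-12))
        return AnosimResult(r=obs, p=p, n_perm=int(len(perms)), method="exact")

    rng = np.random.default_rng() if rng is None else rng
    count = 0
    batch = 64
    done = 0
    while done < n_perm:
        k = min(batch, n_perm - done)
        perm_labels = np.stack([rng.permutation(labels) for _ in range(k)])
        within = perm_labels[:, i_idx] == perm_labels[:, j_idx]
        r_perm = _anosim_r_for_masks(within, ranks)
        count += int(np.sum(r_perm >= obs - 1e-12))
        done += k
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(r=obs, p=float(p), n_perm=int(n_perm), method="sampled")


# ---------------------------------------------------------------------------
# Sensitivity decomposition
# ---------------------------------------------------------------------------

def _paired_distances(cloud_a: np.ndarray, cloud_b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(cloud_a - cloud_b, axis=1)


def _within_distances(cloud: np.ndarray) -> np.ndarray:
    """Distances between disjoint row pairs of one cloud."""
    k = cloud.shape[0] // 2
    return np.linalg.norm(cloud[:k] - cloud[k:2 * k], axis=1)


def _coerce_estimates(value) -> RegionEstimates:
    if isinstance(value, RegionEstimates):
        est = value
    elif isinstance(value, Mapping):
        est = RegionEstimates(np.asarray(value["freqs"], dtype=float),
                              np.asarray(value["allele_totals"]),
                              np.asarray(value["betas"], dtype=float),
                              np.asarray(value["ses"], dtype=float))
    else:
        est = RegionEstimates(*(np.asarray(v) for v in value))
    return RegionEstimates(np.atleast_1d(np.asarray(est.freqs, dtype=float)),
                           np.atleast_1d(np.asarray(est.allele_totals)),
                           np.atleast_1d(np.asarray(est.betas, dtype=float)),
                           np.atleast_1d(np.asarray(est.ses, dtype=float)))


def sensitivity_decomposition(estimates_by_region: Mapping, b_resamples: int = 1000,
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Which noise source separates the regional architectures?

    For every region pair two sets of clouds are built.  Under
    ``beta_only`` both regions share a common (count-weighted pooled)
    frequency vector and only effect sizes are resampled from
    ``Normal(beta_hat, SE)``; under ``freq_only`` both share the
    inverse-variance pooled effects and only frequencies are resampled
    binomially.  Each mode yields B between-cloud distances (paired
    rows), which are compared directly by a Welch two-sample t-test.

    Because resampling noise matches the sampling noise of the
    estimators, the *expected* between-cloud squared distance under a
    shared architecture is twice the within-cloud squared distance.
    The decomposition therefore also reports, per mode, the calibrated
    excess ``mean(d_between^2) - 2 mean(d_within^2)`` and its z-score;
    a mode is credited with real separation only when its z exceeds
    the one-sided 5% threshold, and ``dominant`` names the credited
    mode with the larger excess ("effect_sizes", "allele_frequencies",
    "none", or "degenerate" when all distances vanish).

    Returns one row per region pair.
    """
    if b_resamples < 2:
        raise ParameterError("b_resamples must be at least 2")
    rng = np.random.default_rng() if rng is None else rng
    ests = {region: _coerce_estimates(v) for region, v in estimates_by_region.items()}
    regions = list(ests)
    if len(regions) < 2:
        raise ParameterError("sensitivity decomposition needs at least two regions")

    rows = []
    for reg_a, reg_b in itertools.combinations(regions, 2):
        ea, eb = ests[reg_a], ests[reg_b]
        na = np.asarray(ea.allele_totals, dtype=float)
        nb = np.asarray(eb.allele_totals, dtype=float)
        if np.all(np.isfinite(na)) and np.all(np.isfinite(nb)):
            shared_p = (na * ea.freqs + nb * eb.freqs) / (na + nb)
        else:
            shared_p = (ea.freqs + eb.freqs) / 2.0
        wa, wb = 1.0 / np.maximum(ea.ses, 1e-12) ** 2, 1.0 / np.maximum(eb.ses, 1e-12) ** 2
        shared_beta = (wa * ea.betas + wb * eb.betas) / (wa + wb)

        per_mode = {}
        for mode, kwargs in (("beta_only", {"shared_freqs": shared_p}),
                             ("freq_only", {"shared_betas": shared_beta})):
            pa, ba = _resampled_p_beta(ea, b_resamples, mode, rng, **kwargs)
            pb_, bb = _resampled_p_beta(eb, b_resamples, mode, rng, **kwargs)
            cloud_a, cloud_b = _gvp_rows(pa, ba), _gvp_rows(pb_, bb)
            between = _paired_distances(cloud_a, cloud_b)
            within = np.concatenate([_within_distances(cloud_a),
                                     _within_distances(cloud_b)])
            var_coord = (cloud_a.var(axis=0, ddof=1) + cloud_b.var(axis=0, ddof=1))
            excess = float(np.mean(between ** 2) - 2.0 * np.mean(within ** 2))
            var_excess = (2.0 * float(np.sum(var_coord ** 2))
                          + np.var(between ** 2, ddof=1) / between.size
                          + 4.0 * np.var(within ** 2, ddof=1) / max(within.size, 1))
            z = excess / math.sqrt(var_excess) if var_excess > 0 else np.nan
            per_mode[mode] = {"between": between, "excess": excess, "z": z}

        d_beta = per_mode["beta_only"]["between"]
        d_freq = per_mode["freq_only"]["between"]
        degenerate = bool(np.all(d_beta == 0.0) and np.all(d_freq == 0.0))
        if degenerate:
            t_stat, t_p, dominant = np.nan, np.nan, "degenerate"
        else:
            t_stat, t_p = stats.ttest_ind(d_beta, d_freq, equal_var=False)
            cred = {mode: info for mode, info in per_mode.items()
                    if np.isfinite(info["z"]) and info["z"] > _Z_SIGNIFICANT}
            if not cred:
                dominant = "none"
            else:
                best = max(cred, key=lambda mode: cred[mode]["excess"])
                dominant = {"beta_only": "effect_sizes",
                            "freq_only": "allele_frequencies"}[best]
        rows.append({
            "region_a": reg_a,
            "region_b": reg_b,
            "mean_dist_beta": float(np.mean(d_beta)),
            "mean_dist_freq": float(np.mean(d_freq)),
            "t_stat": float(t_stat) if np.isfinite(t_stat) else np.nan,
            "t_p": float(t_p) if np.isfinite(t_p) else np.nan,
            "excess_beta": per_mode["beta_only"]["excess"],
            "excess_freq": per_mode["freq_only"]["excess"],
            "z_beta": per_mode["beta_only"]["z"],
            "z_freq": per_mode["freq_only"]["z"],
            "larger_mean_distance": ("effect_sizes"
                                     if np.mean(d_beta) >= np.mean(d_freq)
                                     else "allele_frequencies"),
            "dominant": dominant,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def dominant_component(decomposition: pd.DataFrame) -> str:
    """Majority verdict across region pairs ("mixed" on a tie)."""
    votes = decomposition.loc[~decomposition["degenerate"], "dominant"]
    votes = votes[votes.isin(["effect_sizes", "allele_frequencies"])]
    if votes.empty:
        return "none"
    counts = votes.value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        return "mixed"
    return str(counts.index[0])
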