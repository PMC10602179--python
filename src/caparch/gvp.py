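"""Genetic variance proportions (gvp).

A variant's additive contribution to the genetic variance of liability
on the log-odds scale is ``v = 2 p (1 - p) beta^2`` (effect-allele
frequency ``p``, log odds ratio ``beta``).  Normalising the ``v`` of a
fixed variant set within one population yields that population's gvp
vector -- a point on the simplex that summarises the relative
importance of each locus, i.e. the population's genetic architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError, UndefinedStatisticError

__all__ = ["GvpVector", "variance_contribution", "gvp_vector", "gvp_matrix"]


@dataclass(frozen=True)
class GvpVector:
    """Normalised per-variant variance contributions for one region."""

    region: str
    variant_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.variant_ids) != self.values.size:
            raise DataError("variant_ids and values must have equal length")


def variance_contribution(p, beta):
    """Single-locus additive variance ``2 p (1-p) beta^2``.

    Symmetric in ``p <-> 1-p``; zero when ``beta = 0`` or the site is
    monomorphic.  NaN inputs (variant unobserved in a region) count as
    zero contribution, which keeps gvp vectors alignable across regions.
    """
    p = np.asarray(p, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(np.isfinite(p) & ((p < 0) | (p > 1))):
        raise ParameterError("frequencies must lie in [0, 1]")
    v = 2.0 * p * (1.0 - p) * beta ** 2
    v = np.where(np.isfinite(v), v, 0.0)
    return float(v) if v.ndim == 0 else v


def gvp_vector(freqs, betas, region: str = "", variant_ids=None) -> GvpVector:
    """Normalise variance contributions into a gvp vector (sums to 1).

    Raises
    ------
    UndefinedStatisticError
        If every variance contribution is zero.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if freqs.shape != betas.shape:
        raise ParameterError("freqs and betas must have equal length")
    v = variance_contribution(freqs, betas)
    total = v.sum()
    if total <= 0.0:
        raise UndefinedStatisticError(
            "all variance contributions are zero; gvp is undefined")
    ids = tuple(variant_ids) if variant_ids is not None else tuple(range(freqs.size))
    return GvpVector(region=region, variant_ids=ids, values=v / total)


def gvp_matrix(freqs_by_region: Mapping[str, Sequence],
               betas_by_region: Mapping[str, Sequence],
               variant_ids: Sequence | None = None) -> pd.DataFrame:
    """Region-by-variant gvp table over a shared, ordered variant set.

    Every region must supply frequency and effect arrays aligned to the
    same variant order.  Variants that are monomorphic or unobserved
    (NaN) in a region contribute zero in that row rather than being
    dropped; a region missing more than half of the variant set is
    rejected as a data error.  Each row sums to 1.
    """
    regions = list(freqs_by_region)
    if set(regions) != set(betas_by_region):
        raise DataError("freqs_by_region and betas_by_region must cover the same regions")
    m = len(np.atleast_1d(np.asarray(freqs_by_region[regions[0]], dtype=float)))
    ids = list(variant_ids) if variant_ids is not None else list(range(m))
    if len(ids) != m:
        raise DataError("variant_ids length must match the frequency arrays")
    rows = {}
    for region in regions:
        f = np.atleast_1d(np.asarray(freqs_by_region[region], dtype=float))
        b = np.atleast_1d(np.asarray(betas_by_region[region], dtype=float))
        if f.size != m or b.size != m:
            raise DataError(f"region {region!r} supplies {f.size} variants, expected {m}")
        missing = ~(np.isfinite(f) & np.isfinite(b))
        if missing.mean() > 0.5:
            raise DataError(
                f"region {region!r} is missing {missing.sum()}/{m} variants (>50%)")
        rows[region] = gvp_vector(np.where(missing, 0.5, f),
                                  np.where(missing, 0.0, b)).values
    return pd.DataFrame.from_dict(rows, orient="index", columns=ids)
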