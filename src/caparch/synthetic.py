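"""Synthetic three-region case/control GWAS data.

This module generates the inputs that the regional-architecture analyses
assume: per-variant effect-allele counts in cases and controls for three
African regions, and (separately) phased 0/1 haplotype matrices with
tunable linkage disequilibrium.

The generative model is deliberately simple and fully parametric:

* a shared ancestral effect-allele frequency ``p_anc`` per variant,
* regional control frequencies drawn from the Balding-Nichols
  distribution ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, where ``F`` is a
  per-region drift parameter (``F = 0`` means no drift),
* per-region true log odds ratios ``beta``; case frequencies follow
  from the allelic odds-ratio identity,
* binomial sampling of allele counts in cases and controls
  (diploid, autosomal: total allele count = 2 x individuals).

Haplotypes come from a first-order Markov copying model, not a
coalescent: adjacent-site association decays geometrically with a
per-site recombination probability, which is sufficient to create
tunable LD for r^2, EHH and haplotype odds-ratio analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParameterError

__all__ = [
    "DEFAULT_REGION_SIZES",
    "FREQ_EPS",
    "ScenarioConfig",
    "draw_regional_freqs",
    "case_freq_from_or",
    "regional_control_freqs",
    "simulate_counts",
    "simulate_haplotypes",
    "null_scenario",
    "heterogeneous_beta_scenario",
    "drifted_freq_scenario",
]

#: Cases / controls per region in the pan-African prostate-cancer
#: case/control resource these scenarios are patterned on.
DEFAULT_REGION_SIZES: dict[str, tuple[int, int]] = {
    "West": (1780, 1739),
    "East": (835, 667),
    "South": (1348, 1103),
}

#: Frequencies are clipped this far away from 0 and 1 so that
#: downstream log odds ratios stay finite on monomorphic draws.
FREQ_EPS = 1e-6

# Independent RNG streams derived from a single scenario seed.  Each
# stream id is combined with the seed so that e.g. parameter draws and
# count draws never reuse the same underlying bit stream.
_PARAM_STREAM = 0
_FREQ_STREAM = 1
_COUNT_STREAM = 2


@dataclass
class ScenarioConfig:
    """Parameters of a three-region case/control simulation.

    Attributes
    ----------
    regions : tuple of str
        Region labels, e.g. ``("West", "East", "South")``.
    n_cases, n_controls : ndarray of int, shape (r,)
        Individuals per region.
    p_anc : ndarray, shape (m,)
        Ancestral effect-allele frequencies, all in (0, 1).
    f_drift : ndarray, shape (r,)
        Balding-Nichols drift parameter per region, each in [0, 1).
    beta : ndarray, shape (r, m)
        True per-region log odds ratio per variant.
    seed : int
        Seed for all randomness in the scenario; identical configs
        (including the seed) yield byte-identical outputs.
    name : str
        Free-form scenario label, recorded in run manifests.
    """

    regions: tuple[str, ...]
    n_cases: np.ndarray
    n_controls: np.ndarray
    p_anc: np.ndarray
    f_drift: np.ndarray
    beta: np.ndarray
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        self.regions = tuple(str(r) for r in self.regions)
        self.n_cases = np.asarray(self.n_cases, dtype=int)
        self.n_controls = np.asarray(self.n_controls, dtype=int)
        self.p_anc = np.asarray(self.p_anc, dtype=float)
        self.f_drift = np.atleast_1d(np.asarray(self.f_drift, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        r = len(self.regions)
        if r < 1:
            raise ConfigError("at least one region is required")
        if self.f_drift.size == 1:
            self.f_drift = np.full(r, float(self.f_drift[0]))
        for name, arr in (("n_cases", self.n_cases), ("n_controls", self.n_controls),
                          ("f_drift", self.f_drift)):
            if arr.shape != (r,):
                raise ConfigError(f"{name} must have one entry per region, got {arr.shape}")
        if np.any(self.n_cases < 1) or np.any(self.n_controls < 1):
            raise ConfigError("region sizes must be positive")
        if self.p_anc.ndim != 1 or self.p_anc.size < 1:
            raise ConfigError("p_anc must be a non-empty 1-D array")
        if np.any((self.p_anc <= 0.0) | (self.p_anc >= 1.0)):
            raise ConfigError("all ancestral frequencies must lie strictly in (0, 1)")
        if np.any((self.f_drift < 0.0) | (self.f_drift >= 1.0)):
            raise ConfigError("drift parameters must lie in [0, 1)")
        if self.beta.shape != (r, self.p_anc.size):
            raise ConfigError(
                f"beta must have shape (regions, m_variants) = ({r}, {self.p_anc.size}), "
                f"got {self.beta.shape}")
        self.seed = int(self.seed)

    @property
    def m_variants(self) -> int:
        return int(self.p_anc.size)

    @property
    def region_sizes(self) -> dict[str, tuple[int, int]]:
        return {reg: (int(c), int(n))
                for reg, c, n in zip(self.regions, self.n_cases, self.n_controls)}

    @property
    def variant_ids(self) -> list[str]:
        return [f"var{i:04d}" for i in range(self.m_variants)]

    def as_dict(self) -> dict:
        """Plain-type representation, suitable for YAML/JSON round trips."""
        return {
            "name": self.name,
            "regions": list(self.regions),
            "n_cases": self.n_cases.tolist(),
            "n_controls": self.n_controls.tolist(),
            "p_anc": self.p_anc.tolist(),
            "f_drift": self.f_drift.tolist(),
            "beta": self.beta.tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        """Build a config from a key/value mapping.

        Scalar conveniences: ``f_drift`` may be a single number
        (broadcast to all regions) and ``beta`` may be a scalar, a flat
        list of length m (shared across regions) or a full
        region-by-variant nested list.
        """
        try:
            regions = list(d["regions"])
            p_anc = np.asarray(d["p_anc"], dtype=float)
            beta = np.asarray(d["beta"], dtype=float)
        except KeyError as exc:
            raise ConfigError(f"missing required scenario key: {exc.args[0]!r}") from exc
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"malformed scenario value: {exc}") from exc
        if beta.ndim == 0:
            beta = np.full((len(regions), p_anc.size), float(beta))
        elif beta.ndim == 1:
            beta = np.tile(beta, (len(regions), 1))
        return cls(
            regions=tuple(regions),
            n_cases=d.get("n_cases", [s[0] for s in DEFAULT_REGION_SIZES.values()]),
            n_controls=d.get("n_controls", [s[1] for s in DEFAULT_REGION_SIZES.values()]),
            p_anc=p_anc,
            f_drift=d.get("f_drift", 0.0),
            beta=beta,
            seed=d.get("seed", 0),
            name=d.get("name", "scenario"),
        )


def draw_regional_freqs(p_anc, F: float, rng: np.random.Generator):
    """Draw regional allele frequencies under the Balding-Nichols model.

    For drift parameter ``F > 0`` the draw is
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
    ``F p (1-p)``.  ``F = 0`` is the degenerate no-drift case and
    returns ``p_anc`` unchanged.  Draws are clipped to
    ``[FREQ_EPS, 1 - FREQ_EPS]``.

    Parameters
    ----------
    p_anc : float or ndarray
        Ancestral frequency (or frequencies), each strictly in (0, 1).
    F : float
        Drift parameter in [0, 1).
    rng : numpy.random.Generator
    """
    p = np.asarray(p_anc, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ParameterError("ancestral frequency must lie strictly in (0, 1)")
    if not (0.0 <= F < 1.0):
        raise ParameterError(f"drift parameter must lie in [0, 1), got {F}")
    if F == 0.0:
        out = p.copy()
    else:
        scale = (1.0 - F) / F
        out = rng.beta(p * scale, (1.0 - p) * scale)
    out = np.clip(out, FREQ_EPS, 1.0 - FREQ_EPS)
    return float(out) if np.isscalar(p_anc) else out


def case_freq_from_or(p0, odds_ratio):
    """Effect-allele frequency in cases implied by an allelic odds ratio.

    Inverts ``OR = [p1/(1-p1)] / [p0/(1-p0)]``:
    ``p1 = OR p0 / (1 - p0 + OR p0)``, strictly increasing in ``OR``.
    """
    p0 = np.asarray(p0, dtype=float)
    odds_ratio = np.asarray(odds_ratio, dtype=float)
    if np.any((p0 < 0.0) | (p0 > 1.0)):
        raise ParameterError("control frequency must lie in [0, 1]")
    if np.any(odds_ratio <= 0.0):
        raise ParameterError("odds ratio must be positive")
    out = odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)
    return float(out) if out.ndim == 0 else out


def regional_control_freqs(config: ScenarioConfig) -> dict[str, np.ndarray]:
    """True (population) control frequencies per region for a scenario.

    Deterministic given the scenario seed; these are the frequencies
    ``simulate_counts`` samples allele counts from, so repeated cohort
    draws for the same scenario share the same regional frequencies.
    """
    rng = np.random.default_rng([_FREQ_STREAM, config.seed])
    return {region: draw_regional_freqs(config.p_anc, float(F), rng)
            for region, F in zip(config.regions, config.f_drift)}


def simulate_counts(config: ScenarioConfig, rng: np.random.Generator | None = None
                    ) -> pd.DataFrame:
    """Simulate per-variant allele-count tables for every region.

    Control allele counts are ``Binomial(2 n_controls, p_region)`` and
    case counts are ``Binomial(2 n_cases, p_case)`` where ``p_case``
    follows from the region's true log odds ratio.

    Returns a tidy table with columns ``VariantID, Region,
    CaseEffCount, CaseTotal, CtrlEffCount, CtrlTotal`` (one row per
    variant per region).  Passing no ``rng`` uses the scenario seed, so
    the same config always yields byte-identical output; an explicit
    ``rng`` draws an independent replicate cohort from the same
    regional frequencies.
    """
    if rng is None:
        rng = np.random.default_rng([_COUNT_STREAM, config.seed])
    freqs = regional_control_freqs(config)
    ids = config.variant_ids
    frames = []
    for i, region in enumerate(config.regions):
        p_ctrl = freqs[region]
        p_case = np.clip(case_freq_from_or(p_ctrl, np.exp(config.beta[i])),
                         FREQ_EPS, 1.0 - FREQ_EPS)
        n_case_alleles = 2 * int(config.n_cases[i])
        n_ctrl_alleles = 2 * int(config.n_controls[i])
        frames.append(pd.DataFrame({
            "VariantID": ids,
            "Region": region,
            "CaseEffCount": rng.binomial(n_case_alleles, p_case),
            "CaseTotal": n_case_alleles,
            "CtrlEffCount": rng.binomial(n_ctrl_alleles, p_ctrl),
            "CtrlTotal": n_ctrl_alleles,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_haplotypes(n_haps: int, n_sites: int, freqs, ld_decay: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Simulate a phased 0/1 haplotype matrix with tunable LD.

    A latent uniform ``u`` walks along the chromosome: at each site it
    is redrawn with probability ``ld_decay`` and carried over
    otherwise; the allele at site ``j`` is ``1`` iff ``u < freqs[j]``.
    Marginal site frequencies therefore equal ``freqs`` exactly in
    expectation.  ``ld_decay = 1`` gives independent sites;
    ``ld_decay = 0`` gives perfect linkage (with equal frequencies,
    every haplotype is one of two complementary patterns).

    Returns an ``(n_haps, n_sites)`` int8 matrix (rows = haplotypes).
    """
    if n_haps < 2 or n_haps % 2 != 0:
        raise ParameterError("n_haps must be an even number >= 2 (phased diploids)")
    if not (0.0 <= ld_decay <= 1.0):
        raise ParameterError("ld_decay must lie in [0, 1]")
    f = np.broadcast_to(np.asarray(freqs, dtype=float), (n_sites,))
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise ParameterError("site frequencies must lie strictly in (0, 1)")
    u = np.empty((n_haps, n_sites))
    u[:, 0] = rng.random(n_haps)
    for j in range(1, n_sites):
        fresh = rng.random(n_haps)
        resample = rng.random(n_haps) < ld_decay
        u[:, j] = np.where(resample, fresh, u[:, j - 1])
    return (u < f).astype(np.int8)


# ---------------------------------------------------------------------------
# Scenario constructors
# ---------------------------------------------------------------------------

def _base_params(m_variants: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Shared ancestral frequencies and baseline effects for the bundled
    scenarios: tag-SNP-like frequencies Uniform(0.05, 0.95) and marginal
    GWAS-hit effects |beta| ~ Uniform(0.08, 0.35) with random sign
    (allelic OR roughly 1.08-1.42)."""
    rng = np.random.default_rng([_PARAM_STREAM, seed])
    p_anc = rng.uniform(0.05, 0.95, m_variants)
    beta = rng.choice([-1.0, 1.0], m_variants) * rng.uniform(0.08, 0.35, m_variants)
    return p_anc, beta


def _sizes(region_sizes: Mapping[str, tuple[int, int]] | None):
    sizes = dict(region_sizes) if region_sizes is not None else dict(DEFAULT_REGION_SIZES)
    regions = tuple(sizes)
    n_cases = [sizes[r][0] for r in regions]
    n_controls = [sizes[r][1] for r in regions]
    return regions, n_cases, n_controls


def null_scenario(m_variants: int = 90, *, seed: int = 0,
                  region_sizes: Mapping[str, tuple[int, int]] | None = None,
                  f_drift: float = 0.0, name: str = "null") -> ScenarioConfig:
    """Shared-architecture null: identical true effects in every region
    and (with ``f_drift = 0``) identical regional frequencies."""
    regions, n_cases, n_controls = _sizes(region_sizes)
    p_anc, beta = _base_params(m_variants, seed)
    return ScenarioConfig(regions=regions, n_cases=n_cases, n_controls=n_controls,
                          p_anc=p_anc, f_drift=np.full(len(regions), f_drift),
                          beta=np.tile(beta, (len(regions), 1)), seed=seed, name=name)


def heterogeneous_beta_scenario(m_variants: int = 90, n_hetero: int = 10,
                                delta_beta: float = 0.2, *, seed: int = 0,
                                region_sizes: Mapping[str, tuple[int, int]] | None = None,
                                f_drift: float = 0.0,
                                name: str = "heterogeneous_beta") -> ScenarioConfig:
    """Region-specific effect sizes at the first ``n_hetero`` variants.

    Relative to the shared baseline, the second region's log odds ratio
    is shifted by ``+delta_beta`` and the third's by ``-delta_beta`` at
    those variants; frequencies stay shared (``f_drift = 0`` default).
    """
    regions, n_cases, n_controls = _sizes(region_sizes)
    if not (0 < n_hetero <= m_variants):
        raise ParameterError("n_hetero must lie in 1..m_variants")
    if len(regions) < 2:
        raise ParameterError("heterogeneous scenario needs at least two regions")
    p_anc, base = _base_params(m_variants, seed)
    beta = np.tile(base, (len(regions), 1))
    idx = np.arange(n_hetero)
    beta[1, idx] += delta_beta
    if len(regions) > 2:
        beta[2, idx] -= delta_beta
    return ScenarioConfig(regions=regions, n_cases=n_cases, n_controls=n_controls,
                          p_anc=p_anc, f_drift=np.full(len(regions), f_drift),
                          beta=beta, seed=seed, name=name)


def drifted_freq_scenario(m_variants: int = 90, f_drift: float = 0.05, *, seed: int = 0,
                          region_sizes: Mapping[str, tuple[int, int]] | None = None,
                          name: str = "drifted_freq") -> ScenarioConfig:
    """Shared effects, drifted regional frequencies (pure-drift contrast
    to :func:`heterogeneous_beta_scenario`)."""
    cfg = null_scenario(m_variants, seed=seed, region_sizes=region_sizes,
                        f_drift=f_drift, name=name)
    return cfg
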