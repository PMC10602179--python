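# Methods

## Scope and data model

The package analyses *summary-level* case/control GWAS data: for each
variant and region, effect-allele counts in cases and controls (or the
derived frequency, log odds ratio and standard error).  It does not
fit covariate-adjusted logistic regressions on raw genotypes; the
allelic 2×2 model is the unit of computation throughout, which is the
natural desk-scale counterpart of a summary-statistic heterogeneity
analysis.

## Synthetic scenarios

`caparch.synthetic` generates three-region case/control cohorts under
a fully parametric model:

* **Ancestral frequencies** p ~ Uniform(0.05, 0.95) per variant —
  tag-SNP-like frequencies, away from the monomorphic edge.
* **Regional drift**: control frequencies are Balding–Nichols draws,
  Beta(p(1−F)/F, (1−p)(1−F)/F), mean p and variance F·p(1−p).  F = 0
  is the no-drift degenerate case.  This is the standard neutral-drift
  parameterisation; the motivating analysis concluded that drift, not
  selection, governs regional frequency differences, which is exactly
  the regime this model encodes.
* **Effects**: per-region true log odds ratios.  Bundled scenarios
  draw baseline |β| ~ Uniform(0.08, 0.35) with random sign (allelic OR
  ≈ 1.08–1.42, typical of marginal GWAS hits).  The heterogeneous
  scenario shifts β by ±0.2 at 10 of 90 variants in the second/third
  region; 0.2 is roughly 3 standard errors at the default cohort
  sizes, i.e. detectable but not trivial.
* **Counts**: case frequencies follow from the allelic odds-ratio
  identity p₁ = OR·p₀/(1−p₀+OR·p₀); allele counts are binomial with
  2N trials (diploid autosomes).  Frequencies are clipped to
  [1e−6, 1−1e−6] so log odds ratios stay finite.
* **Cohort sizes** default to the motivating study's regions —
  West 1,780/1,739, East 835/667, South 1,348/1,103 cases/controls.
  The bundled *null* scenario uses matched sizes (1,321/1,170 × 3)
  because ANOSIM responds to dispersion differences, and unequal
  cohort sizes change cloud spread even when architectures are
  identical.

What the generator does **not** emulate: linkage between the m
variants (they are simulated independently; LD enters only through the
separate haplotype simulator), covariate structure, genotyping batch
effects, imputation error, and ascertainment of the variant set from
the same data being analysed.  Passing tests therefore demonstrate
statistical correctness of the machinery under the stated model, not
robustness to those real-data complications.

**Haplotypes** come from a first-order Markov copying model: a latent
uniform u is carried along the chromosome and redrawn with probability
`ld_decay` per site; the allele at site j is 1 iff u < f_j.  Marginals
equal f exactly; adjacent-site association decays geometrically.  This
is sufficient to give r², EHH and haplotype-OR code realistic inputs;
it is not a coalescent and has no recombination map or mutation
process.

**Determinism.**  Every scenario stream is seeded as
`default_rng([stream_id, seed])`, so parameter draws, frequency draws
and count draws are independent streams derived from the single config
seed, and identical configs yield byte-identical outputs.

## Association statistics

Per-variant association is the Woolf estimator: β = ln(ad/bc),
SE = √(1/a+1/b+1/c+1/d), two-sided Wald p.  When any cell is zero, 0.5
is added to every cell (Haldane–Anscombe); a table with an all-zero
margin is undefined and raises (vectorised paths return NaN and drop
the variant downstream).  Meta-analysis is inverse-variance
fixed-effect with Cochran's Q (df = k−1) and I² = max(0, (Q−df)/Q)·100.
Random-effects models are out of scope.  The genomic inflation factor
is median(χ²)/0.45494, the χ²₁ null median.  Significance thresholds
default to 5×10⁻⁸ (genome-wide) and 1×10⁻⁵ (marginal).  Greedy LD
pruning visits variants by ascending p (stable sort; input order
breaks ties) and retains a variant iff r² < 0.2 against everything
already retained.

Null calibration at the default cohort sizes (measured by the
acceptance suite at m = 20,000): type-I error at α = 0.05 within
±3·MC-SE of 0.05, 95% Wald coverage within ±1%, λ within a few percent
of 1.  The Wald/Woolf machinery is slightly anticonservative at these
cell sizes, which is visible as λ ≈ 1.01–1.02 rather than exactly 1.

## gvp and architecture space

gvp is the normalised additive single-locus variance 2p(1−p)β² on the
log-odds scale, using the **control** effect-allele frequency.
Variants monomorphic or unobserved in a region contribute zero rather
than being dropped, keeping vectors alignable; a region missing more
than half the variant set is rejected.

Uncertainty propagation resamples p* ~ Binomial(2N, p̂)/2N and
β* ~ Normal(β̂, SE) — the minimal sampling distributions of the two
estimators — giving B-point clouds per region (default B = 1,000).
Distances are Euclidean on the simplex (configurable to any scipy
metric; Euclidean is the tested default).

**ANOSIM** ranks all pairwise distances and computes
R = (r̄_between − r̄_within)/(M/2), M = n(n−1)/2, with a one-sided
permutation p = (1+#{R* ≥ R})/(1+n_perm); n_perm defaults to 999, so
the smallest attainable p is 0.001.  An exact mode enumerates all
label permutations for small point sets.  Because R is rank-based it
is invariant to monotone distance transforms.  Two caveats are
deliberate design decisions:

* Clouds resampled around one realised set of estimates are *not*
  independent evidence: under a shared architecture the realised
  estimator noise already separates the cloud centres by about one
  cloud-spread, so ANOSIM on such clouds overstates significance.
  The pipeline therefore builds its ANOSIM clouds by **independent
  cohort re-simulation** (fresh binomial counts per cloud row), which
  makes the test calibrated under the null; this option exists only
  for simulated scenarios, and results on resampled clouds from real
  summary statistics should be read as descriptive.
* ANOSIM reacts to dispersion differences as well as location; the
  shared-architecture null is only exchangeable when cohort sizes are
  matched.

## Sensitivity decomposition

For each region pair the clouds are rebuilt with one channel active:
`beta_only` shares a count-weighted pooled frequency vector and
resamples effects; `freq_only` shares inverse-variance-pooled effects
and resamples frequencies.  Two outputs are reported per pair:

1. The direct Welch t-test between the B `beta_only` and B `freq_only`
   between-cloud distances, with means — the headline "which channel
   puts the clouds further apart" comparison.
2. A noise-calibrated excess: because resampling noise matches the
   estimators' sampling noise, E[d²_between] = 2·E[d²_within] under a
   shared architecture, so `excess = mean d²_between − 2·mean
   d²_within` has expectation ‖Δ‖² (the true centre separation) and
   expectation 0 under the null.  Its z-score (variance from the
   per-coordinate cloud variances plus Monte-Carlo terms) must exceed
   the one-sided 5% threshold (1.645) for a channel to be credited;
   `dominant` names the credited channel with the larger excess.

The raw t-test is enormously significant whenever the two channels
have different noise scales — under the null too — which is why the
verdict uses the calibrated excess and not the t-test.  Per pair the
verdict has roughly nominal one-sided error; the scenario-level
verdict is a plurality across pairs.  Measured over 100 replicates at
the default conditions, the decomposition names effect sizes in ≥95%
of heterogeneous-effect runs and ≤10% of shared-architecture runs.
Degenerate inputs (zero noise in both channels, identical regions)
are flagged rather than tested.

## Population genetics

* **F_ST**: Hudson's single-SNP estimator (the least-biased
  two-population choice); slightly negative values are expected at low
  differentiation and are clamped to 0 only inside PBS, where branch
  lengths T = −ln(1−F_ST) must be non-negative.  F_ST is capped at
  1−1e−9 before the log.
* **PBS percentiles** map a focal value's midrank in the genome-wide
  background onto 0–100 via 100·(rank−1)/(n−1): the background
  minimum scores 0, the maximum 100, the median of an odd background
  50, and values between background points interpolate at +0.5 rank.
* **Private alleles**: a variant is private to the target when its
  minor-allele frequency exceeds the threshold (default 0.01,
  "effectively monomorphic" elsewhere) in the target and is at or
  below it in every other population; the rule uses min(f, 1−f) and is
  allele-label invariant.
* **EHH/iHS**: EHH is the fraction of core-allele carrier pairs
  identical from the core to each site; iHH integrates EHH against
  genetic position (trapezoid) in both directions, truncating where
  EHH < 0.05 or at the chromosome end; unstandardised iHS is
  ln(iHH_A/iHH_D), z-scored within derived-frequency bins of width
  0.05.  Sites need MAF ≥ 0.01 and at least two carriers per allele;
  sites with a vanishing integral are dropped.  The normality check is
  Shapiro–Wilk (scipy) plus a one-sided binomial test of the
  |z| ≥ 2 count against the normal expectation 0.0455.

## Replication enrichment and haplotypes

PRS replication: fold = (k/m)/α for k of m PRS variants below α in the
new GWAS (so fold·α·m = k exactly, ceiling 1/α), with an exact
binomial upper tail; PRS variants absent from the GWAS are dropped and
logged, never imputed.  Histograms use left-closed bins with a closed
last bin.  Feature stratification is the two-sided Wilcoxon rank-sum
(scipy), reporting which group has the larger median.

Haplotype risk: each distinct lead-site allele string is tested
against all other haplotypes pooled (one OR per haplotype, Woolf 95%
CI, Haldane–Anscombe on zero cells).  The network topology is a
minimum spanning tree on Hamming distances (Kruskal), with
deterministic tie-breaks: descending endpoint frequency, then
lexicographic pair order.  Only the topology is computed; layout and
rendering are out of scope.

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py --seed S --out F`)
recomputes everything at these sizes, chosen to make Monte-Carlo error
small relative to each tolerance while keeping the full run under a
minute: m = 20,000 variants for error-rate calibration; B = 200 cloud
points and 999 permutations for ANOSIM; 100 replicates per condition
for the decomposition rates; 64 chromosomes × 60 sites × 200
haplotypes (≈3,800 scored variants) for the iHS scan, with the
Shapiro–Wilk check on a focal-set-sized draw of 65 scores.  All
randomness derives from the single `--seed` through named streams.

## Known limitations

* All simulation-based guarantees hold under the generator's model;
  see the generator caveats above.
* The gvp formula assumes additivity on the log-odds scale and
  independent variants (hence LD pruning upstream).
* Effect-allele orientation is preserved from input — there is no
  automatic flipping to the minor allele; `harmonize_alleles` is
  provided for explicit reorientation against a reference.
* The decomposition's calibrated verdict assumes the resampling noise
  model matches the estimators' true sampling distributions; strong
  model misspecification (e.g. overdispersed counts) would bias it.
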