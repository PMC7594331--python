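# Methods

## Model and assumptions

The package operates entirely at the GWAS summary-statistic level. An
instrument SNP *j* is assumed to satisfy the three instrumental-variable
conditions: association with the exposure (enforced by the genome-wide
significance filter), independence from confounders (untestable; motivates
the sensitivity estimators), and exclusion restriction — effect on the
outcome only through the exposure (probed by the Egger intercept and
Cochran's Q). Instruments are assumed approximately independent after LD
pruning; residual correlation below the r² threshold is ignored, as is
standard for cis-region instruments. Exposure and outcome samples are
assumed non-overlapping (two-sample regime), so weak-instrument bias acts
toward the null rather than toward the confounded association.

Binary outcomes are handled on the log-odds scale: outcome GWAS betas are
log-odds per allele, so the pooled estimate is log-odds of disease per unit
(per-SD) of the exposure, exponentiated to an odds ratio for reporting.

## Procedure

1. **Instrument selection** (`instruments`): keep SNPs with p strictly below
   5×10⁻⁸; greedily prune LD pairs at r² ≥ 0.8, keeping the smaller-p member
   (ties broken lexicographically by rsid for determinism); drop SNPs on an
   offline exclusion list standing in for a pleiotropy database screen.
   The stages run in that fixed order; the selection report partitions every
   input rsid into kept/dropped buckets, and re-running selection on its own
   output is a no-op. Boundary semantics: p exactly at the threshold is
   dropped, r² exactly at the threshold is pruned.
2. **Harmonization** (`harmonize`): outcome records are rewritten to the
   exposure's effect allele — sign and frequency flipped for swapped
   alleles, strand complements resolved before declaring a mismatch.
   Palindromic (A/T, G/C) SNPs carry no strand information in their labels;
   they are oriented by comparing allele frequencies when both are available
   and both fall outside [0.42, 0.58], otherwise dropped. This is the common
   practice default; a stricter always-drop policy is available.
3. **Estimation** (`estimators`): Wald ratios with first-order delta SEs by
   default (the usual two-sample choice; second-order available by flag),
   pooled by fixed-effects IVW (multiplicative random effects optional,
   inflating the SE by max(1, √(Q/(L−1)))), the weighted median (linear
   interpolation of cumulative weight midpoints at 0.5; SE from a seeded
   parametric bootstrap, default 1000 replicates), and MR-Egger (weighted
   least squares with intercept after orienting exposure effects positive;
   SEs carry a multiplicative overdispersion factor floored at 1).
   All p-values are two-sided normal; a t-distribution switch exists for
   Egger. A 0.05 threshold is reported but never gates computation, and no
   multiple-testing correction is applied across outcomes (recorded in the
   run manifest).
4. **Pipeline** (`pipeline`): instruments are selected once on the exposure
   study and reused for every outcome; harmonization and estimation are
   per-outcome and isolated, so one outcome's failure cannot abort its
   siblings. With fewer than three harmonized instruments only IVW is
   reported (the sensitivity methods are undefined). The forest output
   carries IVW as the headline method, one OR and 95 % CI per outcome.

## Synthetic data generator

`synthgwas.simulate_pair` draws, for each SNP, a true instrument strength
γⱼ ~ U(gamma_range) and observes β̂ₓⱼ ~ N(γⱼ, σₓⱼ²) and
β̂ᵧⱼ ~ N(θγⱼ + αⱼ, σᵧⱼ²), with αⱼ = 0 for valid instruments and
αⱼ ~ N(alpha_mean, alpha_sd) for the invalid fraction. Drawing α
independently of γ makes directional pleiotropy satisfy InSIDE by
construction, which is exactly the regime where the Egger intercept
estimates the mean direct effect.

Defaults emulate the study design the pipeline targets: a cis-pQTL exposure
GWAS of ~5,440 individuals (per-SNP SE ≈ 1/√n ≈ 0.014, range 0.010–0.018,
in per-SD units), large binary-trait consortia outcomes (SE range
0.010–0.030 on the log-odds scale), instrument strengths 0.1–0.5 SD per
allele, allele frequencies 0.05–0.95 with palindromic pairs excluded unless
requested. Validation scenarios use 50 SNPs; pipeline-shaped tests use 5,
the instrument count of the motivating analysis. The generator does **not**
emulate LD between instruments (LD matrices are supplied separately as
block designs), sample overlap, allele-frequency-dependent power, winner's
curse in instrument discovery, or case-control liability-scale effects —
so passing tests demonstrate estimator correctness under the stated
two-sample model, not robustness to those real-data features.

`gdf15_fixture` is a deterministic synthetic stand-in for the GDF-15
candidate-instrument set: the nine rsIDs are real, but all betas, SEs,
p-values and r² values are constructed so that default selection retains
five instruments, drops three for LD and one for significance. The original
per-SNP numeric table was not published, so no numeric fidelity to it is
claimed or tested.

## Numerical choices

- LD matrices are validated to symmetry within 1e-6 and unit diagonal;
  values outside [0, 1] are rejected.
- The weighted median interpolates cumulative weight midpoints
  pⱼ = Σ_{k≤j} w̃ₖ − w̃ⱼ/2 and clamps at the extreme order statistics when
  0.5 falls outside [p₁, p_L] (one instrument dominating the weight).
- The Wald ratio errors on β̂ₓ = 0; the Egger fit errors when the oriented
  exposure effects are collinear (singular weighted design).
- Extreme z-scores clip simulated p-values at the smallest positive float
  rather than 0, keeping records valid.
- The delta-method SE is a local approximation: it describes the sampling
  SD of the ratio only while σₓ ≪ |β̂ₓ|. With a normal denominator the exact
  ratio distribution is heavy-tailed, so Monte-Carlo agreement is only
  asserted (and only holds) in that regime.
- Monte-Carlo validation sizes — 500 replicates for recovery and
  directional-pleiotropy calibration, 1000 for the intercept test's type-I
  error, 10⁶ draws for the delta-method check — keep the whole suite at
  desk scale (seconds) while leaving the binomial/MC error bands well below
  the effects being checked.

## Open design decisions taken

- Weighted-median SE: parametric bootstrap (seeded, default 1000 draws);
  analytic alternatives exist but the bootstrap matches the estimator's
  definition directly.
- Normal rather than t reference distribution by default, matching common
  MR practice with small instrument counts; documented switch for Egger.
- Egger overdispersion inflation floored at 1 (never deflates SEs below the
  fixed-effects value).
- Missing eaf/n are encoded as empty fields, not zeros; positions are
  1-based; strand is handled via alleles only.

## Limitations

- No MR-PRESSO, mode-based estimators, multivariable MR, Steiger filtering
  or winner's-curse correction.
- No proxy-SNP lookup: instruments absent from an outcome study are
  reported missing, not imputed.
- Correlated instruments are pruned, not modelled; a generalized IVW with
  an LD-aware covariance is out of scope.
- The synthetic generator's validity claims are within-model (see above);
  calibration on real summary statistics may differ, particularly for
  palindromic-SNP handling where true strand information is unavailable.
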