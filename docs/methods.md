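# Methods

## Setting and model

The package analyses two-sample summary-statistics Mendelian randomization
(MR) with *cis* instruments: genetic variants within a window (default
±500 kb) of the gene encoding a circulating protein, used to proxy lifelong
differences in that protein. The exposure GWAS reports per-allele effects in
SD units of the standardized protein; the outcome GWAS reports per-allele
log hazard ratios (HR) for cause-specific mortality among disease cases,
with standard errors driven by the number of events. Because cis panels are
small and often correlated, estimation must incorporate the instrument
correlation (LD) matrix rather than assume independence.

### Generalized IVW

For harmonized effects bX, bY with outcome SEs se_Y and LD matrix ρ, the
weight matrix is Ω = D ρ D with D = diag(se_Y). The causal log HR per SD is
the generalized least-squares slope β̂ = (bXᵀΩ⁻¹bX)⁻¹ bXᵀΩ⁻¹bY, with
heterogeneity Q = (bY − β̂bX)ᵀΩ⁻¹(bY − β̂bX) on k−1 degrees of freedom.
Random effects are *multiplicative*: φ = max(1, Q/(k−1)) scales the variance,
so the estimator is never reported as more precise than its fixed-effect
counterpart. With identity ρ this reduces exactly to the textbook IVW
weighted average of ratio estimates; with k = 1 it reduces to the Wald ratio
with the first-order SE se_Y/|bX|.

Confidence intervals and p-values use the normal reference distribution by
default. A t reference (k−1 df for IVW, k−2 for Egger) is available via
`use_t`; point estimates are unaffected, intervals widen for small k. Both
variants are accepted when reproducing two-decimal HR tables, since the
choice moves third decimals for the panel sizes involved here.

### Sensitivity analyses

- **MR-Egger** adds a free intercept to the same generalized regression
  after orienting every variant so bX ≥ 0 (the standard convention; the
  orientation leaves the slope's meaning unchanged). A non-zero intercept
  indicates directional pleiotropy. φ uses k−2 df.
- **Weighted median** interpolates the weighted quantile function of the
  per-variant ratio estimates at 0.5, with weights ∝ bX²/se_Y². It assumes
  independent instruments; a non-identity ρ is replaced by the identity with
  a warning. Its SE comes from a seeded parametric bootstrap (default 1000
  draws) redrawing both bX and bY from their reported SEs — the literature
  gives no closed form.
- **Leave-one-out** refits the generalized IVW dropping each variant in
  turn, with the LD sub-matrix taken consistently.
- **MR-PRESSO-style outlier test** compares each variant's weighted squared
  residual against its leave-that-variant-out IVW prediction with a
  parametric null distribution (default 1000 simulations). The smallest
  reportable p is 1/(n_sim+1); per-variant p-values are Bonferroni-corrected
  over the panel. The add-one-in distortion test of the original method is
  out of scope. Requires k ≥ 4 independent instruments.
- **Bonferroni**: adjusted p = min(1, m·p); with m = 4 exposures per GWAS
  source the effective raw threshold is 0.0125.

### Harmonization

Variants are matched by identifier only (no positional fallback, no
liftover). Outcome records coded on the opposite allele have their effect
sign flipped and EAF complemented; complementary-strand codings are resolved
before declaring a mismatch. Palindromic (A/T, C/G) variants are dropped
when the exposure EAF lies in 0.5 ± 0.08, since strand cannot be resolved
there — the window is configurable and follows common two-sample MR
practice. The LD matrix stays signed relative to the exposure effect
alleles, which harmonization never re-codes; dropped variants leave the
matrix by row/column deletion. Each dropped variant carries a
machine-readable reason (`missing_in_outcome`, `palindromic_ambiguous`,
`allele_mismatch`). Harmonization is idempotent.

LD matrices are taken as input (the package never estimates LD from
genotypes). Near-PSD matrices are repaired by the smallest diagonal
inflation d with (ρ + dI)/(1+d), capped by `jitter_max`.

### Instrument strength and explained variance

Per-variant R² uses 2p(1−p)β², which assumes a standardized exposure. Total
R² defaults to the naive sum over the clumped panel — common practice, but
an overstatement when instruments are correlated — so the
correlation-adjusted quadratic form β'ρ⁻¹β (on the standardized-genotype
scale) is also computed and reported alongside. A published total R² can be
supplied as an override. F = ((n−k−1)/k)·(R²/(1−R²)).

### Power

The minimally detectable HR treats mortality as a binary outcome among
cases, ignoring follow-up time: b_min = (z_{1−α/2} + z_{pow}) /
√(n_cases·R²·r(1−r)) with event fraction r. With 16,964 cases, 4,010 events,
α = 0.05 and 80% power this gives 1.075 at R² = 0.49 and 1.107 at
R² = 0.25. Published analyses of this design print smaller values (e.g.
1.05 at R² = 0.49) that this standard binary-outcome formula does not
reproduce from the stated inputs; the exact variant behind those numbers is
under-determined, so the package implements the standard formula, exposes
every input, and documents the discrepancy rather than tuning toward the
printed values.

### Colocalization

Wakefield log ABFs (½log(1−r) + ½z²r, r = W/(V+W)) with prior effect SDs
W^0.5 = 0.15 for the quantitative protein trait and 0.2 for the log-HR
trait, and enumeration priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ — the conventional
defaults; the published analysis states none. All hypothesis sums are
carried in log space (log-sum-exp), so posteriors are exact at small z and
finite at |z| = 50. Colocalization operates on a full cis-region table, not
the clumped instruments; the synthetic generator produces such regions.
Published posterior probabilities for specific loci (PP.H4 of a few
percent, PP.H1 above 90%) require the full regional summary statistics,
which are not distributed with the printed tables; they are therefore not
recomputable here, and the implementation is validated on generated regions
with known configuration instead.

## Collider-bias simulation

Restricting a survival analysis to disease cases conditions on a collider:
any exposure that raises incidence becomes negatively correlated, among
cases, with every other cause of incidence (here BMI, age), violating MR's
independence assumption even when the exposure has no effect on mortality.
The simulation quantifies the resulting bias for a two-SNP instrument under
a true null.

Design, per replicate: a population of N = 500,000 carries genotypes at two
SNPs with pairwise r² ≈ 0.001, generated from shared haplotypes whose
alleles carry correlation √0.001. The exposure is the genetic score plus
independent noise, standardized to unit variance. BMI ~ N(27.2, 4.6²)
truncated to [15, 60] and age ~ N(64, 9²) truncated to [18, 100] are
independent of genotype. Incidence follows a proportional-hazards model with
constant baseline hazard (the exponential realization; event time by inverse
transform), linear predictor β_tnf·TNF + β_bmi·(BMI−27.2) + β_age·(age−64);
an individual is a case if onset falls within τ = 10 years. Mortality among
cases is exponential in BMI and age only — the exposure truly has no
effect. The case-only MR uses per-SNP Cox fits of death on genotype
(a vectorized univariate Newton solver, cross-checked against lifelines), the
true per-allele exposure effects (two-sample design), and the generalized
IVW with the genotype correlation realized in the case sample. Spurious
genotype-confounder associations are counted as SNPs with linear-regression
p < 0.05 against BMI among cases. 1000 replicates with counter-based child
seeds (stable as the replicate count changes) are aggregated into mean bias,
empirical type-I error, 95% CI coverage of zero, and spurious-count
statistics; a run aborts if more than 5% of replicates fail.

Default parameters are stand-ins chosen once to be epidemiologically
plausible: per-allele exposure effects (0.2, 0.15) SD at MAFs (0.3, 0.25)
(joint R² ≈ 2.5%, matching a typical cytokine pQTL panel), incidence log HRs
log 1.2 per SD exposure, log 1.03 per BMI unit, log 1.05 per year; mortality
log HRs log 1.02 per BMI unit and log 1.03 per year; baseline hazards giving
~4% cumulative incidence over 10 years and ~24% case fatality (≈ 4,010/16,964).
Every parameter is configuration, and the configuration used is embedded in
the output metadata. The published description of this simulation places its
exact parameter values in supplementary material not available here, so the
package's defaults reproduce the *structure* and the qualitative findings
(small bias, mild type-I inflation, occasional spurious SNP-BMI
associations), not the printed decimals.

Two calibration notes. First, the case-only IVW uses **fixed-effect** SEs by
default: with k = 2 the heterogeneity statistic has one degree of freedom
and the multiplicative random-effects correction max(1, Q/1) inflates the SE
erratically, making the test conservative (~2.5–4% type-I in pilot runs)
rather than nominal; a calibration study needs a nominally calibrated
estimator. The main-analysis estimator in `cismr.mr` keeps its
random-effects default. Second, under this causal structure the induced
genotype-BMI correlation among cases is *negative*, so the expected bias is
slightly negative; at the default (weak) effect sizes it is close to zero.

## Synthetic data: what it does and does not emulate

Summary statistics are drawn directly from their asymptotic sampling
distribution: for a standardized trait, per-allele SE = 1/√(2np(1−p)) (event
count n_events in place of n for the survival outcome), estimates jointly
normal around the LD-propagated marginal effects ρ·γ with correlation ρ.
Stored truth is the joint (conditional) γ; emitted summaries are marginal,
matching real GWAS output. `noise_scale=0` is a test hook that emits the
exact marginal truth, used for deterministic worked examples.

This matches two-sample summary-MR assumptions exactly, which is the point:
estimator properties (unbiasedness, coverage, oracle equivalence) are tested
under the model the estimators assume. It does *not* emulate finite-sample
LD estimation error, allele-frequency misreporting between GWAS, sample
overlap, winner's curse from in-sample instrument selection, or
population-structure confounding — so passing tests certify the statistical
machinery, not robustness to those real-data pathologies. Selection effects
that require individuals (the collider mechanism) are simulated at the
individual level in `cismr.collider` only.

Worked-example fixtures are synthetic stand-ins built with published design
values (instrument counts, R², sample and event counts) and a configured
true HR in noise-free mode; they exercise the full file-to-estimate path
deterministically. They are not the published per-variant tables, which are
distributed as journal supplementary material; those tables would slot into
the same readers unchanged.

## Numerical choices

- Ω is inverted by Cholesky factorization; a factorization failure raises
  an "ill-conditioned weight matrix" error rather than silently
  regularizing.
- Clumping ties (equal p-values) break by lexicographic variant id, making
  the output invariant to input row order.
- Generated p-values are floored at the smallest positive float so the
  pval ∈ (0,1] invariant survives extreme z-scores.
- The truncated-normal confounders are drawn by rejection (bounds are ≥2.6
  SDs from the mean, so redraw rates are below 1%).
- The univariate Cox solver uses Breslow risk sets via suffix cumulative
  sums; simulated event times are continuous, so ties do not arise.
- Problem sizes in the shipped studies: 500 replicates for parameter
  recovery; 400 replicates at population 100,000 for the null-calibration
  check and 300 at 500,000 in the test suite's full-structure check; the
  acceptance script runs the full 1000 × 500,000 study. These sizes keep
  Monte-Carlo error well inside the asserted bands.

## Known limitations

- No multivariable MR, Steiger filtering, or contamination-mixture /
  CAUSE-style estimators; no trans instruments.
- No collider-bias *correction* (regression-calibration estimators such as
  Dudbridge-style slope correction need many instruments and are out of
  scope); the simulation quantifies, it does not adjust.
- The PRESSO distortion test is not implemented.
- Gene coordinates are user input; no annotation database ships with the
  package.
- Coloc assumes at most one causal variant per trait in the region.
- The power formula ignores censoring and follow-up time by design.
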