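# cismr

Cis-Mendelian-randomization analysis of circulating protein levels against
survival outcomes, built for the setting where a handful of correlated
cis-acting pQTLs (variants within ±500 kb of the encoding gene) instrument an
inflammatory biomarker and the outcome is cause-specific mortality among
disease cases, summarized as per-SNP log hazard ratios from a survival GWAS.

It is aimed at genetic epidemiologists who work from summary statistics: the
package covers instrument selection, harmonization, correlated-instrument MR
with sensitivity analyses, colocalization, power, and — because case-only
survival analyses condition on disease status — a simulation of the collider
(index-event) bias that this conditioning can induce.

## What it computes

**Instrument selection** (`cismr.instruments`). Cis-window filtering
(±500 kb, inclusive), genome-wide significance (p < 5×10⁻⁸, strict), greedy
LD clumping at r² < 0.001 (or a relaxed r² < 0.1 for sparse loci), explained
variance R² = Σ 2p(1−p)β² (with a correlation-adjusted β'ρ⁻¹β alternative),
an R² ≥ 1% floor, and the instrument-strength statistic

    F = ((n − k − 1) / k) · (R² / (1 − R²)).

**MR estimation** (`cismr.mr`). For harmonized per-variant exposure effects
bX (SD units of the standardized protein) and outcome effects bY (log HR)
with SEs se_Y and instrument correlation matrix ρ, the generalized IVW
estimator weights by Ω⁻¹ with Ω_ij = se_Y,i · se_Y,j · ρ_ij:

    β̂ = (bXᵀ Ω⁻¹ bX)⁻¹ (bXᵀ Ω⁻¹ bY),
    Q  = (bY − β̂ bX)ᵀ Ω⁻¹ (bY − β̂ bX),   φ = max(1, Q/(k−1)),
    se(β̂) = √(φ · (bXᵀ Ω⁻¹ bX)⁻¹).

Results are reported as hazard ratios per 1 SD of the exposure. MR-Egger
(generalized, with a free pleiotropy intercept), the weighted median,
Cochran's Q, leave-one-out, Bonferroni adjustment, and an MR-PRESSO-style
global/outlier test (`cismr.presso`) round out the suite; the weighted median
and PRESSO require independent instruments and are run only for panels
clumped to independence.

**Colocalization** (`cismr.coloc`). Wakefield approximate Bayes factors
(log ABF = ½ log(1−r) + ½ z² r with r = W/(V+W)) and enumeration posteriors
PP.H0–PP.H4 over a cis region, computed in log space.

**Power** (`cismr.power`). Minimally detectable HR per SD for a case-only
binary mortality outcome:
exp((z_{1−α/2} + z_{pow}) / √(n_cases · R² · r(1−r))), r = events/cases.

**Collider-bias simulation** (`cismr.collider`). A seven-step individual
-level study: population of 500,000 with two nearly independent exposure
SNPs; confounders (BMI, age) independent of genotype; proportional-hazards
disease incidence driven by exposure, BMI and age; exponential mortality
among cases driven by BMI and age only (true exposure effect = 0); two-SNP
MR among cases; 1000 replicates aggregated into bias, type-I error, CI
coverage and spurious SNP-confounder association rates.

**Synthetic data** (`cismr.synthetic`). Exposure/outcome summary statistics
with known ground truth drawn from their asymptotic sampling distributions,
plus block LD matrices, full coloc regions, and named scenario presets
(e.g. `sIL6RA_decode`: k=13, R²=0.49, n=35,559; outcome 16,964 cases /
4,010 events).

## Worked example

```python
import numpy as np
from cismr import MRModel, synthetic
from cismr.sumstats import harmonize

# 13 independent instruments, R² = 0.49, exposure GWAS n = 35,559,
# outcome 16,964 cases / 4,010 events, true HR 1.06 — noise-free mode.
we = synthetic.make_worked_example("sIL6RA_decode", theta=np.log(1.06))
h = harmonize(we.exposure, we.outcome, we.ld)
res = MRModel(h, correlated=False).fit(
    methods=("ivw", "egger", "weighted_median"), seed=1
)
print(res.summary())
```

```
MR results (log hazard ratio per 1 SD exposure)
  instruments: k = 13 (independent)
  method            HR (95% CI)                  beta       se          p
  ivw               1.06 (1.01, 1.11)          0.0583   0.0226     0.0098
  egger_slope       1.06 (0.82, 1.38)          0.0583   0.1340      0.664
  egger_intercept   1.00 (0.92, 1.08)         -0.0000   0.0412          1
  weighted_median   1.06 (1.00, 1.12)          0.0583   0.0276     0.0345
  Cochran's Q = 0.000 (df=12, p = 1), phi = 1.000
```

The IVW hazard ratio of 1.06 per SD is the configured true effect, recovered
exactly because the fixture is noise-free; its confidence interval
(1.01–1.11) reflects the outcome GWAS standard errors implied by 4,010
events. The Egger intercept of 1.00 (on the HR scale) indicates no
directional pleiotropy — by construction here — and the weighted median
agrees with the IVW, as it should when every instrument is valid.

The same analysis runs from files via the CLI:

```bash
cismr simulate-data --scenario sIL6RA_decode --seed 7 --out data/
cismr mr --exposure data/exposure.tsv --outcome data/outcome.tsv \
         --ld data/ld.tsv --independent --out mr.json
cismr power --cases 16964 --events 4010 --r2 0.49
cismr collider-sim --reps 1000 --seed 42 --out simdir/
cismr run --config analysis.yaml   # full exposure x stratum grid
```

## Documentation

`docs/methods.md` describes the statistical model, the simulation design,
parameter defaults and their rationale, numerical choices, and known
limitations — including which published quantities are reproducible from
first principles and which are not.
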