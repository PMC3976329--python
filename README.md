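# bivargwas

Bivariate GWAS meta-analysis for the two ends of female reproductive
lifespan — age at menarche and age at natural menopause — built as a
tested, reusable pipeline and exercised end to end on synthetic cohorts.

A variant can act on reproductive lifespan in two ways: shift the whole
window earlier or later (same-direction effects on both traits), or change
its length (opposite-direction effects). Single-trait scans cannot separate
these; this package combines the two traits' association statistics into
one bivariate test and classifies the joint effect directions.

## What it computes

**The eLC combined statistic.** For each SNP, let T₁ and T₂ be the signed
Z statistics from the two univariate GWAS meta-analyses, aligned to one
shared effect allele. The empirical-weighted linear-combined statistic is

    S_eLC(T, c) = Σₖ max(|Tₖ|, c) · |Tₖ|,   c ≥ 0,

which is the sum of squares ΣTₖ² at c = 0 and approaches an equal-weight
linear combination of the |Tₖ| for large c. The weighting constant is
chosen adaptively: the reported statistic is the minimum over a fixed grid
c ∈ {0, 0.5, 1, 1.5, 2, 2.5, 3, 4} of the rank-based p-value of S_eLC —
with the same minimisation replicated inside every null draw, so the
selection cost is paid under the null and type-I error is exact by
construction.

**The perturbation null.** The K×K covariance Σ of (T₁, T₂) — nonzero
off-diagonals arise from sample overlap and phenotypic correlation — is
estimated as the genome-wide sample covariance of the Z statistics. The
null is Monte-Carlo draws from N(0, Σ); a generalized-Pareto tail fitted to
the extreme draws extrapolates p-values beyond the empirical support.
Bivariate p < 5×10⁻⁸ is genome-wide significant — except when one of the
individual trait p-values is lower than the bivariate p-value, in which
case the signal is taken as single-trait-driven, not pleiotropic.

**Supporting machinery.** Per-SNP additive-model OLS on dosages; genomic
control (λ = median(z²)/0.4549, deflation only when λ > 1); fixed-effects
inverse-variance meta-analysis with allele alignment; bivariate GREML
(AI-REML on a MAF-filtered GRM, relatedness-pruned, partial trait overlap
supported) for the genetic correlation r_g = C_g/√(V_g1·V_g2), with a
Haseman–Elston regression as an independent cross-check; and the staged
discovery→replication workflow: suggestive leads (p < 10⁻⁷), LD proxies
(r² > 0.8 within 1 Mb), staged meta-analysis, exact-binomial direction
consistency, and classification into right/left shift and lifespan
increase/decrease.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (4000 discovery / 2000 replication women, 2000 SNPs, heritability
0.5 per trait, genetic correlation 0.138, two planted pleiotropic variants)
and write their tables under `results/`:

```
python analysis/01_simulate_cohorts.py
python analysis/02_univariate_gwas.py
python analysis/03_bivariate_elc.py
python analysis/04_genetic_correlation.py
python analysis/05_replication_classification.py
```

The bivariate scan (03) reports, for this seed:

```
Z covariance: Var(Z1)=0.966 Var(Z2)=1.025 corr=0.068 over 2000 SNPs
top bivariate signals:
  snp001300  S=   49.56 c*=2.0 p=1e-12  [genome_wide]
  snp000300  S=   57.65 c*=1.0 p=1e-12  [genome_wide]
2 genome-wide and 0 additional suggestive signals
```

— the two planted variants, and nothing else, at the calibration's p-value
floor. The replication step (05) confirms both and recovers their planted
classes:

```
snp000300  p_biv=1.00e-12  class=right_shift        [planted:right_shift]
snp001300  p_biv=1.00e-12  class=lifespan_increase  [planted:lifespan_increase]
direction consistency menarche: 2/2 (sign test P = 0.5)
```

and the genetic-correlation analysis (04) on a 2000-woman full-overlap
cohort:

```
AI-REML (eigen, 5 iterations): r_g = 0.186 (s.e. 0.057, Wald P = 0.000999)
Haseman-Elston oracle: r_g = 0.165 (jackknife s.e. 0.087)
with top-10 PCs: r_g = 0.185
```

i.e. the estimate covers the generating value 0.138 within one standard
error, the method-of-moments oracle agrees, and principal-component
adjustment moves it by far less than one SE on stratification-free data.

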