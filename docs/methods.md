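# Methods

## The bivariate combined test

For each SNP the inputs are the signed per-trait association statistics
T = (T₁, T₂) — Z scores from GC-adjusted inverse-variance meta-analyses of
age at menarche and age at natural menopause — aligned to a single shared
effect allele. The combined statistic is

    S_eLC(T, c) = Σₖ max(|Tₖ|, c)·|Tₖ|,  c ≥ 0.

At c = 0 it is the sum of squared statistics; as c grows it approaches an
equal-weight linear combination of |Tₖ|, so c trades quadratic pooling
(favours one strong trait) against linear pooling (favours balanced
evidence). The statistic is exactly Σ Tₖ² at c = 0 and non-decreasing both
in each |Tₖ| and in c; both properties are asserted by tests.

**Choice of c.** No closed-form optimum exists; this implementation makes
the choice adaptive: a fixed grid c ∈ {0, 0.5, 1, 1.5, 2, 2.5, 3, 4}, and
the reported statistic is the *minimum over the grid of the rank-based
p-value* of S_eLC against the null. Crucially, the same minimisation is
performed inside every null draw, so the distribution of the minimised p
is itself calibrated and the selection costs nothing in type-I error. The
grid spans the quadratic-to-linear transition for |Z| values that matter
(|Z| ≲ 4 at genome-wide thresholds); values above ~4 are indistinguishable
from the linear limit on this scale.

**The null and its covariance.** Under the null, (T₁, T₂) ~ N(0, Σ) with
Σ the 2×2 covariance induced by sample overlap and phenotypic correlation
between the trait GWAS. Σ is estimated as the genome-wide sample
covariance of the paired Z statistics over *all* SNPs (the default); an
optional |Z| < trim cut guards against strong true signal inflating Σ in
small panels. A nearest-PSD projection handles numerical indefiniteness.
Because the pipeline operates on summary statistics, the null is calibrated
by *perturbation* (Monte-Carlo draws from N(0, Σ)); there is no
individual-level data to permute.

**Tail extrapolation.** Empirical rank p-values resolve to about 10/B.
Beyond that, two devices extend the range: (i) for each c, a generalized
Pareto distribution is fitted to the top 250 null draws of S_eLC *on the
statistic scale*, so an observed S beyond the Monte-Carlo support still
maps to a continuous per-c p (the S-scale fit is essential — a rank-scale
fit saturates at 1/B and cannot distinguish S = 30 from S = 130); and
(ii) the minimised p maps to its tail probability through the effective
number of tests m_eff, estimated from the slope of the null minimised-p
distribution near zero (P(minp ≤ x) ≈ m_eff·x; m_eff ∈ [1, |grid|], about
1.4 for this grid at ρ ≈ 0.14, reflecting the strong dependence of the
per-c statistics). Reported p-values never go below a recorded floor
(default 10⁻¹²). With B < 10⁴ the floor rises to 10⁻³. The analytic χ²₂
limit at Σ = I, c = 0 (95th percentile 5.991) is kept as a validation
anchor.

**Significance rules.** Bivariate p < 5×10⁻⁸ is genome-wide significant
with potential pleiotropic effects, and p < 10⁻⁷ suggestive — except when
one of the individual trait p-values is lower than the bivariate p-value,
in which case the signal is attributed to that trait alone and not flagged;
the driving trait is recorded. The emulated study in fact advanced six
signals including p up to 3.3×10⁻⁷, above its stated 10⁻⁷ rule, so both
thresholds are configuration values rather than constants.

## Univariate machinery

Association is ordinary least squares of the trait on dosage under an
additive model, with covariates (birth year for menarche) handled by
Frisch–Waugh residualisation — exact OLS at a fraction of the per-SNP cost.
P-values use the t reference. Noiseless fits are kept representable by a
tiny SE floor. Genomic control uses λ = median(z²)/0.4549364, deflating
only when λ > 1; the convention here is GC per study before meta-analysis
and once more after (each application toggleable), the conservative
double-GC convention of the consortium era. Fixed-effects meta-analysis
weights by 1/SE²; alleles are aligned to the first study reporting each
SNP, with swapped-allele sign flips, unambiguous strand-complement
resolution (logged, never silent), and palindromic (A/T, C/G) SNPs oriented
by allele frequency only when both frequencies are at least 0.08 from 0.5
— otherwise the record is excluded. Cochran's Q is reported, never
filtered on.

## Genetic correlation (bivariate GREML)

The GRM is A = (1/m)·Xs·Xsᵀ over SNPs with MAF > 0.01, with Xs the
dosages centred at 2p̂ and scaled by √(2p̂(1−p̂)). Relatedness pruning is
greedy: repeatedly drop the individual in the most pairs ≥ threshold (ties:
the lexicographically later id), guaranteeing the retained set is below
threshold — the threshold is 0.025 by convention, which presumes the
~1/√m GRM sampling noise of a several-hundred-thousand-SNP panel; the
analysis drivers scale it to the panel at hand.

The two-trait mixed model has genetic covariance G₀⊗A and residual
covariance E₀⊗I, with the residual cross-covariance coupling only the two
observations of the same individual, so traits measured on different,
partially overlapping subsets are handled by the general missing-pattern
likelihood. Fitting is average-information REML: AI steps with damped
fallback (step-halving until the restricted likelihood is non-decreasing),
variance components clamped at zero and covariances at |ρ| ≤ 0.9999 (so a
degenerate duplicate-trait input converges to r_g ≈ 1 rather than a
singular covariance). Standard errors come from the inverse AI matrix;
the SE of r_g = C_g/√(V_g1·V_g2) by the delta method; the r_g p-value is a
Wald test against the normal. When both traits are observed on the
identical sample set, the model is solved in the eigenbasis of A, where
the covariance factorises into independent 2×2 blocks per eigenvalue — one
eigendecomposition replaces all O(n³) per-iteration algebra and each
iteration costs O(n·q²).

The Haseman–Elston oracle regresses standardized phenotype cross-products
on GRM entries: within-trait products (i < j) estimate h², cross-trait
products over distinct individuals estimate the standardized C_g, and
block-jackknife over 20 contiguous sample blocks gives SEs. It ignores
covariates deliberately — it exists to cross-check REML, not to replace
it. Simulations here show the two estimators' r_g values correlate > 0.8
across replicates and that AI SEs match the empirical spread (e.g.
empirical SD 0.075 vs mean reported SE 0.072 at n = m = 1000).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real cohort. Genotypes are independent Binomial(2, p) dosages with p
uniform on the MAF range (Hardy–Weinberg by construction); an optional
block mode copies lead gametes with retention probability ρ, giving dosage
correlation exactly ρ for LD-proxy work. Per-SNP effect pairs are drawn
bivariate normal with covariance set by (h², r_g)/m on the standardized
genotype scale — the same scale as the GRM, so h² is exact in expectation
regardless of MAF — and realized genetic values are rescaled so each
trait's genetic variance is exactly h². Residual pairs carry variance
1 − h² and correlation r_e. Liabilities map affinely to trait units
(menarche: mean 13, SD 1.5; menopause: mean 51, SD 4 — cosmetic, since
the analysis is affine-invariant). Inclusion windows (menarche recalled
between 9 and 17, natural menopause between 40 and 60) are applied as
missingness, never resampling, and the excluded fraction is reported. The
overlap design measures both traits on a shared subcohort
(overlap_fraction of the sample) and splits the remainder into
trait-exclusive halves.

Defaults are the emulated study's conditions: h² = 0.5 per trait (about
half the variation in both traits is genetic), r_g = 0.138, overlap
fraction 0.36 (the both-trait sample over the union, at the emulated
consortium's Ns). r_e is not reported anywhere; 0.1 is used as a modest
phenotypic-correlation value consistent with the epidemiology. What the
generator does *not* model: LD beyond the optional proxy blocks,
ascertainment, secular trends, or covariate-driven exclusions — so passing
tests demonstrate the statistical machinery, not robustness to real-data
artifacts like stratification or imputation error.

A note on genomic control under this generator: with every SNP causal and
m in the low thousands, per-SNP non-centrality n·h²/m is order one and λ
lands near 1.3–1.7 — honest polygenic inflation, which GC (designed for
confounding) deflates. Planted effects are therefore specified with mean
per-trait Z of 7 where the recovery studies call for non-centrality of at
least 6, absorbing the ~√λ deflation.

## Problem sizes and numerical choices

The test suite and acceptance script use: B = 10⁵–2×10⁵ perturbation
draws; 10⁵ null SNPs for calibration checks; 2000 replicates for power
comparisons; 50 replicate cohorts at n = m = 2000 for GREML recovery (the
eigen fast path makes each fit ~2 s); 20 end-to-end pipeline runs at
n = 4000, 2000 SNPs. These sizes make every Monte-Carlo tolerance a ≥3-SE
bound while keeping the full suite in a few minutes. Ties in lead
selection break lowest-p-first, then by SNP id; the 1 Mb thinning window is
inclusive on both ends, as are the phenotype windows. Degenerate inputs —
monomorphic SNPs, collinear covariates, zero betas in classification,
empty hit sets — are either excluded with counts or raise typed errors, as
specified per operation.

## Known limitations

The adaptive-minimum-p construction and the m_eff tail approximation are
this repository's resolution of a design in which the weighting constant
is left to be tuned empirically to the data at hand; other resolutions
(analytic approximations, different grids) would give slightly different
deep-tail p-values. GPD extrapolation below ~10/B inherits fit noise in the extreme
tail. The GREML solver fits the single-GRM, two-trait model only; X
chromosome, multi-component and LD-score approaches are out of scope, as
are eQTL lookup, pathway analysis and imputation.
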