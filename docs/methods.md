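# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limits of what a passing test
establishes.

## Mixed linear models

**Base model.** For each trait, `y = X b + g + e` with `g ~ N(0, K sg2)`,
`e ~ N(0, I se2)`, and `K = Z Z' / M` over genotypes standardized with the
training mean and *population* SD (ddof = 0) of counted-allele copies;
missing genotypes are mean-imputed (z = 0), which makes Z exactly
column-centred.  This is equivalent to every SNP effect being a random
draw from `N(0, su2)` with `sg2 = M su2`.  SNP heritability is
`h2 = sg2 / (sg2 + se2)`.

**REML.** One genomic component: K is eigendecomposed once and the
restricted likelihood is profiled down to a 1-D bounded search over
`log(sg2/se2)` on [-14, 14] (Brent, xatol 1e-10) — no iteration, no
convergence failures.  Several components (effect-size groups, MAF strata):
average-information REML.  The first step is always EM; an AI proposal
that would push a component below the floor `1e-8 x var(y)` is retried
with the offending components clamped at the floor and the AI step taken
on the rest, and failing that, a full EM step.  Convergence is
`|delta logL| < 1e-6`; hitting `max_iter` returns a flagged (never silent)
estimate.  Standard errors come from the inverse average-information
matrix, with delta-method propagation to h2.

**SNP-BLUP.** Effects are back-solved as
`a_c = su2(c) Z_c' V^-1 (y - X b_hat)` with
`V = sum_c sg2(c) K_c + se2 I` and GLS `b_hat`.  This dual form equals the
primal ridge solution `(Z'Z + (se2/su2) I)^-1 Z' r` exactly (tested to
1e-8), and predicted genetic values equal the GBLUP form
`sg2 K V^-1 r`.

**Effect-size groups.** A marginal OLS scan on standardized genotypes
(the same covariates as the mixed model) provides per-SNP estimates; SNPs
more than 3 SDs from the mean estimate form the "tail" component, the
rest the "main" component, and the two variances are re-estimated jointly.
Grouping is in-sample (the same data are used for grouping and refitting),
mirroring the original design; this is a known overfitting risk and is
deliberately not corrected.

**MAF strata.** Three components with strict boundaries — MAF > 0.05,
0.01 < MAF < 0.05, 0.001 < MAF < 0.01.  Variants exactly at a boundary or
at/below 0.001 are reported as unassigned (with a warning) and excluded,
because the printed inequalities are strict on both sides.

**Multivariate model.** T traits share one K; SNP-effect vectors across
traits have covariance `Sigma_u` and residuals `Sigma_e` (both T x T).
Rotating through the eigenbasis of K factorizes the restricted likelihood
into n independent T x T blocks (`V_i = d_i Sigma_g + Sigma_e`), which is
maximized over Cholesky factors by L-BFGS-B — PSD holds by construction
rather than by projection.  Genetic correlations get delta-method SEs from
a numerically observed information matrix in the covariance-element
parameterization; at boundary optima (rg near 1) infeasible probe points
are assigned zero curvature so the pseudo-inverse reports a wide SE rather
than crashing.  Missing-trait samples are dropped listwise.

## Quality control

All defaults are the published thresholds: variant missingness > 2%,
platform-differential missingness (two-sided Fisher exact) below 1e-100,
MAF strictly > 0.05 and Hardy-Weinberg exact p below 1e-50 — both computed
on the unrelated training subset — sample missingness > 5%, relatedness
cut 0.0625, ancestry outliers beyond 3 SD on any of the leading 20 PCs,
groups below 1,000 dropped, phenotype values strictly outside ±3 SD of the
per-sex mean set to missing.

Both exact tests are computed in log space (gammaln / logsumexp), so
far-tail p-values compare correctly against the 1e-100 and 1e-50 cuts even
where the linear-scale p underflows a double; the Fisher test returns
`(p, log10_p)` for this reason.  The HWE test enumerates every
heterozygote count compatible with the observed minor-allele count and is
verified against exact fraction arithmetic.

Choices the source left open: heterozygosity outliers at ±3 SD (the
original deferred to internal biobank QC); X-inbreeding sex calls at
F > 0.8 male / F < 0.2 female (common practice; no thresholds given);
greedy max-degree removal for the unrelated set (ties: larger maximum
kinship, then identifier order) — the original algorithm is unspecified,
but the postcondition (no retained pair above threshold) is tested on
1,000 random matrices.  Filter order fixes MAF/HWE last, after the
relatedness split defines the training subset.

**Relatedness needs the full marker panel.** GRM off-diagonal noise has
SD ~ 1/sqrt(M_eff); on an LD-pruned panel of a few thousand markers the
0.0625 cut sits only ~3 SD from zero and thousands of unrelated pairs
cross it.  The pipeline therefore estimates relatedness from all QC-passed
autosomal markers, while PCA uses the LD-pruned set (window 50, step 5,
r2 0.2 — declared defaults, not inferred from the original pruned panel).

## Synthetic cohorts

The generator emulates, per population: Balding-Nichols allele-frequency
divergence (`Beta(p(1-F)/F, (1-p)(1-F)/F)` around an ancestral p drawn
from a configurable MAF law); LD through thresholded latent AR(1)
Gaussians per haplotype within fixed-size blocks — the latent coefficient
is `sin(pi r/2)` of the target genotype correlation, which inverts the
tetrachoric attenuation exactly at MAF 0.5 and approximately below (the
realized adjacent-SNP correlation is slightly weaker at low MAF);
sib pairs bred by per-SNP Mendelian transmission (expected GRM 0.5;
transmission is unlinked across SNPs, so within-gamete LD is not
preserved); an X-like block coded homozygous in males to exercise the sex
check; two platforms with baseline and variant-biased missingness applied
*after* phenotypes are formed, so the truth set is error-free; and
additive architectures — spike-and-slab causal sets, Gaussian /
two-component / MAF-stratified effect variances, cross-trait genetic and
environmental correlation matrices (PSD-validated).  Environmental noise
is scaled so the realized `Var(g)/(Var(g)+Var(e))` hits the h2 target
exactly in-sample.  One integer seed fixes everything; the same seed
reproduces the cohort byte for byte.

What the generator does **not** emulate: coalescent genealogies and
realistic haplotype sharing, imputation error, genotype-intensity
artifacts, non-additive effects, and ascertainment of the SNP panel.  A
green parameter-recovery test therefore establishes correctness of the
estimator under the stated generative model, not robustness to real-data
pathologies.

## Prediction evaluation

Scores are covariate-free genetic values using training standardization
statistics; a flipped counted allele in the target is reconciled by
`s -> 2 - s`; variants missing from the target are skipped up to 5% of the
scoring set (error above).  Accuracy is Pearson r against phenotypes
residualized on the *evaluation* set's own covariates (matching the
"corrected for sex and age" design), with Fisher-z 95% CIs — the CI method
is a choice; the original reports CIs without naming one.  k-fold CV
refits everything (including standardization) on the training folds only.

The C+T baseline scans each SNP by OLS (Frisch-Waugh residualization; the
original used BOLT-LMM, a deliberate substitution documented here: on
simulated unrelated cohorts mixed-model association changes cost, not
logic, and PC covariates are available for structured cohorts), clumps
greedily by ascending p (absorb r2 > 0.05 within 1 Mb, ties by position
then id), and profiles accuracy over thresholds 5e-8 … 1.  The optimal
threshold is selected on the same validation set that is reported —
replicating the original design and its acknowledged overfitting.

## Extrapolation

Unweighted OLS of `1/r^2` on `1/n`, one point per (size, trial); the
intercept estimates `1/h2` (maximum accuracy `1/sqrt(b0)`), and
projections carry delta-method SEs from the OLS covariance (the original's
SE method is unstated; ours is labelled).  Percent-of-maximum values are
rounded to the nearest integer in reports.  At desk scale the fit is only
stable when the subsampled accuracies stay well above zero (noise in
`1/r^2` scales as `2 dr / r^3`), so pipeline subsample fractions start at
25-40% of the training set; a nonpositive fitted intercept is flagged and
the maximum accuracy reported as undefined rather than extrapolated.

## Pipeline worlds

The packaged `small` config states a ~3,000-sample, 20,000-SNP world: a
reference ancestry (2,400 plus 150 sib pairs) and two Balding-Nichols
diverged groups (Fst 0.05 and 0.15), MAF uniform on [0.001, 0.5] so the
MAF-stratified model has rare content, two traits (h2 0.5 and 0.4,
genetic correlation 0.6, environmental 0.3), sex/age effects of 0.5 and
0.01 per year over ages 40-70 (the original cohort's covariate effect
sizes are unpublished; these are configurable defaults), and mild
platform missingness.  The minimum ancestry-group size is lowered from
1,000 (the published default, kept as the package default) to 150 so the
diverged groups survive at desk scale.  At this scale the platform-bias
Fisher stage cannot fire: any bias strong enough for p < 1e-100 also
exceeds the 2% overall-missingness cut that precedes it, so biased
variants exit one stage early; the far-tail behaviour of the test itself
is exercised directly on designed 5,000-per-platform counts.

Validation-group accuracies at these sizes carry sampling SEs of about
0.06-0.07, so orderings between groups (e.g. across-ancestry attenuation)
are visible only as trends, not per-run certainties; the reports state
CIs for exactly this reason.
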