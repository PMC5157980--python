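# snpblup

Desk-scale genomic prediction with mixed linear models.

`snpblup` re-creates, end to end and on simulated cohorts, the workflow used
to build polygenic predictors from large biobank-style datasets: joint
estimation of all SNP effects as random effects (SNP-BLUP / GBLUP), REML
variance components with one or several genomic components, polygenic
scoring with within- and across-ancestry accuracy evaluation, the classical
clump+threshold (C+T) GWAS predictor as a baseline, and extrapolation of
prediction accuracy to larger training cohorts.  Because individual-level
biobank data is access-restricted, the package ships a synthetic-cohort
generator that reproduces the statistical structure the analysis assumes
(ancestry-differentiated allele frequencies, LD blocks, relatives,
platform-differential missingness, additive trait architectures), so every
stage is fully testable offline.

It is aimed at statistical geneticists and methods developers who want a
transparent, tested, single-machine implementation of this pipeline — for
teaching, for method prototyping, or as a reference against production
tools (PLINK, GCTA, DISSECT, BOLT-LMM).

## The model

Phenotypes are modelled as

```
y_i = mu + sum_l x_il b_l + sum_j z_ij a_j + e_i
```

where `z_ij = (s_ij - mu*_j) / sigma*_j` is the standardized count of the
counted allele (training mean and SD), the SNP effects `a ~ N(0, I su2)`
and residuals `e ~ N(0, I se2)`.  With `sg2 = M su2`, SNP heritability is
`h2 = sg2 / (sg2 + se2)`.  Fitting uses REML: an exact eigendecomposition
of the genomic relationship matrix `K = Z Z' / M` for one component, and
average-information REML (with EM fallback) for effect-size-grouped,
MAF-stratified, and multivariate models.  Effects are back-solved as
`a = su2 Z' V^-1 (y - X b)`, and an individual's polygenic score is
`sum_j z_ij a_j`.  Prediction accuracy is the Pearson correlation between
scores and phenotypes residualized on sex and age, with Fisher-z 95% CIs.
Accuracy as a function of training size n follows
`r^2 = h2 / (1 + Me / (n h2))`, linear in `1/n` on the `1/r^2` scale, which
the `extrapolate` module uses to project accuracy at a target cohort size
and to express it as a percentage of the ceiling `sqrt(h2)`.

## Worked example

Run the packaged small workflow (about 2,900 samples after QC, ~18,000
common SNPs, two correlated traits) from the shell:

```bash
snpblup all --outdir out/          # packaged config; ~4 min on one CPU
```

or a reduced version programmatically:

```python
from snpblup.config import packaged_config
from snpblup.pipeline import run_all
cfg = packaged_config("small")
summary = run_all(cfg, "out/")
```

From one such run (reduced scale, seed 1), `out/table1_analogue.tsv` holds
the within-ancestry accuracies of the single-component SNP-BLUP predictor:

```
model  trait       group   n        r   ci_low  ci_high
 main height     holdout 265 0.194237 0.075505 0.307537
 main height     related  93 0.420623 0.237243 0.575058
 main height pca_outlier 281 0.315104 0.205675 0.416750
```

`holdout` is a random held-out subset of the unrelated training ancestry,
`related` are samples with a genomic relationship above 0.0625 to the
training set (they score highest, as expected for relatives), and
`pca_outlier` are same-ancestry samples excluded from training by the
20-PC / 3-SD ancestry filter.  `out/table2_analogue.tsv` reports the same
predictor scored across diverged ancestries, and
`out/variance_components.json` the REML fits, e.g. for this run
`h2(height) = 0.397 (SE 0.066)` against a realized simulated value of 0.5
of which the common-SNP panel captures only part, and a bivariate genetic
correlation of `0.53 (SE 0.10)` against a generative 0.6.
`out/ct_profile_height.tsv` is the C+T comparison (threshold, number of
index SNPs, accuracy), and `out/extrapolation_height.json` the `1/r^2` vs
`1/n` fit with the projected accuracy at n = 500,000 and its percentage of
the `sqrt(h2)` ceiling.

The same stages are available piecewise: `snpblup simulate | qc | grm |
fit | score | cv | gwas | clump | extrapolate` (see `--help`), reading and
writing PLINK .bed/.bim/.fam, TSV phenotype tables, and TSV scoring files
(columns: variant id, counted allele, effect, training mean, training SD).

## Acceptance script

`scripts/acceptance.py` re-runs the complete analysis from scratch —
simulating the cohort, applying every QC filter at its published default,
fitting all model variants, scoring all validation groups, and running the
C+T and extrapolation comparisons — at a reduced scale chosen to finish in
about a minute:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Stage artifacts are written next to the output file under
`results/pipeline/`; the JSON written to `--out` is the script's result
mapping.
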