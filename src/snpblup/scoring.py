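"""Polygenic scoring and prediction-accuracy evaluation.

A polygenic score is the covariate-free genetic value
yhat_i = sum_j ((s_ij - mu*_j) / sigma*_j) a_j, with mu*_j and sigma*_j the
counted-allele mean and SD in the *training* population.  Accuracy is the
Pearson correlation between scores and phenotypes residualized on the
evaluation set's covariates, with a Fisher-z 95% confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, PhenotypeTable
from .kinship import compute_grm, standardize
from .mlm import SNPEffectSet, reml_fit, snp_blup


@dataclass
class PredictionResult:
    scores: pd.Series | None
    r: float
    ci_low: float
    ci_high: float
    n: int
    trait: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation outside [-1, 1]")

    def as_row(self) -> dict:
        return {"trait": self.trait, "group": self.group, "n": self.n,
                "r": self.r, "ci_low": self.ci_low, "ci_high": self.ci_high}


def polygenic_score(gm: GenotypeMatrix, effects: SNPEffectSet, *,
                    allele_policy: str = "flip",
                    max_unmatched: float = 0.05) -> pd.Series:
    """Score every sample in ``gm`` with a fitted SNP-effect set.

    Missing target genotypes contribute zero (training-mean imputation).
    Variants absent from the target (or with irreconcilable alleles) are
    skipped with a warning up to ``max_unmatched`` of the set, beyond which
    scoring errors out.  A counted-allele flip is reconciled by s -> 2 - s.
    """
    tab = effects.table
    idx = pd.Index(gm.variants["id"])
    pos = idx.get_indexer(tab["id"])
    matched = pos >= 0
    frac_unmatched = 1.0 - matched.mean()
    if frac_unmatched > max_unmatched:
        raise ValueError(f"{frac_unmatched:.1%} of scoring variants missing "
                         f"from target (limit {max_unmatched:.0%})")
    if frac_unmatched > 0:
        warnings.warn(f"skipping {(~matched).sum()} scoring variants absent "
                      "from target")
    tab = tab.loc[matched]
    cols = pos[matched]

    counts = gm.counts[:, cols].astype(float)
    counts[counts < 0] = np.nan
    target_a1 = gm.variants["a1"].to_numpy()[cols]
    flipped = target_a1 != tab["a1"].to_numpy()
    if flipped.any():
        if allele_policy != "flip":
            raise ValueError("counted-allele mismatch in scoring file")
        counts[:, flipped] = 2.0 - counts[:, flipped]

    z = (counts - tab["mean"].to_numpy()) / tab["sd"].to_numpy()
    z[np.isnan(z)] = 0.0
    return pd.Series(z @ tab["effect"].to_numpy(),
                     index=gm.samples["iid"].to_numpy(), name="score")


def adjust_phenotype(y, covariates) -> np.ndarray:
    """Residuals of y on intercept + covariates, fitted on the given samples."""
    y = np.asarray(y, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != len(y):
        C = C.T
    X = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def accuracy(scores, adjusted_y, *, trait: str = "", group: str = "",
             keep_scores: bool = False) -> PredictionResult:
    """Pearson accuracy with a Fisher-z 95% confidence interval."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(adjusted_y, dtype=float).ravel()
    ok = np.isfinite(s) & np.isfinite(y)
    s, y = s[ok], y[ok]
    n = len(s)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if s.std() == 0 or y.std() == 0:
        raise ValueError("constant vector; correlation undefined")
    r = float(np.corrcoef(s, y)[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(n - 3)
    # clamp so the interval always contains r (degenerate at |r| ~ 1)
    lo = min(float(np.tanh(z - half)), r)
    hi = max(float(np.tanh(z + half)), r)
    return PredictionResult(
        scores=pd.Series(s) if keep_scores else None,
        r=r, ci_low=lo, ci_high=hi, n=n, trait=trait, group=group)


# ---------------------------------------------------------------------------
# Cross-validation and subsampling
# ---------------------------------------------------------------------------

def _fit_and_score(gm_train: GenotypeMatrix, gm_test: GenotypeMatrix,
                   pheno: PhenotypeTable, trait: str, *, tol=1e-6):
    """One train/evaluate round: standardize, REML, BLUP, score, correlate."""
    z, stats = standardize(gm_train)
    data_tr = pheno.data.loc[gm_train.samples["iid"]]
    y = data_tr[trait].to_numpy()
    X = data_tr[list(pheno.covariates)].to_numpy()
    kin = compute_grm(z, ids=gm_train.samples["iid"])
    est = reml_fit(y, X, kin, tol=tol)
    eff = snp_blup(z, X, y, est, stats=stats, kinships=kin.values)

    scores = polygenic_score(gm_test, eff)
    data_te = pheno.data.loc[gm_test.samples["iid"]]
    mask = data_te[trait].notna().to_numpy()
    adj = adjust_phenotype(data_te.loc[mask, trait],
                           data_te.loc[mask, list(pheno.covariates)])
    return accuracy(scores.to_numpy()[mask], adj, trait=trait), est


def kfold_cv(gm: GenotypeMatrix, pheno: PhenotypeTable, trait: str, *,
             k: int = 10, seed: int = 0, tol: float = 1e-6):
    """k-fold cross-validated SNP-BLUP accuracy.

    Folds partition the samples; each fold is scored by a model trained on
    the other k-1 folds only (standardization statistics included), so
    held-out samples never touch training.  Returns (per-fold results,
    mean r, SD of r).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = gm.n_samples
    rng = np.random.default_rng(seed)
    fold_of = rng.permuted(np.arange(n) % k)
    if min(np.bincount(fold_of, minlength=k)) < 10:
        raise ValueError("a fold has fewer than 10 samples")

    results = []
    for fold in range(k):
        test = fold_of == fold
        res, _ = _fit_and_score(gm.subset(samples=~test),
                                gm.subset(samples=test), pheno, trait, tol=tol)
        res.group = f"fold{fold}"
        results.append(res)
    rs = np.array([r.r for r in results])
    return results, float(rs.mean()), float(rs.std(ddof=1))


def subsample_series(gm_train: GenotypeMatrix, gm_test: GenotypeMatrix,
                     pheno: PhenotypeTable, trait: str, sizes, *,
                     n_seeds: int = 1, seed: int = 0, tol: float = 1e-6):
    """Accuracy at decreasing training sizes against one fixed held-out set.

    Returns a DataFrame with one row per (size, seed): training n and
    accuracy r.  Needs >= 3 distinct sizes for the downstream 1/r^2 fit.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if len(sizes) < 3:
        raise ValueError("need at least 3 distinct training sizes")
    if max(sizes) > gm_train.n_samples:
        raise ValueError("subsample size exceeds available training samples")
    rows = []
    for size in sizes:
        for rep in range(n_seeds):
            rng = np.random.default_rng([seed, size, rep])
            pick = rng.choice(gm_train.n_samples, size=size, replace=False)
            res, _ = _fit_and_score(gm_train.subset(samples=np.sort(pick)),
                                    gm_test, pheno, trait, tol=tol)
            rows.append({"n": size, "seed": rep, "r": res.r})
    return pd.DataFrame(rows)
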