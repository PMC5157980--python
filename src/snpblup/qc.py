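"""Variant, sample, phenotype, ancestry and relatedness quality control.

Every threshold default is the one printed in the source study: variant
missingness 2%, platform-differential missingness Fisher P < 1e-100, MAF
strictly > 0.05, Hardy-Weinberg exact P < 1e-50 (both computed on the
unrelated training subset), sample missingness 5%, heterozygosity outliers
beyond +/-3 SD, relatedness cut 0.0625 (second cousins once removed),
ancestry outliers beyond 3 SD on the leading 20 principal components,
phenotype outliers strictly outside +/-3 SD of the per-sex mean.

The two exact tests are computed in log space so that far-tail p-values
(the 1e-100 and 1e-50 cuts) compare correctly even where the linear-scale
p underflows a float.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io_formats import GenotypeMatrix, PhenotypeTable

_LN10 = np.log(10.0)


@dataclass
class QCReport:
    """Ordered record of applied filters: name, threshold, removed, retained."""

    stages: list = field(default_factory=list)

    def add(self, name: str, threshold, n_in: int, n_removed: int) -> None:
        self.stages.append({
            "filter": name,
            "threshold": threshold,
            "input": int(n_in),
            "removed": int(n_removed),
            "retained": int(n_in - n_removed),
        })

    def to_json(self, path=None) -> str:
        text = json.dumps(self.stages, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def __str__(self) -> str:
        lines = [f"{s['filter']} (threshold={s['threshold']}): "
                 f"{s['input']} -> {s['retained']} (-{s['removed']})"
                 for s in self.stages]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test conditional on the minor-allele count.

    Enumerates every heterozygote count compatible with the observed
    rare-allele count and sums the probabilities of configurations no more
    probable than the observed one.  Monomorphic input gives p = 1.
    """
    counts = (n_hom_minor, n_het, n_hom_major)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be nonnegative integers")
    n = int(sum(counts))
    if n == 0:
        raise ValueError("empty genotype table")
    n_rare = 2 * int(n_hom_minor) + int(n_het)
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hom_r - hets
    # log multinomial weight x 2^het (allele-phase multiplicity)
    logw = (gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(hets + 1)
            - gammaln(hom_c + 1) + hets * np.log(2.0))
    logz = logsumexp(logw)
    logp = logw - logz
    obs = logp[hets == int(n_het)][0]
    keep = logp <= obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


class FisherResult(NamedTuple):
    """Two-sided Fisher exact p-value with its log10 (finite in the far tail)."""

    p: float
    log10_p: float


def platform_missingness_test(missing_a: int, called_a: int,
                              missing_b: int, called_b: int) -> FisherResult:
    """Two-sided Fisher exact test for platform-differential missingness.

    Works on the 2x2 table [[missing_a, called_a], [missing_b, called_b]].
    Computed in log space: ``log10_p`` stays finite far below 1e-308.
    """
    cells = (missing_a, called_a, missing_b, called_b)
    if any(c < 0 or c != int(c) for c in cells):
        raise ValueError("table cells must be nonnegative integers")
    if sum(cells) == 0:
        raise ValueError("empty 2x2 table")
    row_a = missing_a + called_a
    row_b = missing_b + called_b
    col_miss = missing_a + missing_b
    total = row_a + row_b
    if row_a == 0 or row_b == 0 or col_miss == 0 or col_miss == total:
        return FisherResult(1.0, 0.0)

    k = np.arange(max(0, col_miss - row_b), min(row_a, col_miss) + 1)
    # central hypergeometric log-pmf via log-binomials
    logpmf = (_logcomb(row_a, k) + _logcomb(row_b, col_miss - k)
              - _logcomb(total, col_miss))
    obs = logpmf[k == int(missing_a)][0]
    keep = logpmf <= obs + np.log1p(1e-7)
    logp = min(0.0, float(logsumexp(logpmf[keep])))
    return FisherResult(float(np.exp(logp)), logp / _LN10)


def _logcomb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

def variant_qc(gm: GenotypeMatrix, *, max_missing: float = 0.02,
               platform_log10p: float = -100.0, min_maf: float = 0.05,
               hwe_log10p: float = -50.0,
               training_samples=None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the variant filters in their fixed order.

    Order: multi-allelic, overall missingness > ``max_missing``, platform
    Fisher below ``platform_log10p``, then — computed on the designated
    unrelated training subset — MAF <= ``min_maf`` (strict > retained) and
    Hardy-Weinberg exact p below ``hwe_log10p``.
    """
    for name, val in (("max_missing", max_missing), ("min_maf", min_maf)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    report = QCReport()
    keep = np.ones(gm.n_variants, dtype=bool)

    bad = (gm.variants["a1"] == gm.variants["a2"]).to_numpy()
    report.add("multi_allelic", None, keep.sum(), bad[keep].sum())
    keep &= ~bad

    miss = gm.variant_missingness()
    bad = miss > max_missing
    report.add("variant_missingness", max_missing, keep.sum(), (bad & keep).sum())
    keep &= ~bad

    platforms = gm.samples["platform"] if "platform" in gm.samples else None
    if platforms is not None and platforms.notna().any() and platforms.nunique() > 1:
        labels = platforms.to_numpy()
        uniq = pd.unique(labels[pd.notna(labels)])[:2]
        in_a = labels == uniq[0]
        in_b = labels == uniq[1]
        missing = gm.missing_mask()
        miss_a = missing[in_a].sum(axis=0)
        miss_b = missing[in_b].sum(axis=0)
        n_a, n_b = int(in_a.sum()), int(in_b.sum())
        bad = np.zeros(gm.n_variants, dtype=bool)
        for j in np.flatnonzero(keep):
            if miss_a[j] + miss_b[j] == 0:
                continue
            res = platform_missingness_test(miss_a[j], n_a - miss_a[j],
                                            miss_b[j], n_b - miss_b[j])
            bad[j] = res.log10_p < platform_log10p
        report.add("platform_missingness_fisher", f"1e{platform_log10p:g}",
                   keep.sum(), (bad & keep).sum())
        keep &= ~bad
    else:
        report.add("platform_missingness_fisher", f"1e{platform_log10p:g}",
                   keep.sum(), 0)

    if training_samples is not None:
        train = gm.select_samples(training_samples)
    else:
        train = gm
    maf = train.maf()
    bad = ~(maf > min_maf)  # NaN-safe: all-missing columns removed too
    report.add("maf", min_maf, keep.sum(), (bad & keep).sum())
    keep &= ~bad

    bad = np.zeros(gm.n_variants, dtype=bool)
    counts = train.counts
    freq = train.allele_frequency()
    todo = np.flatnonzero(keep) if np.isfinite(hwe_log10p) else []
    for j in todo:
        col = counts[:, j]
        col = col[col >= 0]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        hom_minor, hom_major = (n2, n0) if freq[j] <= 0.5 else (n0, n2)
        p = hwe_exact_test(hom_minor, n1, hom_major)
        with np.errstate(divide="ignore"):
            bad[j] = np.log10(p) < hwe_log10p if p > 0 else True
    report.add("hwe_exact", f"1e{hwe_log10p:g}", keep.sum(), (bad & keep).sum())
    keep &= ~bad

    return gm.subset(variants=keep), report


# ---------------------------------------------------------------------------
# Sample filters
# ---------------------------------------------------------------------------

def x_inbreeding(gm: GenotypeMatrix, x_chrom: str = "23") -> np.ndarray:
    """Per-sample inbreeding coefficient F on the X-like block.

    F = 1 - observed het / expected het under the block's allele
    frequencies; hemizygous-coded males give F near 1, females near 0.
    """
    on_x = (gm.variants["chrom"].astype(str) == str(x_chrom)).to_numpy()
    if not on_x.any():
        raise ValueError("no X-like variants present; cannot run sex check")
    sub = gm.subset(variants=on_x)
    freq = sub.allele_frequency()
    exp_het = 2.0 * freq * (1.0 - freq)
    miss = sub.missing_mask()
    obs = ((sub.counts == 1) & ~miss).sum(axis=1)
    exp = np.where(miss, 0.0, exp_het[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(exp > 0, 1.0 - obs / exp, np.nan)


def sample_qc(gm: GenotypeMatrix, *, max_missing: float = 0.05,
              het_sd: float = 3.0, sex_check: bool = True,
              x_chrom: str = "23",
              f_male: float = 0.8, f_female: float = 0.2
              ) -> tuple[np.ndarray, QCReport]:
    """Sample filters: missingness, heterozygosity outliers, sex mismatch.

    Returns the boolean keep-mask over samples plus the report.  Sex calls:
    male if X inbreeding F > ``f_male``, female if F < ``f_female``,
    otherwise no call (never removed on a no-call).
    """
    report = QCReport()
    keep = np.ones(gm.n_samples, dtype=bool)

    autosomal = (gm.variants["chrom"].astype(str) != str(x_chrom)).to_numpy()
    auto = gm.subset(variants=autosomal) if not autosomal.all() else gm

    miss = auto.sample_missingness()
    bad = miss > max_missing
    report.add("sample_missingness", max_missing, keep.sum(), (bad & keep).sum())
    keep &= ~bad

    missm = auto.missing_mask()
    called = (~missm).sum(axis=1)
    het = ((auto.counts == 1) & ~missm).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het_rate = np.where(called > 0, het / called, np.nan)
    mu = np.nanmean(het_rate[keep])
    sd = np.nanstd(het_rate[keep])
    bad = np.abs(het_rate - mu) > het_sd * sd if sd > 0 else np.zeros_like(keep)
    report.add("heterozygosity_outlier", f"{het_sd} SD", keep.sum(),
               (bad & keep).sum())
    keep &= ~bad

    if sex_check:
        f = x_inbreeding(gm, x_chrom=x_chrom)
        call = np.zeros(gm.n_samples, dtype=int)  # 0 = no call
        call[f > f_male] = 1
        call[f < f_female] = 2
        reported = gm.samples["sex"].fillna(0).astype(int).to_numpy()
        bad = (call != 0) & (reported != 0) & (call != reported)
        report.add("sex_mismatch", f"F<{f_female}|F>{f_male}", keep.sum(),
                   (bad & keep).sum())
        keep &= ~bad

    return keep, report


# ---------------------------------------------------------------------------
# Phenotype, ancestry, relatedness
# ---------------------------------------------------------------------------

def phenotype_outlier_filter(pheno: PhenotypeTable, trait: str,
                             z: float = 3.0) -> PhenotypeTable:
    """Set trait values strictly outside ±z SD of their per-sex mean to NA.

    Means and SDs are computed once on the input (per sex stratum); a
    stratum with fewer than two observations is an error.
    """
    if "sex" not in pheno.data.columns:
        raise ValueError("sex covariate required for phenotype outlier filter")
    out = pheno.data.copy()
    y = out[trait]
    for sex_val, grp in out.groupby("sex")[trait]:
        vals = grp.dropna()
        if len(vals) < 2:
            raise ValueError(f"sex stratum {sex_val!r} has <2 observations")
        mu, sd = vals.mean(), vals.std(ddof=1)
        outlier = (y.index.isin(grp.index)) & (np.abs(y - mu) > z * sd)
        out.loc[outlier, trait] = np.nan
    return PhenotypeTable(out, list(pheno.traits), list(pheno.covariates))


def ancestry_filter(projections, groups, k: int = 20, z: float = 3.0,
                    min_group_size: int = 1000):
    """Within-group PCA-outlier removal plus small-group exclusion.

    ``projections``: (n x >=k) array/DataFrame of PC projections;
    ``groups``: length-n labels.  A sample is retained iff its group has at
    least ``min_group_size`` members and every one of its leading ``k``
    projections lies within ``z`` group SDs of the group mean.
    Returns (keep mask, per-group summary DataFrame).
    """
    proj = np.asarray(projections, dtype=float)
    if proj.ndim != 2 or proj.shape[1] < k:
        raise ValueError(f"need at least k={k} components, have {proj.shape}")
    groups = pd.Series(list(groups))
    keep = np.zeros(len(groups), dtype=bool)
    rows = []
    for label, idx in groups.groupby(groups).groups.items():
        idx = np.asarray(idx)
        if len(idx) < min_group_size:
            rows.append({"group": label, "n": len(idx), "dropped_group": True,
                         "outliers": 0})
            continue
        sub = proj[idx, :k]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd = np.where(sd > 0, sd, np.inf)  # constant PC: nothing is an outlier
        ok = (np.abs(sub - mu) <= z * sd).all(axis=1)
        keep[idx[ok]] = True
        rows.append({"group": label, "n": len(idx), "dropped_group": False,
                     "outliers": int((~ok).sum())})
    return keep, pd.DataFrame(rows)


def relatedness_split(kinship, ids=None, threshold: float = 0.0625):
    """Split samples into an unrelated core and a related validation group.

    Greedy: repeatedly drop the sample with the most above-threshold
    partners (ties: larger maximum kinship, then identifier order) until no
    retained pair exceeds ``threshold``.  Dropped samples keeping at least
    one above-threshold link to the retained set form the related group.
    """
    K = np.asarray(getattr(kinship, "values", kinship), dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kinship matrix must be square")
    n = K.shape[0]
    if ids is None:
        ids = getattr(kinship, "ids", None)
    ids = np.asarray([str(i) for i in ids]) if ids is not None \
        else np.char.mod("%d", np.arange(n))

    adj = K > threshold
    np.fill_diagonal(adj, False)
    active = np.ones(n, dtype=bool)
    removed = []
    order = np.argsort(ids, kind="stable")  # identifier-order tie-break
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    while True:
        deg = (adj & active[None, :]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        cand = np.flatnonzero(deg == deg.max())
        if len(cand) > 1:
            kmax = np.where(adj[cand] & active[None, :], K[cand], -np.inf).max(axis=1)
            cand = cand[kmax == kmax.max()]
        drop = cand[np.argmin(rank[cand])]
        active[drop] = False
        removed.append(drop)

    removed = np.asarray(removed, dtype=int)
    related = [i for i in removed if (adj[i] & active).any()]
    return ids[active], ids[np.asarray(related, dtype=int)] if related else ids[:0]
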