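"""GWAS scan, LD clumping and p-value-threshold prediction profiles.

The clump+threshold (C+T) predictor is the classical baseline against
which joint SNP-BLUP prediction is compared: estimate each SNP's marginal
effect by OLS, reduce to approximately independent index SNPs by greedy
clumping (r^2 > 0.05 within 1 Mb absorbed), then score with index SNPs
passing each p-value threshold in turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GenotypeMatrix
from .mlm import SNPEffectSet
from .scoring import accuracy, adjust_phenotype, polygenic_score

#: Default p-value grid, spanning genome-wide significance to "all SNPs in".
DEFAULT_THRESHOLDS = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)

_P_FLOOR = 1e-300  # underflow guard for perfect fits


@dataclass
class GWASSummary:
    """Per-variant marginal OLS estimates on the standardized-genotype scale."""

    table: pd.DataFrame  # columns: id, chrom, pos, a1, beta, se, p, maf
    n: int

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy()


@dataclass
class ClumpSet:
    """Greedily selected index variants and the variants they absorbed."""

    index: pd.DataFrame              # id, chrom, pos, p (ascending p)
    members: dict = field(default_factory=dict)  # index id -> absorbed ids


def gwas_scan(y, covariates, gm: GenotypeMatrix, *,
              pcs: np.ndarray | None = None) -> GWASSummary:
    """Per-SNP OLS of y on intercept + covariates (+ optional PCs) + genotype.

    Genotypes are standardized with mean imputation of missing calls.
    Implemented by residualizing phenotype and genotypes on the nuisance
    design (Frisch-Waugh), which reproduces the joint OLS coefficient and
    its t-test exactly.  Constant genotype columns get effect 0, p = 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if not np.isfinite(y).all():
        raise ValueError("phenotype must be complete for the scan")
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    X = np.column_stack([np.ones(n), C] + ([pcs] if pcs is not None else []))
    p_cov = X.shape[1]

    counts = gm.counts.astype(float)
    counts[gm.missing_mask()] = np.nan
    mu = np.nanmean(counts, axis=0)
    sd = np.nanstd(counts, axis=0, ddof=0)
    constant = ~(sd > 0)
    sd_safe = np.where(constant, 1.0, sd)
    Z = np.where(np.isnan(counts), 0.0, (counts - mu) / sd_safe)

    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    Z_res = Z - Q @ (Q.T @ Z)

    zz = (Z_res ** 2).sum(axis=0)
    zz_safe = np.where(zz > 0, zz, 1.0)
    beta = (Z_res.T @ y_res) / zz_safe
    df = n - p_cov - 1
    rss = (y_res ** 2).sum() - beta ** 2 * zz_safe
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / df / zz_safe)
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = np.clip(2.0 * sps.t.sf(np.abs(tstat), df), _P_FLOOR, 1.0)
    beta[constant | (zz == 0)] = 0.0
    se[constant | (zz == 0)] = np.nan
    pvals[constant | (zz == 0)] = 1.0

    table = pd.DataFrame({
        "id": gm.variants["id"].to_numpy(),
        "chrom": gm.variants["chrom"].to_numpy(),
        "pos": gm.variants["pos"].to_numpy(),
        "a1": gm.variants["a1"].to_numpy(),
        "beta": beta, "se": se, "p": pvals,
        "maf": gm.maf(),
        "mean": mu, "sd": sd_safe,
        "flagged": constant | (zz == 0),
    })
    return GWASSummary(table, n=n)


def clump(summary: GWASSummary, gm: GenotypeMatrix, *, r2: float = 0.05,
          window_bp: int = 1_000_000) -> ClumpSet:
    """PLINK-style greedy clumping by ascending p-value.

    The best remaining SNP becomes an index; unassigned SNPs on the same
    chromosome within ``window_bp`` whose genotype r^2 with it exceeds
    ``r2`` (strict) are absorbed.  Ties on p break by position then id.
    """
    tab = summary.table
    order_tab = tab.sort_values(["p", "pos", "id"], kind="stable")
    idx_of = pd.Index(gm.variants["id"]).get_indexer(tab["id"])
    if (idx_of < 0).any():
        raise ValueError("summary contains variants absent from genotypes")

    counts = gm.counts.astype(float)
    counts[gm.missing_mask()] = np.nan
    col_mean = np.nanmean(counts, axis=0)
    filled = np.where(np.isnan(counts), col_mean, counts)
    filled -= filled.mean(axis=0)
    norm = np.sqrt((filled ** 2).sum(axis=0))
    norm[norm == 0] = np.inf
    filled /= norm

    assigned = pd.Series(False, index=tab["id"].to_numpy())
    chrom = tab.set_index("id")["chrom"]
    pos = tab.set_index("id")["pos"]
    gcol = dict(zip(tab["id"], idx_of))

    index_rows, members = [], {}
    for _, row in order_tab.iterrows():
        vid = row["id"]
        if assigned[vid]:
            continue
        assigned[vid] = True
        index_rows.append({"id": vid, "chrom": row["chrom"], "pos": row["pos"],
                           "p": row["p"]})
        near = tab.index[(~assigned.to_numpy())
                         & (chrom.to_numpy() == row["chrom"])
                         & (np.abs(pos.to_numpy() - row["pos"]) <= window_bp)]
        if len(near) == 0:
            members[vid] = []
            continue
        cand_ids = tab.loc[near, "id"].to_numpy()
        cols = np.array([gcol[c] for c in cand_ids])
        rvec = filled[:, cols].T @ filled[:, gcol[vid]]
        absorb = cand_ids[rvec ** 2 > r2]
        assigned[absorb] = True
        members[vid] = list(absorb)

    return ClumpSet(pd.DataFrame(index_rows), members)


def threshold_profile(clumps: ClumpSet, summary: GWASSummary,
                      gm_valid: GenotypeMatrix, pheno_valid, trait: str,
                      covariates=("sex", "age"),
                      thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """C+T accuracy per p-value threshold on a validation cohort.

    Scores use index SNPs with p <= threshold, GWAS betas as effects, and
    training standardization statistics.  A threshold passing zero SNPs is
    recorded with r = NaN (undefined, not zero) and flagged.
    """
    thresholds = sorted(thresholds)
    stab = summary.table.set_index("id")
    data = pheno_valid.data.loc[gm_valid.samples["iid"]]
    mask = data[trait].notna().to_numpy()
    adj = adjust_phenotype(data.loc[mask, trait],
                           data.loc[mask, list(covariates)])

    rows = []
    for thr in thresholds:
        use = clumps.index.loc[clumps.index["p"] <= thr, "id"]
        if len(use) == 0:
            rows.append({"threshold": thr, "n_snps": 0, "r": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "flagged": "no SNPs pass"})
            continue
        sel = stab.loc[use]
        eff = SNPEffectSet(pd.DataFrame({
            "id": sel.index, "a1": sel["a1"].to_numpy(),
            "effect": sel["beta"].to_numpy(),
            "mean": sel["mean"].to_numpy(), "sd": sel["sd"].to_numpy(),
            "component": "gwas",
        }), description=f"C+T threshold {thr:g}")
        scores = polygenic_score(gm_valid, eff)
        res = accuracy(scores.to_numpy()[mask], adj, trait=trait,
                       group=f"p<={thr:g}")
        rows.append({"threshold": thr, "n_snps": int(len(use)), "r": res.r,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "flagged": ""})
    return pd.DataFrame(rows)
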