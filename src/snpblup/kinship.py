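"""Genotype standardization, genomic relationships, PCA, LD pruning.

The standardized genotype z_ij = (s_ij - mu*_j) / sigma*_j uses the
*training* mean and population SD of counted-allele copies; missing
genotypes are mean-imputed (z = 0).  The genomic relationship matrix is
K = Z Z^T / M, whose entries estimate genomic relatedness (sibs ~ 0.5,
unrelated ~ 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix


@dataclass
class StandardizationStats:
    """Per-variant training mean and SD of counted-allele copies."""

    table: pd.DataFrame  # columns: id, a1, mean, sd

    def __post_init__(self) -> None:
        if (self.table["sd"] <= 0).any():
            bad = self.table.loc[self.table["sd"] <= 0, "id"].tolist()
            raise ValueError(f"non-positive training SD for variants: {bad}")


@dataclass
class KinshipMatrix:
    values: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray([str(i) for i in self.ids])
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship dimensions do not match ids")

    def submatrix(self, iids) -> "KinshipMatrix":
        pos = pd.Index(self.ids).get_indexer([str(i) for i in iids])
        if (pos < 0).any():
            raise KeyError("unknown ids in kinship submatrix request")
        return KinshipMatrix(self.values[np.ix_(pos, pos)], self.ids[pos])


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # nonincreasing, length k
    projections: np.ndarray          # (n x k), sqrt(n)-scaled singular vectors
    ids: np.ndarray


def standardize(gm: GenotypeMatrix, stats: StandardizationStats | None = None,
                *, allele_policy: str = "error", dtype=np.float64
                ) -> tuple[np.ndarray, StandardizationStats]:
    """Standardize counted-allele copies; mean-impute missing entries.

    With ``stats`` supplied (scoring a validation cohort) variants are
    matched by id; a flipped counted allele is an error under
    ``allele_policy='error'`` or is reconciled by s -> 2 - s under
    ``allele_policy='flip'``.  Without ``stats``, the mean and *population*
    SD (ddof=0, missing excluded) are computed from the input and returned;
    monomorphic variants are rejected with their ids listed.
    """
    counts = gm.counts.astype(dtype)
    miss = gm.missing_mask()
    counts[miss] = np.nan

    if stats is None:
        mu = np.nanmean(counts, axis=0)
        sd = np.nanstd(counts, axis=0, ddof=0)
        mono = ~(sd > 0)
        if mono.any():
            raise ValueError(
                "monomorphic variants cannot be standardized: "
                f"{gm.variants.loc[mono, 'id'].tolist()[:20]}")
        stats = StandardizationStats(pd.DataFrame({
            "id": gm.variants["id"].to_numpy(),
            "a1": gm.variants["a1"].to_numpy(),
            "mean": mu, "sd": sd,
        }))
    else:
        t = stats.table.set_index("id")
        pos = pd.Index(t.index).get_indexer(gm.variants["id"])
        if (pos < 0).any():
            missing = gm.variants.loc[pos < 0, "id"].tolist()[:20]
            raise ValueError(f"no training statistics for variants: {missing}")
        t = t.iloc[pos]
        flipped = (t["a1"].to_numpy() != gm.variants["a1"].to_numpy())
        if flipped.any():
            if allele_policy == "flip":
                counts[:, flipped] = 2.0 - counts[:, flipped]
            else:
                bad = gm.variants.loc[flipped, "id"].tolist()[:20]
                raise ValueError(f"counted-allele mismatch for variants: {bad}")
        mu = t["mean"].to_numpy()
        sd = t["sd"].to_numpy()

    z = (counts - mu) / sd
    z[np.isnan(z)] = 0.0
    return z.astype(dtype, copy=False), stats


def compute_grm(z: np.ndarray, ids=None) -> KinshipMatrix:
    """K = Z Z^T / M over standardized genotypes."""
    z = np.asarray(z)
    n, m = z.shape
    if m == 0:
        raise ValueError("cannot compute a GRM from zero variants")
    k = (z @ z.T) / m
    k = np.asarray((k + k.T) / 2.0, dtype=float)  # enforce exact symmetry
    if ids is None:
        ids = np.char.mod("%d", np.arange(n))
    return KinshipMatrix(k, ids)


def pca_from_grm(kin: KinshipMatrix, k: int) -> PCAResult:
    n = kin.values.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds available components ({n - 1})")
    w, v = np.linalg.eigh(kin.values)
    order = np.argsort(w)[::-1][:k]
    w = np.maximum(w[order], 0.0)
    v = v[:, order]
    # deterministic sign: largest-magnitude entry of each component positive
    for j in range(k):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    return PCAResult(eigenvalues=w, projections=np.sqrt(n) * v, ids=kin.ids)


def pca(z: np.ndarray, k: int, ids=None) -> PCAResult:
    """PCA of standardized (LD-pruned) genotypes via the GRM spectrum.

    Projections are the sqrt(n)-scaled leading eigenvectors of ZZ^T/M
    (equivalently scaled left singular vectors of Z) with a deterministic
    sign convention; eigenvalues are nonincreasing and nonnegative.
    """
    return pca_from_grm(compute_grm(z, ids=ids), k)


def ld_prune(gm: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.2) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns the kept boolean mask.

    Within each window (per chromosome), while any surviving pair has
    genotype r^2 > ``r2_max``, the member of the worst pair with the lower
    MAF is dropped (ties: later position).  Deterministic by construction.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must lie in (0, 1]")
    counts = gm.counts.astype(float)
    counts[gm.missing_mask()] = np.nan
    col_mean = np.nanmean(counts, axis=0)
    filled = np.where(np.isnan(counts), col_mean, counts)
    filled -= filled.mean(axis=0)
    norm = np.sqrt((filled ** 2).sum(axis=0))
    norm[norm == 0] = np.inf  # constant columns correlate with nothing
    filled /= norm

    maf = gm.maf()
    pos = gm.variants["pos"].to_numpy()
    keep = np.ones(gm.n_variants, dtype=bool)

    for chrom in pd.unique(gm.variants["chrom"]):
        idx = np.flatnonzero((gm.variants["chrom"] == chrom).to_numpy())
        for start in range(0, len(idx), step):
            win = idx[start:start + window]
            if len(win) < 2:
                continue
            live = win[keep[win]]
            while len(live) > 1:
                sub = filled[:, live]
                r2 = (sub.T @ sub) ** 2
                np.fill_diagonal(r2, 0.0)
                worst = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[worst] <= r2_max:
                    break
                a, b = live[worst[0]], live[worst[1]]
                if maf[a] < maf[b]:
                    drop = a
                elif maf[b] < maf[a]:
                    drop = b
                else:
                    drop = a if pos[a] > pos[b] else b
                keep[drop] = False
                live = win[keep[win]]
            if start + window >= len(idx):
                break
    return keep
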