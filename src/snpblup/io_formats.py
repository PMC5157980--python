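"""Genotype, phenotype and SNP-effect file I/O.

Genotypes travel as PLINK 1 binary triplets (``.bed``/``.bim``/``.fam``,
SNP-major), phenotypes and covariates as headered TSV, and fitted SNP
effects as a TSV "scoring file" carrying, per variant, the counted allele,
the effect on the standardized-genotype scale and the training
standardization statistics (mean and SD of counted-allele copies).  All
three formats round-trip exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: In-memory sentinel for a missing allele count.  Never used in arithmetic;
#: every consumer masks or mean-imputes before computing.
MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK codes (per byte, LSB first): 00 = 2 copies of allele1,
# 10 = 1 copy, 11 = 0 copies, 01 = missing.
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


@dataclass
class GenotypeMatrix:
    """Allele-count matrix with variant and sample metadata.

    ``counts[i, j]`` is the number of copies of the counted allele
    (``variants.a1``) carried by sample ``i`` at variant ``j``; values are
    0, 1, 2 or :data:`MISSING`.
    """

    counts: np.ndarray
    variants: pd.DataFrame  # columns: chrom, pos, id, a1, a2
    samples: pd.DataFrame   # columns: iid, sex, platform, population, family

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x variants)")
        n, m = self.counts.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError("metadata dimensions do not match counts")
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant identifiers")
        if self.samples["iid"].duplicated().any():
            raise ValueError("duplicate sample identifiers")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.counts == MISSING

    def allele_frequency(self) -> np.ndarray:
        """Per-variant frequency of the counted allele (missing excluded)."""
        miss = self.missing_mask()
        called = (~miss).sum(axis=0)
        total = np.where(miss, 0, self.counts).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, total / (2.0 * called), np.nan)

    def maf(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def variant_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        """Return a copy restricted to boolean/index selections."""
        srows = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        if srows.dtype == bool:
            srows = np.flatnonzero(srows)
        vcols = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        if vcols.dtype == bool:
            vcols = np.flatnonzero(vcols)
        return GenotypeMatrix(
            counts=self.counts[np.ix_(srows, vcols)].copy(),
            variants=self.variants.iloc[vcols].reset_index(drop=True),
            samples=self.samples.iloc[srows].reset_index(drop=True),
        )

    def select_samples(self, iids) -> "GenotypeMatrix":
        pos = pd.Index(self.samples["iid"]).get_indexer(list(iids))
        if (pos < 0).any():
            raise KeyError("unknown sample identifiers requested")
        return self.subset(samples=pos)


@dataclass
class PhenotypeTable:
    """Trait values and covariates, one row per sample (NaN = missing)."""

    data: pd.DataFrame  # indexed by iid
    traits: list = field(default_factory=list)
    covariates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample identifiers in phenotype table")
        missing_cols = [c for c in list(self.traits) + list(self.covariates)
                        if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"phenotype table lacks columns: {missing_cols}")

    def loc(self, iids) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(iids)].copy(),
                              list(self.traits), list(self.covariates))


# ---------------------------------------------------------------------------
# PLINK binary triplet
# ---------------------------------------------------------------------------

def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major, padding bits zeroed)."""
    prefix = Path(prefix)
    n, m = gm.counts.shape
    if n == 0 or m == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    if gm.variants["id"].duplicated().any():
        raise ValueError("duplicate variant ids")

    codes = np.empty_like(gm.counts, dtype=np.uint8)
    for count, code in _COUNT_TO_CODE.items():
        codes[gm.counts == count] = code

    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T  # pad codes are 0b00; harmless, ignored on read
    packed = (padded[:, 0::4]
              | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4)
              | (padded[:, 3::4] << 6)).astype(np.uint8)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())

    bim = pd.DataFrame({
        "chrom": gm.variants["chrom"],
        "id": gm.variants["id"],
        "cm": 0,
        "pos": gm.variants["pos"],
        "a1": gm.variants["a1"],
        "a2": gm.variants["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    s = gm.samples
    fam = pd.DataFrame({
        "fid": (s["family"].fillna("").replace("", "0")
                if "family" in s else "0"),
        "iid": s["iid"],
        "father": "0",
        "mother": "0",
        "sex": s["sex"].fillna(0).astype(int) if "sex" in s else 0,
        "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK triplet written by :func:`write_plink` or PLINK itself."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError("not a PLINK .bed file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise FormatError("sample-major .bed unsupported")
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != n_bytes * m:
        raise FormatError(
            f"truncated .bed payload: expected {n_bytes * m} bytes, "
            f"found {payload.size}")

    packed = payload.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = packed & 0b11
    codes[:, 1::4] = (packed >> 2) & 0b11
    codes[:, 2::4] = (packed >> 4) & 0b11
    codes[:, 3::4] = (packed >> 6) & 0b11
    counts = _CODE_TO_COUNT[codes[:, :n]].T

    samples = pd.DataFrame({
        "iid": fam["iid"].astype(str),
        "sex": fam["sex"].astype(int),
        "platform": pd.NA,
        "population": pd.NA,
        "family": fam["fid"].astype(str),
    })
    variants = bim[["chrom", "pos", "id", "a1", "a2"]].copy()
    return GenotypeMatrix(counts=counts, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# Phenotype / covariate TSV
# ---------------------------------------------------------------------------

_REQUIRED_PHENO_COLS = ("iid",)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    out = pheno.data.copy()
    out.insert(0, "iid", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path, traits=None, covariates=("sex", "age")) -> PhenotypeTable:
    """Read a headered TSV; "NA" marks missing trait values.

    ``traits=None`` treats every non-covariate, non-identifier column as a
    trait.  Unknown requested columns raise; extra file columns warn.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"iid": str})
    for col in _REQUIRED_PHENO_COLS:
        if col not in df.columns:
            raise FormatError(f"phenotype file lacks required column '{col}'")
    df = df.set_index("iid")
    covariates = [c for c in covariates if c in df.columns]
    if traits is None:
        traits = [c for c in df.columns if c not in covariates]
    else:
        absent = [t for t in traits if t not in df.columns]
        if absent:
            raise FormatError(f"phenotype file lacks trait columns: {absent}")
        extra = [c for c in df.columns if c not in list(traits) + covariates]
        if extra:
            warnings.warn(f"ignoring unknown phenotype columns: {extra}")
    return PhenotypeTable(df, list(traits), list(covariates))


# ---------------------------------------------------------------------------
# SNP-effect scoring file
# ---------------------------------------------------------------------------

_EFFECT_COLS = ["id", "a1", "effect", "mean", "sd", "component"]


def write_effects(effects, path) -> None:
    """Write a scoring file.  Accepts an SNPEffectSet or its table."""
    table = getattr(effects, "table", effects)
    table = table[_EFFECT_COLS] if all(c in table for c in _EFFECT_COLS) else table
    table.to_csv(path, sep="\t", index=False)


def read_effects(path):
    """Read a scoring file back into an :class:`~snpblup.mlm.SNPEffectSet`."""
    from .mlm import SNPEffectSet  # deferred: mlm does not import io_formats

    table = pd.read_csv(path, sep="\t", dtype={"id": str, "a1": str})
    required = {"id", "a1", "effect", "mean", "sd"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"scoring file lacks columns: {sorted(missing)}")
    if "component" not in table.columns:
        table["component"] = "all"
    if (table["sd"] <= 0).any():
        bad = table.loc[table["sd"] <= 0, "id"].tolist()
        raise FormatError(f"scoring file has non-positive training SD for: {bad}")
    if not np.isfinite(table["effect"]).all():
        raise FormatError("scoring file contains non-finite effects")
    return SNPEffectSet(table=table, description=f"read from {path}")
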