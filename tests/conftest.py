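"""Shared fixtures: tiny deterministic genotype matrices and cohorts."""

import numpy as np
import pandas as pd
import pytest

from snpblup.io_formats import GenotypeMatrix, PhenotypeTable
from snpblup.simdata import (SyntheticCohortConfig, TraitArchitecture,
                             generate_cohort)


def make_gm(counts, chrom=None, pos=None, sex=None, platform=None,
            population=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw count array with default metadata."""
    counts = np.asarray(counts, dtype=np.int8)
    n, m = counts.shape
    variants = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "id": [f"snp{j}" for j in range(m)],
        "a1": ["A"] * m,
        "a2": ["G"] * m,
    })
    samples = pd.DataFrame({
        "iid": [f"s{i:03d}" for i in range(n)],
        "sex": sex if sex is not None else [1, 2] * (n // 2) + [1] * (n % 2),
        "platform": platform if platform is not None else pd.NA,
        "population": population if population is not None else "POP",
        "family": "",
    })
    return GenotypeMatrix(counts, variants, samples)


@pytest.fixture(scope="session")
def small_cohort():
    """500 samples x 400 unlinked SNPs, one trait at h2=0.5 (seeded)."""
    cfg = SyntheticCohortConfig(
        n_samples={"EUR": 500}, n_variants=400, n_chromosomes=4,
        ld_block_size=10, within_block_r=0.0, maf_low=0.05, maf_high=0.5,
        trait_architectures=[TraitArchitecture("t1", 0.5, 400)],
        sex_effects=(0.5,), age_effects=(0.01,), seed=11)
    gm, pheno, truth = generate_cohort(cfg)
    return cfg, gm, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
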