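"""Synthetic cohort generator: frequencies, LD, relatives, traits."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from snpblup.io_formats import MISSING
from snpblup.simdata import (SyntheticCohortConfig, TraitArchitecture,
                             apply_missingness, assemble_phenotypes,
                             draw_allele_frequencies, draw_genotypes,
                             draw_snp_effects, generate_cohort,
                             spike_relatives)


def _cfg(**kw):
    base = dict(
        n_samples={"A": 100}, n_variants=200, n_chromosomes=2,
        ld_block_size=10, within_block_r=0.0, maf_low=0.05, maf_high=0.5,
        trait_architectures=[TraitArchitecture("t1", 0.5, 100)], seed=1)
    base.update(kw)
    return SyntheticCohortConfig(**base)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def test_fst_zero_copies_ancestral(rng):
    cfg = _cfg(n_samples={"A": 10, "B": 10}, fst={"B": 0.0})
    freqs = draw_allele_frequencies(cfg, rng)
    np.testing.assert_array_equal(freqs["B"], freqs["ancestral"])


def test_fst_one_rejected():
    with pytest.raises(ValueError, match="fst"):
        _cfg(n_samples={"A": 10, "B": 10}, fst={"B": 1.0})


def test_balding_nichols_variance(rng):
    """Across-SNP variance of drifted frequencies ~ fst * p(1-p)."""
    cfg = _cfg(n_samples={"A": 10, "B": 10}, fst={"B": 0.1},
               n_variants=10000, n_chromosomes=10, maf_low=0.3,
               maf_high=0.30001)
    freqs = draw_allele_frequencies(cfg, rng)
    var = (freqs["B"] - freqs["ancestral"]).var()
    assert var == pytest.approx(0.1 * 0.3 * 0.7, rel=0.1)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def test_unlinked_genotype_moments(rng):
    cfg = _cfg(n_samples={"A": 10000}, n_variants=20, n_chromosomes=2,
               within_block_r=0.0, maf_low=0.4999, maf_high=0.5,
               trait_architectures=[TraitArchitecture("t1", 0.5, 20)])
    freqs = draw_allele_frequencies(cfg, rng)
    gm = draw_genotypes(freqs, cfg, rng)
    assert gm.counts.mean() == pytest.approx(1.0, abs=0.03)
    assert gm.counts.var() == pytest.approx(0.5, abs=0.03)
    corr = np.corrcoef(gm.counts.T)
    off = corr[~np.eye(20, dtype=bool)]
    assert np.abs(off).max() < 0.05


def test_perfect_ld_identical_adjacent(rng):
    cfg = _cfg(within_block_r=1.0, maf_low=0.3, maf_high=0.30001)
    freqs = draw_allele_frequencies(cfg, rng)
    gm = draw_genotypes(freqs, cfg, rng)
    block = gm.counts[:, :10]                  # one LD block, equal freqs
    assert (block == block[:, [0]]).all()


def test_intermediate_ld_tracks_target(rng):
    cfg = _cfg(n_samples={"A": 5000}, within_block_r=0.6, maf_low=0.45,
               maf_high=0.5, n_variants=100, n_chromosomes=1)
    freqs = draw_allele_frequencies(cfg, rng)
    gm = draw_genotypes(freqs, cfg, rng)
    rs = [np.corrcoef(gm.counts[:, j], gm.counts[:, j + 1])[0, 1]
          for j in range(0, 99) if (j % 10) != 9]  # adjacent within block
    assert np.mean(rs) == pytest.approx(0.6, abs=0.07)


def test_unrelated_grm_concentrates_near_zero(small_cohort):
    from snpblup.kinship import compute_grm, standardize
    _, gm, _, _ = small_cohort
    z, _ = standardize(gm)
    off = compute_grm(z).values[~np.eye(gm.n_samples, dtype=bool)]
    assert np.abs(off).mean() < 0.1


# ---------------------------------------------------------------------------
# Relatives
# ---------------------------------------------------------------------------

def test_sibs_share_half_genome(rng):
    cfg = _cfg(n_samples={"A": 200}, n_variants=5000, n_chromosomes=5,
               maf_low=0.1)
    gm, _, _ = generate_cohort(cfg)
    gm2 = spike_relatives(gm, 50, rng)
    from snpblup.kinship import compute_grm, standardize
    z, _ = standardize(gm2)
    kin = compute_grm(z)
    fams = gm2.samples["family"].to_numpy()
    vals = [kin.values[tuple(np.flatnonzero(fams == f))]
            for f in np.unique(fams[fams != ""])]
    assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


def test_zero_pairs_no_family_labels(rng):
    cfg = _cfg()
    gm, _, _ = generate_cohort(cfg)
    assert (gm.samples["family"] == "").all()


def test_reused_parents_make_related_quartet(rng):
    cfg = _cfg(n_samples={"A": 100}, n_variants=4000, n_chromosomes=4,
               maf_low=0.1)
    gm, _, _ = generate_cohort(cfg)
    gm2 = spike_relatives(gm, 0, rng, parent_pairs=[(0, 1), (0, 1)])
    from snpblup.kinship import compute_grm, standardize
    z, _ = standardize(gm2)
    kin = compute_grm(z)
    sibs = np.arange(100, 104)                 # 4 offspring of the same parents
    sub = kin.values[np.ix_(sibs, sibs)]
    off = sub[~np.eye(4, dtype=bool)]
    assert (off > 0.0625).all()


def test_insufficient_parents_rejected(rng):
    cfg = _cfg(n_samples={"A": 10})
    gm, _, _ = generate_cohort(cfg)
    with pytest.raises(ValueError, match="insufficient"):
        spike_relatives(gm, 8, rng)


# ---------------------------------------------------------------------------
# SNP effects
# ---------------------------------------------------------------------------

def test_uncorrelated_effects_independent(rng):
    archs = [TraitArchitecture("a", 0.5, 10000),
             TraitArchitecture("b", 0.5, 10000)]
    eff = draw_snp_effects(archs, 10000, np.full(10000, 0.3), np.eye(2), rng)
    r = np.corrcoef(eff["a"], eff["b"])[0, 1]
    assert abs(r) < 0.05


def test_genetic_correlation_recovered(rng):
    corr = np.array([[1.0, 0.5], [0.5, 1.0]])
    archs = [TraitArchitecture("a", 0.5, 10000),
             TraitArchitecture("b", 0.5, 10000)]
    eff = draw_snp_effects(archs, 10000, np.full(10000, 0.3), corr, rng)
    r = np.corrcoef(eff["a"], eff["b"])[0, 1]
    assert r == pytest.approx(0.5, abs=0.02)


def test_zero_tail_fraction_reduces_to_gaussian(rng):
    arch_two = [TraitArchitecture("t", 0.5, 10000,
                                  effect_model="two_component",
                                  tail_fraction=0.0,
                                  tail_variance_ratio=100.0)]
    arch_one = [TraitArchitecture("t", 0.5, 10000)]
    mafs = np.full(10000, 0.3)
    e1 = draw_snp_effects(arch_two, 10000, mafs, np.eye(1),
                          np.random.default_rng(4))["t"]
    e2 = draw_snp_effects(arch_one, 10000, mafs, np.eye(1),
                          np.random.default_rng(5))["t"]
    assert scipy.stats.ks_2samp(e1, e2).pvalue > 0.01


def test_two_component_tail_inflation(rng):
    arch = [TraitArchitecture("t", 0.5, 10000, effect_model="two_component",
                              tail_fraction=0.01, tail_variance_ratio=100.0)]
    eff = draw_snp_effects(arch, 10000, np.full(10000, 0.3), np.eye(1),
                           rng)["t"].to_numpy()
    # ~1% of SNPs carry 10x-SD effects: excess kurtosis is unmistakable
    assert scipy.stats.kurtosis(eff[eff != 0]) > 5


def test_noncausal_exactly_zero(rng):
    archs = [TraitArchitecture("t", 0.5, 50)]
    eff = draw_snp_effects(archs, 200, np.full(200, 0.3), np.eye(1), rng)
    assert (eff["t"] == 0).sum() == 150


def test_non_psd_correlation_rejected(rng):
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])
    archs = [TraitArchitecture("a", 0.5, 10), TraitArchitecture("b", 0.5, 10)]
    with pytest.raises(ValueError, match="positive semidefinite"):
        draw_snp_effects(archs, 100, np.full(100, 0.3), bad, rng)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def test_h2_zero_phenotype_independent_of_genetics():
    cfg = _cfg(n_samples={"A": 2000}, n_variants=100, n_chromosomes=1,
               trait_architectures=[TraitArchitecture("t1", 0.0, 100)])
    gm, pheno, truth = generate_cohort(cfg)
    r = np.corrcoef(pheno.data["t1"],
                    gm.counts.astype(float) @ np.ones(100))[0, 1]
    assert abs(r) < 2 / np.sqrt(2000)
    assert truth.realized_h2["t1"] == 0.0


def test_h2_one_phenotype_equals_genetic_value():
    cfg = _cfg(trait_architectures=[TraitArchitecture("t1", 1.0, 100)],
               sex_effects=(0.5,), age_effects=(0.01,))
    gm, pheno, truth = generate_cohort(cfg)
    fixed = (pheno.data["sex"] * 0.5 + pheno.data["age"] * 0.01)
    np.testing.assert_allclose(pheno.data["t1"] - fixed,
                               truth.genetic_values["t1"], atol=1e-10)


def test_h2_one_without_causals_rejected(rng):
    cfg = _cfg(trait_architectures=[TraitArchitecture("t1", 1.0, 0)])
    gm, _, _ = generate_cohort(_cfg())
    eff = pd.DataFrame({"t1": np.zeros(200)})
    with pytest.raises(ValueError, match="causal"):
        assemble_phenotypes(gm, eff, cfg, rng)


def test_realized_h2_matches_target_at_scale():
    """Var explained by true genetic values hits the h2 dial (n=5000)."""
    cfg = _cfg(n_samples={"A": 5000}, n_variants=500, n_chromosomes=5,
               trait_architectures=[TraitArchitecture("t1", 0.5, 500)],
               sex_effects=(0.5,), age_effects=(0.01,), seed=77)
    gm, pheno, truth = generate_cohort(cfg)
    assert truth.realized_h2["t1"] == pytest.approx(0.5, abs=0.03)
    from snpblup.scoring import adjust_phenotype
    adj = adjust_phenotype(pheno.data["t1"],
                           pheno.data[["sex", "age"]])
    r2 = np.corrcoef(adj, truth.genetic_values["t1"])[0, 1] ** 2
    assert r2 == pytest.approx(0.5, abs=0.03)


def test_environmental_correlation_respected():
    corr = np.array([[1.0, 0.8], [0.8, 1.0]])
    cfg = _cfg(n_samples={"A": 4000}, n_variants=100, n_chromosomes=1,
               trait_architectures=[TraitArchitecture("a", 0.0, 0),
                                    TraitArchitecture("b", 0.0, 0)],
               environmental_correlation=corr, seed=13)
    _, pheno, _ = generate_cohort(cfg)
    r = np.corrcoef(pheno.data["a"], pheno.data["b"])[0, 1]
    assert r == pytest.approx(0.8, abs=0.05)


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def test_zero_rates_no_missing(rng):
    cfg = _cfg()
    gm, _, _ = generate_cohort(cfg)
    assert not gm.missing_mask().any()


def test_missing_rate_binomial(rng):
    cfg = _cfg(n_samples={"A": 1000}, n_variants=1000, n_chromosomes=1,
               platform_missing_rates=(0.01, 0.01))
    gm, _, _ = generate_cohort(cfg)
    assert gm.missing_mask().mean() == pytest.approx(0.01, abs=0.001)


def test_biased_variants_show_platform_differential(rng):
    cfg = _cfg(n_samples={"A": 2000}, n_variants=1000, n_chromosomes=1,
               platform_missing_rates=(0.0, 0.0),
               biased_variant_fraction=0.01, biased_missing_rate=0.5)
    gm, _, _ = generate_cohort(cfg)
    miss = gm.missing_mask()
    on_b = (gm.samples["platform"] == "B").to_numpy()
    biased = miss.any(axis=0)
    assert biased.sum() == 10
    assert miss[np.ix_(~on_b, biased)].sum() == 0   # bias hits platform B only
    rate_b = miss[np.ix_(on_b, biased)].mean()
    assert rate_b == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------

def test_same_seed_identical_cohort():
    cfg = _cfg(n_sib_pairs=5, platform_missing_rates=(0.01, 0.02))
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    np.testing.assert_array_equal(a[0].counts, b[0].counts)
    pd.testing.assert_frame_equal(a[1].data, b[1].data)
    pd.testing.assert_frame_equal(a[2].effects, b[2].effects)


def test_block_divisibility_enforced():
    with pytest.raises(ValueError, match="blocks"):
        _cfg(n_variants=205)
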