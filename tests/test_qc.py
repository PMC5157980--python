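"""Quality-control filters and exact tests."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from snpblup.io_formats import MISSING, PhenotypeTable
from snpblup.qc import (ancestry_filter, hwe_exact_test,
                        phenotype_outlier_filter, platform_missingness_test,
                        relatedness_split, sample_qc, variant_qc)

from conftest import make_gm


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_oracle(hom_minor, het, hom_major):
    """Independent exact-fraction enumeration of the conditional HWE test."""
    n = hom_minor + het + hom_major
    n_rare = 2 * hom_minor + het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    weights = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hr = (n_rare - h) // 2
        hc = n - hr - h
        weights[h] = Fraction(
            math.factorial(n) * 2 ** h,
            math.factorial(hr) * math.factorial(h) * math.factorial(hc))
    total = sum(weights.values())
    obs = weights[het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


@pytest.mark.parametrize("counts,expected", [
    ((0, 0, 10), 1.0),
    ((1, 0, 9), 10 / 190),       # enumeration: weights 10 and 180
    ((0, 2, 8), 1.0),            # observed configuration is the most probable
])
def test_hwe_worked_examples(counts, expected):
    assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)


def test_hwe_matches_enumeration_oracle(rng):
    """Exact agreement with a fraction-arithmetic oracle, totals <= 50."""
    for _ in range(300):
        n = int(rng.integers(1, 51))
        rare = int(rng.integers(0, 2 * n + 1))
        hets = list(range(rare % 2, min(rare, 2 * n - rare) + 1, 2))
        het = int(rng.choice(hets))
        hom_minor = (rare - het) // 2
        hom_major = n - hom_minor - het
        assert hwe_exact_test(hom_minor, het, hom_major) == pytest.approx(
            hwe_oracle(hom_minor, het, hom_major), abs=1e-12)


def test_hwe_input_validation():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 5)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# Platform Fisher test
# ---------------------------------------------------------------------------

def test_fisher_symmetry_and_unit_margin():
    assert platform_missingness_test(5, 95, 5, 95).p == 1.0
    assert platform_missingness_test(1, 9, 0, 10).p == pytest.approx(1.0)


def test_fisher_far_tail_finite_in_log_space():
    res = platform_missingness_test(2500, 2500, 0, 5000)
    assert np.isfinite(res.log10_p)
    assert res.log10_p < -100


def test_fisher_matches_scipy_on_moderate_tables(rng):
    for _ in range(50):
        a, b, c, d = rng.integers(0, 40, size=4)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        ours = platform_missingness_test(a, b, c, d).p
        ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_fisher_empty_table_rejected():
    with pytest.raises(ValueError):
        platform_missingness_test(0, 0, 0, 0)


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def test_variant_missingness_threshold(rng):
    counts = rng.integers(0, 3, size=(100, 3)).astype(np.int8)
    counts[:3, 1] = MISSING  # 3% missing at variant 1
    gm = make_gm(counts)
    out, rep = variant_qc(gm, min_maf=0.0, hwe_log10p=-np.inf)
    assert "snp1" not in set(out.variants["id"])
    stage = [s for s in rep.stages if s["filter"] == "variant_missingness"][0]
    assert stage["removed"] == 1 and stage["threshold"] == 0.02


def test_maf_exactly_at_boundary_removed():
    # counted-allele frequency exactly 0.05 in 10 samples: one het in 10
    counts = np.zeros((10, 2), dtype=np.int8)
    counts[0, 0] = 1                      # MAF 0.05 -> strict > 0.05 fails
    counts[:5, 1] = 1                     # MAF 0.25 -> retained
    gm = make_gm(counts)
    out, _ = variant_qc(gm, hwe_log10p=-np.inf)
    assert list(out.variants["id"]) == ["snp1"]


def test_clean_matrix_fully_retained(rng):
    counts = rng.integers(0, 3, size=(200, 8)).astype(np.int8)
    gm = make_gm(counts)
    out, _ = variant_qc(gm, min_maf=0.0, hwe_log10p=-np.inf)
    assert out.n_variants == 8


def test_variant_qc_idempotent(rng):
    counts = rng.integers(0, 3, size=(150, 10)).astype(np.int8)
    counts[rng.random((150, 10)) < 0.01] = MISSING
    gm = make_gm(counts)
    once, _ = variant_qc(gm)
    twice, _ = variant_qc(once)
    assert list(once.variants["id"]) == list(twice.variants["id"])


def test_variant_qc_threshold_validation(rng):
    gm = make_gm(rng.integers(0, 3, size=(10, 2)))
    with pytest.raises(ValueError):
        variant_qc(gm, max_missing=1.5)


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

def _cohort_with_x(rng, n=200, m_auto=60, m_x=40):
    counts = rng.integers(0, 3, size=(n, m_auto + m_x)).astype(np.int8)
    sex = np.where(rng.random(n) < 0.5, 1, 2)
    hap = (rng.random((n, m_x)) < 0.4).astype(np.int8)
    x_block = hap + (rng.random((n, m_x)) < 0.4).astype(np.int8)
    x_block[sex == 1] = 2 * hap[sex == 1]      # males homozygous on X
    counts[:, m_auto:] = x_block
    chrom = ["1"] * m_auto + ["23"] * m_x
    return make_gm(counts, chrom=chrom, sex=sex), sex


def test_sample_missingness_threshold(rng):
    gm, _ = _cohort_with_x(rng)
    counts = gm.counts.copy()
    counts[0, :6] = MISSING                     # 6% of 100 variants
    gm.counts = counts
    keep, rep = sample_qc(gm, sex_check=False)
    assert not keep[0]
    assert [s for s in rep.stages
            if s["filter"] == "sample_missingness"][0]["threshold"] == 0.05


def test_sex_mismatch_removed(rng):
    gm, sex = _cohort_with_x(rng)
    male = int(np.flatnonzero(sex == 1)[0])
    gm.samples.loc[male, "sex"] = 2             # male X coding, reported female
    keep, rep = sample_qc(gm)
    assert not keep[male]
    assert [s for s in rep.stages if s["filter"] == "sex_mismatch"][0][
        "removed"] >= 1


def test_clean_cohort_none_removed(rng):
    """No missingness or sex-mismatch removals on clean data.

    The +/-3 SD heterozygosity rule flags the empirical tail of any finite
    exchangeable cohort (expected ~0.3% of samples), so that stage is
    allowed a 3-SD-consistent handful.
    """
    gm, _ = _cohort_with_x(rng, n=300)
    keep, rep = sample_qc(gm)
    by_name = {s["filter"]: s for s in rep.stages}
    assert by_name["sample_missingness"]["removed"] == 0
    assert by_name["sex_mismatch"]["removed"] == 0
    assert by_name["heterozygosity_outlier"]["removed"] <= 3


def test_sex_check_without_x_block_errors(rng):
    gm = make_gm(rng.integers(0, 3, size=(20, 10)))
    with pytest.raises(ValueError, match="X-like"):
        sample_qc(gm, sex_check=True)


# ---------------------------------------------------------------------------
# Phenotype outliers
# ---------------------------------------------------------------------------

def _pheno(values, sexes):
    data = pd.DataFrame({"y": values, "sex": sexes, "age": 50},
                        index=[f"s{i}" for i in range(len(values))])
    return PhenotypeTable(data, ["y"], ["sex", "age"])


def test_phenotype_boundary_is_retained_strictly():
    base = [0.0, 1.0, -1.0, 2.0, -2.0] * 4
    vals = np.array(base, dtype=float)
    mu, sd = vals.mean(), vals.std(ddof=1)
    vals = np.append(vals, mu + 3 * sd)        # exactly at the boundary
    pheno = _pheno(vals, [1] * len(vals))
    out = phenotype_outlier_filter(pheno, "y")
    assert out.data["y"].notna().all()


def test_phenotype_outlier_removed_per_sex():
    vals = list(np.random.default_rng(1).normal(size=40)) + [25.0]
    pheno = _pheno(vals, [1, 2] * 20 + [1])
    out = phenotype_outlier_filter(pheno, "y")
    assert out.data["y"].isna().sum() == 1
    assert np.isnan(out.data["y"].iloc[-1])


def test_phenotype_degenerate_stratum_no_removal():
    pheno = _pheno([5.0] * 10, [1] * 10)
    out = phenotype_outlier_filter(pheno, "y")
    assert out.data["y"].notna().all()


def test_phenotype_small_stratum_errors():
    pheno = _pheno([1.0, 2.0, 3.0], [1, 1, 2])
    with pytest.raises(ValueError, match="stratum"):
        phenotype_outlier_filter(pheno, "y")


# ---------------------------------------------------------------------------
# Ancestry filter
# ---------------------------------------------------------------------------

def test_ancestry_all_identical_retained():
    proj = np.zeros((50, 20))
    keep, _ = ancestry_filter(proj, ["g"] * 50, min_group_size=10)
    assert keep.all()


def test_ancestry_displaced_sample_excluded(rng):
    proj = rng.standard_normal((200, 20))
    proj[7, 0] += 50.0                          # ~5 SD displacement on PC1
    keep, _ = ancestry_filter(proj, ["g"] * 200, min_group_size=10)
    assert not keep[7]
    assert keep.sum() >= 150


def test_ancestry_small_group_dropped(rng):
    proj = rng.standard_normal((999, 20))
    keep, summary = ancestry_filter(proj, ["small"] * 999,
                                    min_group_size=1000)
    assert not keep.any()
    assert summary.loc[0, "dropped_group"]


def test_ancestry_insufficient_components(rng):
    with pytest.raises(ValueError, match="k=20"):
        ancestry_filter(rng.standard_normal((10, 5)), ["g"] * 10)


# ---------------------------------------------------------------------------
# Relatedness split
# ---------------------------------------------------------------------------

def _kin(n, pairs, value=0.5):
    k = np.eye(n)
    for i, j in pairs:
        k[i, j] = k[j, i] = value
    return k


def test_relatedness_no_pairs_related_empty():
    unrel, rel = relatedness_split(_kin(6, []))
    assert len(unrel) == 6 and len(rel) == 0


def test_relatedness_single_sib_pair():
    unrel, rel = relatedness_split(_kin(6, [(0, 1)]))
    assert len(unrel) == 5 and len(rel) == 1


def test_relatedness_three_clique():
    k = _kin(6, [(0, 1), (0, 2), (1, 2)], value=0.3)
    unrel, rel = relatedness_split(k)
    assert len(unrel) == 4          # one clique member survives
    kept = [int(i) for i in unrel]
    sub = k[np.ix_(kept, kept)]
    np.fill_diagonal(sub, 0.0)
    assert sub.max() < 0.0625
    assert len(rel) == 2


def test_relatedness_postcondition_random_matrices(rng):
    for _ in range(100):
        n = int(rng.integers(3, 15))
        k = rng.random((n, n)) * 0.2
        k = (k + k.T) / 2
        np.fill_diagonal(k, 1.0)
        unrel, _ = relatedness_split(k)
        kept = [int(i) for i in unrel]
        sub = k[np.ix_(kept, kept)]
        np.fill_diagonal(sub, 0.0)
        assert sub.size == 0 or sub.max() <= 0.0625


def test_relatedness_non_square_rejected():
    with pytest.raises(ValueError):
        relatedness_split(np.zeros((3, 4)))
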