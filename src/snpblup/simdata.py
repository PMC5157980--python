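"""Synthetic cohort generator for genomic-prediction analyses.

Emulates the statistical structure the downstream pipeline assumes:
multiple ancestry groups with Balding-Nichols differentiated allele
frequencies, LD-blocked biallelic SNPs on a regular physical grid, a
spiked-in set of sibling pairs, two genotyping platforms with optional
platform-differential missingness, an X-like block (males hemizygous,
coded homozygous) for the sex-check filter, and additive trait
architectures with configurable SNP-heritability, effect-size mixtures,
MAF-coupled effect variances and cross-trait genetic/environmental
correlations.

LD within a block comes from a thresholded latent AR(1) Gaussian per
haplotype (a Gaussian copula).  The latent autocorrelation is set to
sin(pi * within_block_r / 2), which inverts the tetrachoric attenuation
exactly at allele frequency 0.5 and approximately elsewhere, so realized
adjacent-genotype correlation tracks ``within_block_r``.

Everything is driven by a single integer seed; the same seed reproduces
the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable

_BASES = np.array(list("ACGT"))


@dataclass
class TraitArchitecture:
    """Additive architecture of one trait.

    ``effect_model``:
      - ``single_gaussian``: causal effects i.i.d. normal.
      - ``two_component``: a ``tail_fraction`` of causal SNPs drawn with
        variance inflated by ``tail_variance_ratio``.
      - ``maf_stratified``: per-MAF-bin effect variance
        (``maf_bin_edges`` ascending, ``maf_bin_variances`` relative).
    """

    name: str
    h2_target: float
    n_causal: int
    effect_model: str = "single_gaussian"
    tail_fraction: float = 0.0
    tail_variance_ratio: float = 1.0
    maf_bin_edges: tuple = (0.001, 0.01, 0.05, 0.5)
    maf_bin_variances: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must lie in [0, 1]")
        if self.n_causal < 0:
            raise ValueError("n_causal must be nonnegative")
        if self.effect_model not in ("single_gaussian", "two_component",
                                     "maf_stratified"):
            raise ValueError(f"unknown effect model {self.effect_model!r}")
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise ValueError("tail_fraction must lie in [0, 1]")


@dataclass
class SyntheticCohortConfig:
    """Full description of a synthetic cohort (the stated world).

    ``n_samples`` maps population label -> count; the first label is the
    reference population whose allele frequencies are ancestral.  ``fst``
    maps each non-reference population to its Balding-Nichols divergence.
    """

    n_samples: dict
    n_variants: int
    trait_architectures: list
    n_chromosomes: int = 10
    ld_block_size: int = 10
    within_block_r: float = 0.6
    maf_low: float = 0.01
    maf_high: float = 0.5
    maf_beta: tuple | None = None   # optional (a, b) Beta shape on [maf_low, maf_high]
    fst: dict = field(default_factory=dict)
    n_sib_pairs: int = 0
    platform_missing_rates: tuple = (0.0, 0.0)
    biased_variant_fraction: float = 0.0
    biased_missing_rate: float = 0.25
    genetic_correlation: np.ndarray | None = None
    environmental_correlation: np.ndarray | None = None
    sex_effects: tuple = ()
    age_effects: tuple = ()
    age_range: tuple = (40, 70)
    position_spacing: int = 1000
    x_variants: int = 0
    x_chrom: str = "23"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.trait_architectures:
            raise ValueError("at least one trait architecture required")
        if self.n_variants % (self.n_chromosomes * self.ld_block_size):
            raise ValueError("n_variants must divide into whole LD blocks "
                             "per chromosome")
        for pop, f in self.fst.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"fst for {pop!r} must lie in [0, 1)")
        for r in self.platform_missing_rates:
            if not 0.0 <= r < 1.0:
                raise ValueError("platform missing rates must lie in [0, 1)")
        if not 0.0 <= self.within_block_r <= 1.0:
            raise ValueError("within_block_r must lie in [0, 1]")
        for arch in self.trait_architectures:
            if arch.n_causal > self.n_variants:
                raise ValueError("n_causal exceeds n_variants")
        t = self.n_traits
        for name in ("genetic_correlation", "environmental_correlation"):
            mat = getattr(self, name)
            if mat is None:
                setattr(self, name, np.eye(t))
            else:
                mat = np.asarray(mat, dtype=float)
                _check_correlation(mat, t, name)
                setattr(self, name, mat)

    @property
    def n_traits(self) -> int:
        return len(self.trait_architectures)

    @property
    def reference_population(self) -> str:
        return next(iter(self.n_samples))

    @property
    def trait_names(self) -> list:
        return [a.name for a in self.trait_architectures]


def _check_correlation(mat: np.ndarray, t: int, name: str) -> None:
    if mat.shape != (t, t):
        raise ValueError(f"{name} must be {t}x{t}")
    if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 1.0):
        raise ValueError(f"{name} must be symmetric with unit diagonal")
    if np.linalg.eigvalsh(mat).min() < -1e-10:
        raise ValueError(f"{name} is not positive semidefinite")


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests."""

    effects: pd.DataFrame          # (M x T) standardized-scale effects, id index
    genetic_values: pd.DataFrame   # (n x T), iid index
    realized_h2: dict              # trait -> realized heritability
    population: pd.Series          # iid -> population label
    family: pd.Series              # iid -> family label ("" = unrelated)


# ---------------------------------------------------------------------------
# Allele frequencies and genotypes
# ---------------------------------------------------------------------------

def draw_allele_frequencies(config: SyntheticCohortConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Ancestral plus per-population frequencies (Balding-Nichols).

    Each non-reference population draws SNP-wise from
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p; F=0 copies the
    ancestral frequencies.  All frequencies are kept inside (0, 1).
    """
    m = config.n_variants + config.x_variants
    if config.maf_beta is not None:
        a, b = config.maf_beta
        p = config.maf_low + rng.beta(a, b, size=m) * (config.maf_high
                                                       - config.maf_low)
    else:
        p = rng.uniform(config.maf_low, config.maf_high, size=m)
    out = pd.DataFrame({"ancestral": p, config.reference_population: p})
    for pop in config.n_samples:
        if pop == config.reference_population:
            continue
        f = config.fst.get(pop, 0.0)
        if f == 0.0:
            out[pop] = p
        else:
            shape = (1.0 - f) / f
            q = rng.beta(p * shape, (1.0 - p) * shape)
            out[pop] = np.clip(q, 1e-4, 1.0 - 1e-4)
    return out


def _latent_ar1_haplotypes(n: int, freqs: np.ndarray, block: int, r_latent: float,
                           rng: np.random.Generator) -> np.ndarray:
    """One haplotype set (n x m) of 0/1 alleles with block-AR(1) latent LD."""
    m = len(freqs)
    thresh = norm.ppf(freqs)
    alleles = np.empty((n, m), dtype=np.int8)
    innov_sd = np.sqrt(max(0.0, 1.0 - r_latent ** 2))
    for start in range(0, m, block):
        b = min(block, m - start)
        latent = np.empty((n, b))
        latent[:, 0] = rng.standard_normal(n)
        for j in range(1, b):
            latent[:, j] = (r_latent * latent[:, j - 1]
                            + innov_sd * rng.standard_normal(n))
        alleles[:, start:start + b] = latent < thresh[start:start + b]
    return alleles


def draw_genotypes(freqs: pd.DataFrame, config: SyntheticCohortConfig,
                   rng: np.random.Generator) -> GenotypeMatrix:
    """Draw the full multi-population cohort (autosomes + X-like block).

    Genotype = sum of two latent-AR(1) haplotypes; blocks are independent
    and never straddle chromosomes.  Positions sit on a regular 1-based
    grid of ``position_spacing`` bp.  Males (sex code 1) carry a single
    doubled haplotype on the X-like block.
    """
    if ((freqs.drop(columns="ancestral") <= 0).any().any()
            or (freqs.drop(columns="ancestral") >= 1).any().any()):
        raise ValueError("allele frequencies must lie in (0, 1)")
    m_auto = config.n_variants
    m_x = config.x_variants
    per_chrom = m_auto // config.n_chromosomes
    r_latent = min(1.0, np.sin(np.pi * config.within_block_r / 2.0))

    chroms = np.repeat([str(c + 1) for c in range(config.n_chromosomes)],
                       per_chrom)
    pos = np.concatenate([np.arange(per_chrom) * config.position_spacing + 1
                          for _ in range(config.n_chromosomes)])
    if m_x:
        chroms = np.concatenate([chroms, [config.x_chrom] * m_x])
        pos = np.concatenate([pos, np.arange(m_x) * config.position_spacing + 1])
    ids = np.array([f"snp_{c}_{p}" for c, p in zip(chroms, pos)])
    a_idx = rng.integers(0, 4, size=len(ids))
    a1 = _BASES[a_idx]
    a2 = _BASES[(a_idx + 1 + rng.integers(0, 3, size=len(ids))) % 4]

    counts_blocks, sample_rows = [], []
    for pop, n_pop in config.n_samples.items():
        p_pop = freqs[pop].to_numpy()
        sex = rng.integers(1, 3, size=n_pop)  # 1 = male, 2 = female
        geno = np.empty((n_pop, len(ids)), dtype=np.int8)
        hap_a = _latent_ar1_haplotypes(n_pop, p_pop[:m_auto],
                                       config.ld_block_size, r_latent, rng)
        hap_b = _latent_ar1_haplotypes(n_pop, p_pop[:m_auto],
                                       config.ld_block_size, r_latent, rng)
        geno[:, :m_auto] = hap_a + hap_b
        if m_x:
            hx_a = _latent_ar1_haplotypes(n_pop, p_pop[m_auto:],
                                          config.ld_block_size, r_latent, rng)
            hx_b = _latent_ar1_haplotypes(n_pop, p_pop[m_auto:],
                                          config.ld_block_size, r_latent, rng)
            male = sex == 1
            hx_b[male] = hx_a[male]  # hemizygous males coded homozygous
            geno[:, m_auto:] = hx_a + hx_b
        counts_blocks.append(geno)
        for i in range(n_pop):
            sample_rows.append((f"{pop}_{i:05d}", int(sex[i]), pop))

    samples = pd.DataFrame(sample_rows, columns=["iid", "sex", "population"])
    samples["platform"] = pd.NA
    samples["family"] = ""
    variants = pd.DataFrame({"chrom": chroms, "pos": pos, "id": ids,
                             "a1": a1, "a2": a2})
    return GenotypeMatrix(np.vstack(counts_blocks), variants, samples)


def spike_relatives(gm: GenotypeMatrix, n_sib_pairs: int,
                    rng: np.random.Generator, population: str | None = None,
                    x_chrom: str = "23", parent_pairs=None) -> GenotypeMatrix:
    """Append sibling pairs bred from cohort members by Mendelian sampling.

    Each pair shares two parents drawn (without replacement) from the given
    population; ``parent_pairs`` overrides the draw with explicit index
    pairs (allowing reuse, e.g. to create larger sibships).  Transmission
    is independent per SNP: a heterozygous parent transmits a fair coin,
    homozygotes transmit deterministically — expected sib-pair GRM 0.5.
    Sib X-like genotypes follow the male-homozygous coding convention.
    """
    if n_sib_pairs == 0 and parent_pairs is None:
        return gm
    pool = np.flatnonzero((gm.samples["population"] == population).to_numpy()) \
        if population is not None else np.arange(gm.n_samples)
    if parent_pairs is None:
        if len(pool) < 2 * n_sib_pairs:
            raise ValueError("insufficient parents for the requested sib pairs")
        chosen = rng.choice(pool, size=2 * n_sib_pairs, replace=False)
        parent_pairs = chosen.reshape(n_sib_pairs, 2)
    parent_pairs = np.asarray(parent_pairs)

    on_x = (gm.variants["chrom"].astype(str) == str(x_chrom)).to_numpy()
    rows, meta = [], []
    for k, (pa, pb) in enumerate(parent_pairs):
        pop = gm.samples["population"].iloc[pa]
        for s in range(2):
            sex = int(rng.integers(1, 3))
            gam = np.empty((2, gm.n_variants), dtype=np.int8)
            for slot, parent in enumerate((pa, pb)):
                g = gm.counts[parent]
                transmit = (g == 2).astype(np.int8)
                het = g == 1
                transmit[het] = rng.integers(0, 2, size=het.sum())
                gam[slot] = transmit
            child = gam[0] + gam[1]
            if on_x.any():
                if sex == 1:
                    child[on_x] = 2 * gam[0, on_x]  # doubled single haplotype
            rows.append(child)
            meta.append((f"fam{k:04d}_sib{s}", sex, pop, f"fam{k:04d}"))

    sib_samples = pd.DataFrame(meta, columns=["iid", "sex", "population",
                                              "family"])
    sib_samples["platform"] = pd.NA
    sib_samples = sib_samples[["iid", "sex", "population", "platform", "family"]]
    counts = np.vstack([gm.counts, np.asarray(rows, dtype=np.int8)])
    samples = pd.concat([gm.samples, sib_samples], ignore_index=True)
    return GenotypeMatrix(counts, gm.variants.copy(), samples)


# ---------------------------------------------------------------------------
# Effects and phenotypes
# ---------------------------------------------------------------------------

def draw_snp_effects(architectures, n_variants: int, mafs: np.ndarray,
                     genetic_correlation: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Per-SNP standardized-scale effects for every trait (M x T).

    Non-causal SNPs get exactly zero (spike-and-slab).  Causal effect
    vectors across traits are drawn with the configured genetic correlation
    on a shared causal set; per-trait marginal variances follow each
    trait's effect model, normalized so the total genetic variance on the
    standardized scale is ~1 per trait (the phenotype assembly rescales the
    environment to hit h2 anyway).
    """
    archs = list(architectures)
    t = len(archs)
    corr = np.asarray(genetic_correlation, dtype=float)
    _check_correlation(corr, t, "genetic_correlation")
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(t))

    n_causal = max(a.n_causal for a in archs)
    causal = rng.choice(n_variants, size=n_causal, replace=False) \
        if n_causal else np.array([], dtype=int)
    raw = rng.standard_normal((n_causal, t)) @ chol.T

    effects = np.zeros((n_variants, t))
    for ti, arch in enumerate(archs):
        use = causal[:arch.n_causal]
        col = raw[:arch.n_causal, ti].copy()
        var = np.ones(arch.n_causal)
        if arch.effect_model == "two_component" and arch.tail_fraction > 0:
            n_tail = int(round(arch.tail_fraction * arch.n_causal))
            tail_idx = rng.choice(arch.n_causal, size=n_tail, replace=False)
            var[tail_idx] *= arch.tail_variance_ratio
        elif arch.effect_model == "maf_stratified":
            edges = np.asarray(arch.maf_bin_edges)
            bins = np.digitize(mafs[use], edges) - 1
            bin_var = np.asarray(arch.maf_bin_variances, dtype=float)
            ok = (bins >= 0) & (bins < len(bin_var))
            var = np.where(ok, bin_var[np.clip(bins, 0, len(bin_var) - 1)], 0.0)
        col *= np.sqrt(var)
        denom = np.sqrt(max((col ** 2).sum(), 1e-300))
        effects[use, ti] = col / denom if arch.n_causal else 0.0
    return pd.DataFrame(effects, columns=[a.name for a in archs])


def assemble_phenotypes(gm: GenotypeMatrix, effects: pd.DataFrame,
                        config: SyntheticCohortConfig,
                        rng: np.random.Generator
                        ) -> tuple[PhenotypeTable, TruthSet]:
    """Build y = mu + sex*b_sex + age*b_age + g + e per trait.

    ``g`` is the standardized-genotype weighted sum of true effects
    (cohort-wide standardization, autosomes only); the environmental draw
    has the configured cross-trait correlation and is scaled per trait so
    Var(g) / (Var(g) + Var(e)) equals the trait's h2 target.
    """
    autosomal = (gm.variants["chrom"].astype(str) != str(config.x_chrom)).to_numpy()
    counts = gm.counts[:, autosomal].astype(float)
    counts[counts == MISSING] = np.nan
    mu = np.nanmean(counts, axis=0)
    sd = np.nanstd(counts, axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = np.where(np.isnan(counts), 0.0, (counts - mu) / sd)

    g = z @ effects.to_numpy()
    n, t = g.shape
    env_corr = np.asarray(config.environmental_correlation, dtype=float)
    e_raw = rng.standard_normal((n, t)) @ np.linalg.cholesky(
        env_corr + 1e-12 * np.eye(t)).T

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    sex = gm.samples["sex"].to_numpy().astype(float)
    sex_eff = list(config.sex_effects) or [0.0] * t
    age_eff = list(config.age_effects) or [0.0] * t

    y = np.empty((n, t))
    realized = {}
    for ti, arch in enumerate(config.trait_architectures):
        var_g = g[:, ti].var()
        if arch.h2_target == 1.0:
            if var_g == 0:
                raise ValueError(f"h2_target=1 with no causal variance for "
                                 f"trait {arch.name!r}")
            e = np.zeros(n)
        elif arch.h2_target == 0.0 or var_g == 0:
            g[:, ti] = 0.0
            e = e_raw[:, ti]
        else:
            sigma_e = np.sqrt(var_g * (1.0 - arch.h2_target) / arch.h2_target)
            e = e_raw[:, ti] / e_raw[:, ti].std() * sigma_e
        y[:, ti] = sex * sex_eff[ti] + ages * age_eff[ti] + g[:, ti] + e
        var_e = e.var()
        tot = g[:, ti].var() + var_e
        realized[arch.name] = float(g[:, ti].var() / tot) if tot > 0 else 0.0

    iids = gm.samples["iid"].to_numpy()
    data = pd.DataFrame(y, columns=config.trait_names, index=iids)
    data.index.name = "iid"
    data["sex"] = gm.samples["sex"].to_numpy()
    data["age"] = ages
    pheno = PhenotypeTable(data, config.trait_names, ["sex", "age"])

    eff_full = pd.DataFrame(0.0, index=gm.variants["id"],
                            columns=config.trait_names)
    eff_full.iloc[np.flatnonzero(autosomal)] = effects.to_numpy()
    truth = TruthSet(
        effects=eff_full,
        genetic_values=pd.DataFrame(g, columns=config.trait_names, index=iids),
        realized_h2=realized,
        population=pd.Series(gm.samples["population"].to_numpy(), index=iids),
        family=pd.Series(gm.samples["family"].to_numpy(), index=iids),
    )
    return pheno, truth


def apply_missingness(gm: GenotypeMatrix, config: SyntheticCohortConfig,
                      rng: np.random.Generator) -> GenotypeMatrix:
    """Assign platforms and knock out genotypes.

    Each sample lands on platform A or B (fair coin); each platform has its
    baseline missing rate, and a ``biased_variant_fraction`` of variants
    additionally loses genotypes on platform B at ``biased_missing_rate``.
    """
    n, m = gm.counts.shape
    platform = np.where(rng.random(n) < 0.5, "A", "B")
    counts = gm.counts.copy()
    rate_a, rate_b = config.platform_missing_rates
    drop = np.zeros((n, m), dtype=bool)
    if rate_a > 0:
        drop[platform == "A"] = rng.random(((platform == "A").sum(), m)) < rate_a
    if rate_b > 0:
        drop[platform == "B"] |= rng.random(((platform == "B").sum(), m)) < rate_b
    if config.biased_variant_fraction > 0:
        n_biased = int(round(config.biased_variant_fraction * m))
        biased = rng.choice(m, size=n_biased, replace=False)
        sel = np.ix_(platform == "B", biased)
        drop[sel] |= rng.random(((platform == "B").sum(), n_biased)) \
            < config.biased_missing_rate
    counts[drop] = MISSING
    samples = gm.samples.copy()
    samples["platform"] = platform
    return GenotypeMatrix(counts, gm.variants.copy(), samples)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticCohortConfig
                    ) -> tuple[GenotypeMatrix, PhenotypeTable, TruthSet]:
    """Draw the complete cohort: genotypes, relatives, phenotypes, missingness.

    Phenotypes are assembled from the complete genotypes; missingness is
    applied afterwards, so the truth set reflects the error-free data.
    """
    rng = np.random.default_rng(config.seed)
    freqs = draw_allele_frequencies(config, rng)
    gm = draw_genotypes(freqs, config, rng)
    gm = spike_relatives(gm, config.n_sib_pairs, rng,
                         population=config.reference_population,
                         x_chrom=config.x_chrom)
    autosomal = (gm.variants["chrom"].astype(str) != str(config.x_chrom)).to_numpy()
    sub = gm.subset(variants=autosomal)
    effects = draw_snp_effects(config.trait_architectures, sub.n_variants,
                               sub.maf(), config.genetic_correlation, rng)
    pheno, truth = assemble_phenotypes(gm, effects, config, rng)
    gm = apply_missingness(gm, config, rng)
    return gm, pheno, truth
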