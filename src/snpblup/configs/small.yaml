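# Packaged desk-scale cohort: ~3,000 samples, ~20,000 autosomal SNPs.
# One reference ancestry (EUR-like) with sib pairs spiked in, plus two
# Balding-Nichols diverged groups for across-population scoring.
sim:
  n_samples: {EUR: 2400, SAS: 300, AFR: 300}
  n_variants: 20000
  n_chromosomes: 10
  ld_block_size: 10
  within_block_r: 0.6
  maf_low: 0.001
  maf_high: 0.5
  maf_beta: null
  fst: {SAS: 0.05, AFR: 0.15}
  n_sib_pairs: 150
  platform_missing_rates: [0.001, 0.003]
  biased_variant_fraction: 0.005
  biased_missing_rate: 0.25
  trait_architectures:
    - {name: height, h2_target: 0.5, n_causal: 2000,
       effect_model: single_gaussian}
    - {name: bmr, h2_target: 0.4, n_causal: 2000,
       effect_model: single_gaussian}
  genetic_correlation: [[1.0, 0.6], [0.6, 1.0]]
  environmental_correlation: [[1.0, 0.3], [0.3, 1.0]]
  sex_effects: [0.5, 0.3]
  age_effects: [0.01, -0.01]
  age_range: [40, 70]
  position_spacing: 1000
  x_variants: 300
  x_chrom: "23"
  seed: 20160755
min_group_size: 150
subsample_fractions: [0.25, 0.4, 0.55, 0.75, 1.0]
subsample_seeds: 2
seed: 7
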