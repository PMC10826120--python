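# Example end-to-end configuration with the package defaults materialized.
# Sections map to pipeline stages: sim (synthetic cohort), assoc (allelic
# filter), rf (two-step random-forest selection), triplets (3WII cascade).

sim:
  n_cases: 1000
  n_controls: 1000
  n_background_snps: 50
  maf_range: [0.05, 0.5]
  ld_blocks: []                    # e.g. [[4, 0.99]] = 4 SNPs, latent r 0.99
  marginal_effects: []             # e.g. [{maf: 0.3, relative_risks: [1.0, 1.5, 2.25]}]
  planted_triplets:
    - mafs: [0.5, 0.5, 0.5]        # MAF 0.5 makes the parity table exactly pure
      base: 0.1
      effect: 0.08
  baseline_prevalence: 0.1
  missing_rate: 0.0
  seed: 0

assoc:
  alpha: 0.01                      # strict '<' on the allelic chi-square p

rf:
  ntree_grid: [100, 250, 500, 1000]
  mtry_grid: auto                  # sqrt(n SNPs) and its halvings/doublings
  cv_folds: 5
  importance_permutations: 100
  importance_measure: permutation  # or 'gini' (cheaper)
  holdout_fraction: 0.25
  stage1_alpha: 0.05
  stage2_alpha: 0.05               # 0.01 for large panels
  seed: 0

triplets:
  triplet_alpha: 0.05              # chi-square(1 df) screen on the IIG statistic
  pair_alpha: 0.05                 # two-way information-gain exclusion
  ld_r2_max: 0.8                   # genotype-correlation r^2 exclusion
  n_perm: 1000                     # 10000 with perm_alpha 0.01 for large panels
  perm_alpha: 0.05
  reference: controls              # 'general population' term; or 'pooled'
  pseudocount: 0.0
  seed: 0
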