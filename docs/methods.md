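# Methods

`epitrio` prioritizes SNP triplets whose joint association with a binary
disease status is *third order* — present in the three-locus genotype
distribution but not explained by any single SNP or SNP pair.  The
pipeline has three stages: a single-locus allelic chi-square filter, a
two-step random-forest (RF-RF) selection, and an entropy-based three-way
interaction screen with permutation validation.  A synthetic cohort
generator with planted pure third-order penetrance signals provides
ground truth for every stage.

## Entropy statistics

All information quantities are plug-in (maximum-likelihood) estimates in
nats from genotype-combination count tables, stratified by disease status
D (1 = case, 0 = control).  For markers X, Y (each coded 0/1/2):

    IG(X,Y|D)    = I(X;Y | D=1) − I(X;Y | reference)

and for triplets, with McGill interaction information
I(X;Y;Z) = I(X;Y) − I(X;Y|Z) (positive = redundancy, negative = synergy):

    IIG(X,Y,Z|D) = I(X;Y;Z | D=1) − I(X;Y;Z | reference)

The *reference* ("general population") stratum is the controls by
default; `reference="pooled"` uses cases + controls combined.  Controls
were chosen because the pipeline's direction labels read a positive IIG
as an excess of three-way information among the affected relative to the
unaffected; with balanced retrospective sampling the pooled table is
dominated by neither stratum and the two modes rarely disagree in sign.

Individuals missing any genotype of a tuple are dropped for that tuple
only (tuple-wise deletion).  Zero cells contribute zero (0·ln 0 = 0); an
optional +0.5 pseudocount is available for very sparse tables but is off
by default.

### The variance normalizer Λ

The screening statistic is T = IG²/Λ (or IIG²/Λ), referred to a
chi-square distribution with 1 degree of freedom.  Λ is a first-order
(delta-method) variance of the plug-in gain: with w the gradient of the
information functional with respect to the cell probabilities,

    Λ = Var_w · (1/N_case + 1/N_ref),
    Var_w = Σ p w² − (Σ p w)².

Two evaluation points for w are implemented:

* **`weights="null"` (default):** w is evaluated at the pooled
  case+control table — the common cell distribution both strata share
  under the null hypothesis that the markers are jointly independent of
  disease.  This is the variance the chi-square reference requires.
* **`weights="stratum"`:** w evaluated separately within each stratum and
  the per-stratum variances summed.

The per-stratum form looks natural but is badly behaved exactly where the
screen operates: when the markers are also mutually independent, the true
gradient of MI / interaction information is identically zero, so the
per-stratum ŵ is pure estimation noise that is *correlated with the gain
itself*.  Empirically this halves the statistic (T ≈ χ²₁/2; type-I rate
≈ 0.01 at the nominal 0.05 cut), while the pooled-weight form calibrates
at ≈ 0.06 with identical power on planted signals.  Both forms satisfy
the structural checks (Λ halves when all counts double; Λ is within a
factor of two of the bootstrap variance of the gain on generic tables).
Because the final inference is permutation-based, Λ only has to be good
enough for an intermediate screen; the permutation p-values are exact by
construction regardless of Λ.

### Permutation validation

Disease labels are shuffled B times (one shuffle scores every surviving
triplet, which keeps B = 10000 tractable and leaves each triplet's
marginal p-value untouched); p_perm = (1 + #{T_perm ≥ T_obs})/(1 + B).
The add-one form bounds p away from zero and counts ties conservatively.

## Triplet cascade

1. **Screen:** all C(m,3) triplets of the selected panel; keep
   p_χ² < `triplet_alpha` (0.05).
2. **Pairwise exclusion:** a surviving triplet is flagged when any of its
   three pairs has a significant two-way IG (p < `pair_alpha`) — the
   triplet's signal could then be second order.
3. **LD exclusion:** flagged when any pair's genotype-correlation r²
   (squared Pearson correlation of 0/1/2 codes over shared non-missing
   individuals) exceeds `ld_r2_max` (default 0.8; composite r² is used
   because phased haplotypes are unavailable).
4. **Permutation test** on the survivors; significance at `perm_alpha`
   (0.05, or 0.01 for large panels).

## Random-forest selection

Both RF stages tune (mtry, ntree) by stratified 5-fold cross-validated
misclassification error (ties toward smaller ntree, then smaller mtry),
with gini splits and maximal (unbounded-depth) trees.  The automatic mtry
grid is √p and its halvings/doublings, clipped to [1, p].  Per-SNP
importance p-values follow the label-permutation (Altmann) scheme: the
observed importance is compared against importances from forests refit on
shuffled labels, p = (1 + #{null ≥ obs})/(1 + n_perm).  Stage 1 keeps
p < `stage1_alpha`; stage 2 re-tunes and re-tests on the kept panel at
`stage2_alpha`.  If stage 1 keeps fewer than three SNPs the triplet stage
cannot run, so stage 2 is skipped with a warning.

Importance measures: `"permutation"` (default) scores the accuracy drop
on a held-out row fraction (`holdout_fraction`, default 0.25) when one
column is shuffled.  The holdout plays the role OOB samples play in
classic RF permutation importance; scoring in-sample is ruled out because
maximal trees memorize their training rows, which inflates the null
forests' importances and destroys the test.  `"gini"` (impurity decrease)
is much cheaper and remains a valid Altmann test statistic, at some cost
in sensitivity to interactions.

### A structural limit worth knowing

Greedy trees split on marginal impurity gain.  A *pure* third-order
signal offers zero gain at the first and second split by construction, so
random forests detect it only when chance conditioning on two of the
three loci happens often enough — which requires a small panel.
Empirically (holdout accuracy on planted-parity cohorts of 2000+2000):
~0.72 with the 3 causal SNPs alone, ~0.55 at 13 SNPs, chance at ≥ 50
SNPs, *at any effect size up to near-deterministic penetrance*.  The
allelic pre-filter compounds this: a pure triplet has no single-locus
signal, so a p < 0.01 marginal filter removes it with probability ≈ 0.97
per SNP.  The end-to-end cascade therefore recovers pure planted triplets
reliably only when the entropy stage receives them (small panels, or
marginally-associated causal SNPs, which is the regime GWAS pre-filtering
produces in practice).  The corresponding end-to-end acceptance check on
a 100-SNP panel is left failing rather than weakened.  The triplet
machinery itself is not the limit: at effect 0.08 (n = 2000+2000) the
screen plus permutation test recovers the planted signal in every
replicate; the calibrated pairwise exclusion then removes ≈ 10% of pure
triplets as designed (three 0.05-level pair tests per triplet,
0.967³ ≈ 0.90 expected survival — measured 16/20 on fixed seeds).

## Synthetic cohorts

`simulate_cohort` draws biallelic genotypes under Hardy–Weinberg
equilibrium (background MAFs uniform on (0.05, 0.5)), optional LD blocks
(two latent-Gaussian haplotypes per individual with equicorrelation r
inside a block, thresholded at the block's shared MAF — latent r
attenuates under dichotomization, e.g. r = 0.99 yields genotype r² ≈ 0.7),
marginal-effect SNPs with genotype relative risks, and planted penetrance
triplets.  Disease status follows a log-odds-additive model,

    logit P(D=1) = logit(baseline) + Σ log RR_j(g_j)
                 + Σ_t [logit f_t(g_t) − logit f̄_t],

so with a single planted triplet and baseline equal to the table's HWE
mean the table acts as an exact override.  Exact case/control quotas are
filled by rejection sampling (retrospective ascertainment); a fixed seed
reproduces the cohort bit-exactly.

The **parity table** f(g) = base + effect·(−1)^(g₁+g₂+g₃) is the planted
pure signal: at MAF 0.5 the genotype-code parity is a fair coin
independent of any one or two codes, so every lower-order marginal equals
`base` exactly (verified to 1e-12 by enumeration).  Purity is exact only
at MAF 0.5; the constructor requires base ± effect ∈ [0, 1], so, e.g.,
effect 0.08 needs base ≥ 0.08 (the shipped examples use base 0.10).

What the generator does **not** emulate: population structure,
relatedness, genotyping batch effects, haplotype-scale LD decay,
covariates, sex chromosomes.  A green recovery test therefore establishes
that the statistics behave as designed on clean HWE data, not that the
pipeline is robust to confounding.

## Numerical choices

* Entropies in nats; only the scale-free T is ever compared externally.
* Λ floored at 1e-12; T = 0 ⇔ gain = 0.
* Allelic test: Pearson 2×2 without continuity correction; monomorphic
  SNPs score χ² = 0, p = 1; the 0.01 filter is a strict inequality.
* PLINK 1 SNP-major BED only (magic `6C 1B 01`); genotype code counts A1
  copies; pad bits encode hom-A2.
* RF backend: scikit-learn `RandomForestClassifier`; any implementation
  honoring gini splits / maximal depth / mtry / majority vote could be
  substituted.
* Heavy test simulations run with reduced forest sizes and permutation
  depths (noted in the tests); thresholds are asserted at full stated
  levels.
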