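# Methods

`outbredqtl` maps expression quantitative trait loci (eQTL for mRNA, mirQTL
for miRNA) in Diversity Outbred (DO) mice and characterizes how their
architecture responds to diet. This note documents the statistical models,
the synthetic-data generator that stands in for real cohorts, the numerical
conventions, and the limitations a user should know before trusting a
number.

## Genotype representation and kinship

DO genomes are mosaics of eight founder haplotypes. All mapping works on the
founder allele-probability tensor `P` of shape `(n individuals, M markers,
8 founders)`, where each `(i, m)` slice is a probability vector over the
founders on the homolog-averaged dosage scale (sums to 1).

Kinship between individuals is the marker-averaged probability of carrying
the same founder allele:

    K_ij = (1/M) * sum_m sum_f P[i,m,f] * P[j,m,f]

Genome scans use the leave-one-chromosome-out (LOCO) variant: while
scanning chromosome `c`, the kinship is recomputed from all markers *not*
on `c`, so the polygenic term cannot absorb the very signal being tested.
With a single chromosome the LOCO exclusion would be empty; the kinship
falls back to a zero matrix (plain least squares) with a warning.

## The mixed-model scan

At each marker the phenotype is modeled as

    y = X beta + g + e,    g ~ N(0, sigma_g^2 K_LOCO),   e ~ N(0, sigma_e^2 I)

Variance components are estimated by REML once per (phenotype x LOCO
chromosome) under the no-marker null and held fixed across that
chromosome's markers — the standard multiparent-scan convention that trades
per-marker exactness for tractability. The REML criterion is concentrated
to one dimension (the heritability ratio h2 = sigma_g^2 / (sigma_g^2 +
sigma_e^2)) after a single eigendecomposition of `K`, and optimized by
bounded scalar search with tolerance 1e-8. When the eigenvalue spectrum of
`K` is flat (identity-like or zero kinship) the criterion does not depend
on h2 and h2 = 0 is returned, which makes a zero kinship reduce exactly to
ordinary least squares.

Given the null variance components, the marker LOD is computed in the
whitened space:

    LOD = (n / 2) * log10(RSS_null / RSS_full)

Model definitions (cell-means coding: the 8 dosage columns replace the
intercept in the full model, avoiding the exact collinearity of dosages
with the constant):

- **additive**: null = intercept + diet; full = diet + 8 dosages.
- **interactive**: null = intercept + diet; full = 8 dosages + 8
  dosage x diet products (the diet column itself is spanned by the
  products). Because the interactive full model nests the additive one
  against the same null, interactive LODs are never smaller — which is why
  interactive permutation thresholds are systematically higher.
- **subset-HFCA / subset-HP**: mice of one diet only, no diet covariate;
  null = intercept; full = 8 dosages.

The implementation precomputes, per chromosome, the LOCO eigendecomposition
and the rotated covariate and marker blocks (`ScanContext`), so scanning
one phenotype (or one permutation of it) costs one rotation, one 1-D REML
fit per chromosome, and a batched normal-equation solve across markers. The
batched solve falls back to a pseudo-inverse for any marker whose normal
equations are rank-deficient (e.g., a founder entirely absent under hard
probabilities), preserving least-squares semantics.

Degenerate inputs: a constant phenotype yields LOD = 0 everywhere with a
warning (not an exception); a perfect fit is kept finite by flooring the
full-model RSS at 1e-14 of the phenotype's sum of squares.

## Permutation significance

Per-phenotype genome-wide thresholds: phenotype labels are permuted against
the genotype/covariate/kinship rows, the genome-wide maximum LOD recorded,
and the 95th empirical quantile (linear interpolation between order
statistics) of `n_perm` such draws (default 1000) is the threshold at
P = 0.05.

The two-stage screen reduces cost on large panels: stage one draws 50
permutations and computes a deliberately conservative threshold, the 90th
quantile minus the standard error of that quantile; phenotypes whose
observed maximum LOD clears it proceed to the full null. The quantile SE
uses the Maritz–Jarrett estimator (order statistics weighted by increments
of the Beta(q(n+1), (1-q)(n+1)) CDF); a bootstrap SE is available by
config. Permutation streams are derived per phenotype by stable hashing
(CRC32 of the phenotype id mixed with the master seed), with separate
screen-stage and full-stage substreams, so (a) adding phenotypes never
changes existing nulls and (b) a phenotype's full-stage threshold is
identical whether reached through the screen or through exhaustive
permutation — the screen-vs-exhaustive comparison then isolates exactly the
screen's false-drop risk.

## QTL characterization

- **Peaks**: at most one per chromosome — the maximum-LOD marker if it
  strictly exceeds the phenotype's threshold; ties break to the smallest
  position.
- **Support interval**: walk outward from the peak; each bound is the
  position of the first marker whose LOD is at least 1.8 below the peak
  (first-below convention), censored at the outermost marker of the
  chromosome. The 1.8-LOD drop approximates 95% coverage; the
  `interval_coverage` study measures it directly on planted QTL.
- **cis/trans**: cis iff the peak marker lies on the feature's chromosome
  within 4 Mb (inclusive) of its transcription start site; everything else
  is trans. A 1-Mb window is a config switch. Classification is monotone in
  the window: shrinking it can only convert cis calls to trans.
- **Variance explained**: plain (unmixed) Haley–Knott regression at the
  peak — R^2(covariates + 8 dosages) − R^2(covariates) — deliberately
  different from the mixed-model scan; the scan/ANOVA split is part of the
  procedure being reproduced.
- **Founder effects**: best linear unbiased predictions. After whitening by
  the null kinship fit, the 8 dosages enter as a random effect whose
  variance ratio is estimated by REML (bounded search on the log ratio);
  the coefficients are ridge-shrunken founder deviations around an explicit
  intercept, so their L2 norm never exceeds the unpenalized least-squares
  solution on the same whitened design. Under a genotype-independent trait
  the REML ratio sits at the zero boundary in roughly half of replicates
  (exactly zero coefficients) and the median maximum coefficient stays
  below 0.1 SD of the trait; individual null replicates can still show
  coefficients up to ~0.3 SD, which is a property of per-marker REML, not a
  defect.
- **Heritability**: narrow-sense h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)
  from the REML fit against the single full (non-LOCO) kinship.

## Architecture statistics

- **Wild-derived founder enrichment**: each peak's 8 BLUP effects are
  mean-centered and scaled to unit SD; Kruskal–Wallis compares the absolute
  scaled effects across the 8 founder groups and Dunn's post hoc (pooled
  ranks, tie-corrected z statistics, BH adjustment) locates the enriched
  founders. Dunn's test is implemented in-package (no post-hoc library in
  the dependency set).
- **Colocalization**: all same-chromosome eQTL/mirQTL pairs whose support
  intervals overlap (closed intervals), with the peak-to-peak distance in
  Mb; 0 means the same marker.
- **miRNA x mRNA correlation structure**: all pairwise Spearman
  correlations, computed as Pearson correlations of rank matrices with the
  t-approximation p-value (the same convention as `scipy.stats.spearmanr`,
  verified in tests; the matrix path is needed because the full
  cross-product at study scale is ~5.9 million pairs). BH correction is
  applied across the full set; significant correlations are compared
  between mRNA eQTL categories (cis / trans / no-eqtl) by Wilcoxon rank-sum
  on |rho|, with multi-mapping mRNAs (both cis and trans peaks) removed
  before categorization; Fisher's exact test checks independence of mapping
  status and cataloged miRNA-target interactions.
- **Differential expression**: features must pass an abundance filter
  first — mRNA at or above 4 (log-intensity units) in at least 25% of
  samples, miRNA at or above 50 RPMMM in ~25% — both comparisons inclusive,
  so a feature exactly at the floor in exactly a quarter of samples passes.
  Diet groups are compared by Wilcoxon rank-sum (exact null when both
  groups have <= 50 tie-free observations, normal approximation with tie
  correction otherwise) with BH correction at 0.05.
- **Allele x diet interaction ranking**: for each interactive-model eQTL,
  an F-test of the dosage x diet block by plain least squares (full:
  covariates + dosages + dosage x diet; reduced: covariates + dosages),
  BH-adjusted across eQTL. Significant phenotypes must also carry a
  concordant eQTL in *both* diet-subset models (same chromosome,
  overlapping support intervals, matching cis/trans class). For those, the
  per-founder percent difference of HFCA vs HP BLUP effects (HP as
  reference) is computed with near-zero references floored at 0.05 x the SD
  of all sixteen effects — the floor keeps the ratio defined and makes the
  divergence score invariant to a common rescaling of both effect vectors —
  and the divergence score is the sum of the eight absolute percent
  differences, ranked descending.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: a DO cohort
(default 243 animals in the unbalanced 134:109 HFCA:HP split) genotyped on
an evenly spaced marker map, with expression panels of a few hundred mRNA
features and 246 miRNA features.

- **Mosaics**: each homolog starts from a uniform founder; between
  consecutive markers `d` Mb apart it switches with probability
  `1 − exp(−rate·d)` (default rate 0.05/Mb) to a uniformly chosen
  *different* founder. Expected founder changes per homolog approach
  rate x length at dense spacing; founder marginals converge to 1/8. Rate 0
  is the valid no-recombination limit.
- **Probabilities**: each homolog puts `1 − softening` mass on its true
  founder, the rest spread uniformly (default softening 0.02, emulating
  probabilistic reconstruction); slices sum to 1 exactly.
- **Traits**: `y = sum_q P_mq (a_q + b_q·diet) + c·diet + g + e` with
  `g ~ N(0, h2·K)` drawn under the realized kinship and
  `e ~ N(0, 1 − h2)`, so a correctly specified mixed model recovers the
  target h2 in expectation; `background_sd` scales the whole stochastic
  part (0 gives the noise-free limit). mRNA are emitted as baseline + y on
  a log-intensity-like scale; miRNA as `2^(baseline + y)` on a nonnegative
  RPMMM-like scale. Default planted architecture: 30% of features get a
  cis QTL (inside the 4-Mb TSS window; sparse maps that leave no marker in
  the window honestly relabel the nearest marker trans), 10% a trans QTL,
  with cis effects larger than trans (matching the qualitative finding that
  local variants explain more variance); target h2 drawn around 0.34.
  Founder effect-size distributions are free parameters — the generator
  makes no claim of realism there — and CAST/PWK inflation and
  founder-specific diet interactions are opt-in knobs.
- **Streams**: one seeded substream per component (mosaics, diet, effects,
  polygenic, noise), so adding phenotypes never perturbs genotypes; a fixed
  seed makes all outputs byte-identical.

What the generator does **not** emulate — and hence what green tests do not
certify about real data: SNP-level genotypes and LD with causal variants,
empirical recombination maps and interference, X-chromosome dosage,
microarray normalization artifacts, sequencing count noise (miRNA values
are transformed Gaussians, not counts), batch effects, and sibling-pair
family structure beyond what the mosaic kinship induces.

## Validation studies and sizes

`outbredqtl.evaluation` packages the calibration/recovery studies that
`scripts/acceptance.py` and the test suite run. Study sizes are desk scale,
chosen so the whole battery completes in minutes on one CPU while keeping
each measurement statistically meaningful:

- scan-vs-oracle agreement: 50 random instances, n=12, kinship zeroed;
- two-stage screen vs exhaustive permutation: 200 phenotypes (20 planted),
  n=150, 2x60 markers, 200 full permutations per phenotype;
- threshold type-I error: 100 independent null traits, n=120, 200
  permutations each (nominal 0.05; at 100 traits the binomial SE of the
  estimate is ~0.022);
- heritability recovery: targets 0.2/0.4/0.8, 20 replicates each, n=400;
- cis/trans recovery: 40 planted cis + 40 planted trans, n=200, two-stage
  thresholds at 30/100 permutations;
- wild-founder enrichment: 20 replicates of 80 planted QTL with CAST/PWK
  effects inflated 3x, n=200;
- diet-interaction recovery: 20 replicates of 30 strong shared cis eQTL
  (dosage term SD 1.5) with one NZO-only-in-HFCA interaction (SD 1.0),
  n=160, fixed LOD-6 detection;
- support-interval coverage: 200 planted QTL, n=200, fixed LOD-6 detection.

## Known limitations

- Variance components fixed per chromosome under the null (not re-fit per
  marker or per permutation stage beyond the per-permutation null re-fit) —
  the standard convention, slightly conservative near very strong QTL.
- The two-stage screen is a heuristic: a phenotype whose observed maximum
  LOD lies between its (noisy) screen threshold and its full threshold can
  in principle be dropped; the agreement study measures this directly.
- BLUP founder effects use per-marker REML for the effect variance; under
  the null the estimate is boundary-distributed (see above).
- Percent-difference divergence scores depend on the near-zero-reference
  floor; scores for phenotypes with genuinely tiny HP effects are
  floor-dominated and should be read as rankings, not effect sizes.
- No X-chromosome model, no dominance, no multi-QTL joint fits.
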