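# Methods

`edanet` implements a complete analysis chain for genotype-contrast bulk
RNA-seq designs of the kind used in *Eda*-genotype stickleback work: three
families x three genotypes (CC/CL/LL) x two sexes x two replicates
(36 samples), with the freshwater *Eda* allele L acting recessively. The
package bundles a generative simulator with planted truth so every method
can be exercised and calibrated end to end without external data.

## 1. Synthetic data generator

`SimulationConfig` / `generate_dataset` produce gene counts, exon counts,
sample metadata, gene lengths and a `SyntheticTruth` ledger.

Model, per gene g and sample k:

- **Baseline abundance.** log2-CPM-scale baseline `a_g ~ N(5, 2)`
  (`baseline_log2_mean_sd`), giving a realistic dynamic range of ~12 log2
  units across 3,000 genes (`n_genes`).
- **Co-expression modules.** `n_modules` (default 10) disjoint modules of
  `module_size` (default 100) genes. Each module m has a latent sample
  score `z_mk ~ N(0,1)`; member genes load on it with
  `|loading| ~ U(0.4, 0.8)` (`module_loading_band`) and a per-module
  orientation sign, so members are positively inter-correlated in the
  signed-network sense.
- **Family batch effect.** One latent factor: per-gene loading
  `~ N(0, family_sd)` (default 0.5) times a centred, unit-variance family
  score (A < B < C gradient). A rank-1 factor rather than independent
  per-family offsets is used deliberately: independent offsets for three
  families span two dimensions and would occupy both leading MDS axes,
  whereas real batch structure in bulk RNA-seq MDS plots typically forms a
  single gradient. With the rank-1 factor, dimension 1 carries family and
  dimension 2 carries genotype, the published sample-space pattern.
- **Differential expression.** `n_deg` genes (default 200) get a genotype
  effect `delta_g` with `|delta| ~ U(1, 2)` log2 units and random sign,
  multiplied by the genotype design value x(genotype). Under the default
  `recessive_L` model x(CC)=x(CL)=0, x(LL)=1; `additive` and `dominant_L`
  are also available. Counts are compositional (softmax over genes times
  library size), so the realized log2 fold change differs from `delta_g`
  by a small global shift, recorded in the truth ledger as
  `compositional_log2_shift`.
- **Counts.** Library sizes `~ N(5e5, CV 0.1)`. Counts are
  gamma-Poisson (negative binomial) draws around `mu = p * L` with a
  decreasing dispersion trend `phi = 0.05 + 2 / mean(mu)`
  (`dispersion_intercept`, `dispersion_slope`), the standard mean-
  dispersion shape of bulk RNA-seq.
- **Exons and splicing.** Each gene has 3-8 exons with Dirichlet(5) base
  usage proportions; exon counts partition the gene count multinomially
  (or Dirichlet-multinomially when `dirichlet_alpha` is finite). `n_dsg`
  genes (default 100, disjoint from the DEGs) get a usage shift: one
  target exon (the one nearest 25% usage with headroom) gains
  `usage_shift` = 0.2 of the gene's output in affected genotypes, the
  remaining exons renormalized. This changes splicing without changing
  the gene total, the defining feature of differential exon usage.

What the generator does **not** emulate: positional read biases, isoform-
level correlation between exons beyond the multinomial/Dirichlet split,
GC/length effects on counts, sex-linked expression, and any real genome
annotation. It is a calibration instrument, not a forward model of a
sequencer.

All randomness flows from a single `numpy` generator seeded by
`SimulationConfig.seed`; the same seed reproduces the dataset bit for bit.

## 2. Filtering and normalization

- **Low-expression filter.** A gene is removed iff its count is below
  `min_count` (default 10) in at least `max_low_samples` samples, with
  `max_low_samples = floor(n_samples / 3)` by default. This reproduces
  the published thresholds for both 35-sample (11) and 36-sample (12)
  designs.
- **TMM.** The reference sample is the one whose 75th-percentile CPM is
  closest to the mean across samples. For each sample, M (log ratio) and
  A (mean abundance) values over genes positive in both are doubly
  trimmed (30% of M, 5% of A, rank-based on both tails) and the factor is
  the inverse-asymptotic-variance weighted mean of the surviving M
  values. Factors are rescaled to geometric mean 1.
- **Units.** CPM, TPM (counts over gene length, renormalized to 1e6) and
  log2-CPM with a prior count of 0.5.

## 3. Differential expression (TREAT)

Each gene is fit with a log-link negative-binomial GLM, design
`~ genotype + family + sex` with CC as the genotype reference, offsets
`log(library_size * TMM factor)`. Fitting is batched IRLS across genes
(working weights `mu / (1 + phi * mu)`), with a per-gene least-squares
fallback for singular systems and stability flags (finite covariance,
bounded standard errors); unstable genes receive NA p-values and are
excluded from multiplicity correction.

Dispersions are estimated by method of moments on a Poisson pilot fit
(raw `phi`), smoothed by a lowess trend on log2 mean, and shrunk gene-wise
toward the trend with prior weight `prior_df` = 10:
`tagwise = (d0 * trend + d_res * raw) / (d0 + d_res)`.

The TREAT test of H0 `|log2FC| <= tau` (default tau = 0.585, i.e. the
1.5-fold line since 2^0.585 ≈ 1.5) computes
`p = P(T_d >= (|b| - tau)/s) + P(T_d >= (|b| + tau)/s)`, capped at 1.
The reference degrees of freedom are `d = residual_df + prior_df`,
reflecting the information the shrunken dispersion borrows from the trend
(the moderated-statistic convention); without the augmentation the test
is slightly conservative at n = 36. BH adjustment at alpha = 0.05 per
contrast; the three contrasts are LLvsCC, CLvsCC and LLvsCL.

## 4. Differential exon usage

Exons are fit with the same NB GLM machinery (offsets: log total exon
library). For a gene with m exons, the usage effect of exon e is its
contrast coefficient minus the inverse-variance-weighted consensus of the
*other* m-1 exons, with standard error
`sqrt(s_e^2 + 1 / sum_{j != e} s_j^{-2})`; gene-wide expression shifts
cancel exactly. Single-exon genes are excluded (reason-coded).

Gene-level aggregation uses two routes:

- **Chi-square route.** Exon t statistics are mapped to normal scores,
  then `S = ((m-1)/m) * sum(z_e^2)` is referred to chi-square with m-1
  degrees of freedom. The scaling matters: under the leave-one-out
  construction the m statistics satisfy one linear constraint, and
  `((m-1)/m) * sum(z^2)` is exactly chi-square(m-1) under the null in the
  equal-variance normal limit, whereas the unscaled sum is
  anticonservative (by a factor of 2 at m = 2). The calibration test in
  the suite verifies uniform null p-values under this law.
- **Simes route.** `min_j (m * p_(j) / j)` over ordered exon p-values,
  powerful for single-exon shifts.

Each route is BH-adjusted across genes; a gene significant on either
route is a differentially spliced gene (the union rule).

## 5. Co-expression network

Built from family-adjusted log2-CPM (per-gene, per-family centring, grand
mean restored), whole-matrix only (capped at 6,000 genes).

- **Correlation.** Biweight midcorrelation with `maxPOutliers` = 0.10:
  the biweight u-scores are scaled per side so that at most 10% of
  samples per side can be zero-weighted as outliers; zero-MAD genes fall
  back to Pearson with a warning.
- **Adjacency.** Signed: `a_ij = ((1 + cor_ij)/2)^beta`. The soft
  threshold is the smallest candidate from
  {1..10, 12, 14, 16, 18, 20} whose signed scale-free fit R^2 (sign-
  corrected log-log regression of the connectivity histogram) reaches
  0.85, falling back to the argmax with a warning. `beta` can be fixed
  (e.g. the conventional 14). Caveat: when the scan selects a low beta
  (< ~9), the TOM dissimilarities compress toward 1 and the static cut
  below can under-split; fixing `beta` = 14 is the robust choice on data
  of this design's scale.
- **TOM.** `TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`,
  unit diagonal.
- **Modules.** Average-linkage clustering of 1 - TOM with a static cut at
  height 0.99; clusters below 20 genes go to the unassigned label M0;
  modules whose eigengenes (first PC of standardized member expression,
  sign-oriented) correlate >= 0.75 are merged iteratively, most
  correlated pair first. Surviving modules are relabelled M1, M2, ... by
  decreasing size (ties broken by smallest member id), making labels
  independent of input order.
- **Connectivity and kME.** `kTotal_i = sum_j a_ij` is the pleiotropy
  proxy used by the permutation comparisons. kME is the (bicor)
  correlation of any profile with a module eigengene; *exon atomization*
  assigns each exon of a gene to the module maximizing its kME when that
  kME >= 0.5, else M0 — localizing module membership of a spliced gene
  to specific exons. `extract_subnetwork` yields edge lists around a
  focal gene (top-n neighbours) or a module (top-n kTotal hubs).

## 6. Permutation and set statistics

- **Median comparison.** Observed statistic: difference in medians of a
  per-gene value (kTotal, mean TPM) between a gene set and the universe,
  or between two disjoint sets. B = 10,000 random same-size draws
  (two-set draws are disjoint by construction); `p = c / B` with a floor
  flag reported as "p < 1/B" when c = 0; the `(c+1)/(B+1)` estimator is
  optional.
- **Overlap test.** Random same-size set pairs; the exact hypergeometric
  upper tail is computed alongside as a cross-check.
- **ORA.** Hypergeometric over-representation against the explicit
  filtered background, terms intersected with the background, minimum
  term size 3, BH across terms.
- **Crosstab.** Module x {DSG-only, DEG-only, both, total} counts for the
  modules hit by either set, M0 first.

## 7. Sample-space embedding

Pairwise leading-logFC distances: root-mean-square of the 500 largest
absolute log2-CPM differences per sample pair, embedded by classical
(Torgerson) MDS. With the default generator, dimension 1 captures the
family gradient and dimension 2 separates LL from CC/CL.

## 8. Determinism and problem sizes

Every stochastic step takes an explicit seed (default 1234) and uses
`numpy.random.default_rng`; the pipeline writes no timestamps, so two
runs with the same configuration produce byte-identical output bundles.
Default problem sizes (3,000 genes x 36 samples, ~15,000 exons) run the
full pipeline in a few minutes on one CPU; the network stage is
O(genes^2) memory and deliberately capped rather than blockwise.

## 9. Limitations

- The NB GLM uses IRLS point estimates with Wald-type TREAT tests, not
  quasi-likelihood F-tests; calibration is demonstrated by simulation.
- The gene-level splicing statistic assumes approximately equal exon
  variances for its exact null law; heavily unbalanced exons push it
  toward conservatism (covered by the Simes route in the union).
- The static-cut module detection is simpler than dynamic tree cutting;
  see the soft-threshold caveat above.
- The simulator's compositional softmax means planted log2FCs are
  realized up to a recorded global shift; recovery is evaluated against
  realized effects.
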