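# Methods

This note documents the models, parameter choices, and numerical
conventions behind `wbtdc`, and what its synthetic benchmarks do and do
not demonstrate about real data.

## Pipeline overview

Training side (the test cohort touches none of these stages):
globin-gene removal → (microarray: probe collapse, IQR filter;
RNA-seq: median-of-ratios log2 transform) → differential expression →
ranked DEG pools → set-size scan → gene-set sampling → per-dataset
enrichment scoring → minority-class oversampling → random-forest
tuning and fit. The fitted model is then applied to the test cohort's
independently computed enrichment scores. A benchmark arm replaces the
enrichment features with the raw expression values of the top 100
upregulated + 100 downregulated DEGs and runs the identical balancing
and tuning protocol.

## Preprocessing

- **Globin removal.** HBB, HBA2 and HBA1 dominate whole-blood RNA by
  orders of magnitude; they are removed from every dataset (absent
  genes are a no-op).
- **Probe collapse.** Per gene, the probe with the highest
  across-sample mean is kept; exact ties break to the lexicographically
  smallest probe ID so the operation is deterministic. Collapse
  precedes the IQR filter.
- **IQR filter** (microarray-scale inputs by default). Genes whose
  interquartile range lies at or below the `drop_fraction` (default
  0.25) empirical quantile of all gene IQRs are removed. The cutoff is
  inclusive with linear-interpolation quantiles — ties at the cutoff
  all go — and `drop_fraction = 0` is an explicit identity. A constant
  matrix is an error rather than an empty result.
- **Count transform.** RNA-seq counts are normalized by
  median-of-ratios size factors (reference: per-gene geometric mean
  over genes positive in every sample; library-size fallback when
  fewer than 50 such genes) and mapped to `log2(count/sf + 1)`.
  Factors are normalized to geometric mean 1 so the output scale is
  depth-independent. This is a variance-stabilizing stand-in, not
  DESeq2's VST: the downstream scorer consumes only per-gene
  distributions and within-sample ranks, which the two transforms
  order identically; an externally transformed matrix can be supplied
  with `value_scale="transformed"` to bypass the stage.

## Differential expression

Welch's t-test on log2-scale values with Benjamini–Hochberg
correction; log2FC is the difference of group means. Genes with zero
pooled variance get p = 1 when the means agree and a variance floor of
1e-12 otherwise. The engine is intentionally simple: downstream stages
use only the direction call, the |log2FC| ranking and the padj < 0.05
gate. DESeq2/limma results can be injected as a TSV
(`read_de_table`) when exact replication of those engines matters.
When a direction has fewer significant genes than the pool size, the
pool is padded with non-significant genes of the matching fold-change
sign (warning raised); this keeps the pipeline operational on
null-like data, where the strict alternative would abort.

## Enrichment scoring

Gaussian-kernel CDF (`h_i = s_i/4`, sample SD with n−1 denominator;
constant genes sit at 0.5), symmetric rank statistic
`r_ij = |p/2 − rank_ij|` with ties broken by gene ID for
bit-reproducibility, and a KS-like walk with in-set weights `r^τ`
(τ = 1 default) against a uniform out-of-set step. The default
enrichment score is the signed difference `max(0, max ν) + min(0, min ν)`;
the single maximum deviation (`max_dev`) is also implemented. The walk
closes at zero by construction; |ES| ≤ 1 always. A set whose members
all sit exactly mid-list has zero in-set mass and scores the pure
out-of-set deficit — a documented degenerate case. The kcdf is an
exact O(n²)-per-gene computation evaluated in gene chunks; kcdf and
ranks are computed once per matrix and shared across all sets and
scan repetitions.

Two properties matter for cross-platform transfer: scores are exactly
invariant to per-gene positive affine transforms of the input, and
each dataset is scored on its own matrix (the kernel CDF is a
cross-sample statistic, so adding samples changes existing scores — a
regression test pins this).

## Set-size scan

For each size in the grid (default 24 values, 10–1000, dense where
whole-blood optima tend to fall) and each direction, random subsets of
the DEG pool are scored and the disease/control separation of their
enrichment scores summarized by a two-sided Wilcoxon rank-sum p-value
(exact when min(n) ≤ 8 and tie-free, otherwise normal approximation
with tie and continuity correction). The chosen size is the smallest
member of the longest contiguous run of sizes whose median −log10 p
stays within 95% of the maximum — operationalizing "separation has
stabilized"; with strong signal the statistic saturates at the
rank-sum floor for the sample size, and the rule returns the smallest
size reaching that floor.

The raw in-sample p-values are selection-biased: the pools are ranked
on the very samples being scanned, so even pure noise yields extreme
p-values (at n = 120 and 2000 genes, the null median reaches ~1e-16).
The scan's `stable_significance` verdict is therefore calibrated by
selection-aware label permutation: labels are permuted, pools
re-derived from scratch, the scan statistic recomputed (5 permutations,
reusing the label-free kcdf/rank stage), and the flag raised only when
the observed peak median −log10 p exceeds the permutation null's best
peak by 2 orders of magnitude. On null data this flag stays down; the
chosen size itself is reported regardless. Score normality is assessed
(Shapiro–Wilk, deterministic thinning above n = 5000) and recorded,
but the rank-sum test is used unconditionally — enrichment-score
distributions are routinely non-normal.

## Balancing and classification

ROSE-style smoothed bootstrap: synthetic minority rows are real rows
plus independent per-feature Gaussian noise with the multivariate
rule-of-thumb bandwidth `σ_q (4/((d+2) n_min))^{1/(d+4)}`, bringing
class counts to equality while preserving all originals. Balancing is
training-only; the pipeline asserts test-sample disjointness.
Balancing precedes CV splitting, matching the simplest reading of the
original protocol; this leaks smoothed copies across folds and can
flatter CV accuracy, so fold-internal balancing is the recommended
alternative for new studies (disable with `balance=False` and balance
per fold externally).

The classifier is a random forest (1000 trees by default, tree count
not tuned). Tuning: repeated stratified k-fold CV (10 × 3 default)
over features-per-split (√d-centred candidates) and
min-samples-to-split {2, 5, 10, 20}; highest mean CV accuracy wins,
ties to the smaller mtry then smaller min_n; the winner is refit on
all training rows. Disease probability is the tree-vote fraction;
accuracy and the confusion matrix use threshold 0.5; ROC-AUC uses the
Mann–Whitney identity with half credit for ties.

## Synthetic cohort pairs

The generator emulates the cross-platform study design: a training
cohort of RNA-seq-like negative-binomial counts and a test cohort of
microarray-like log2 intensities sharing one disease signal.

- Baselines `mu_g` are log-normal(ln 100, 1); per-gene log2 effects are
  `effect_mean × U(0.5, 1.5)` with 100 up + 100 down genes spread
  evenly across the expression range (so the IQR filter cannot remove
  the signal wholesale).
- A latent per-subject factor (SD 1) with per-gene loadings models
  cell-composition variability — the dominant covariance in whole
  blood. DE genes load on it in their effect direction
  (coupling 0.4): disease markers in blood are largely
  immune-cell-fraction markers, so healthy composition variation is
  common-mode noise along the signal axis. This is what keeps
  single-dataset performance realistically below 1 and disease/control
  overlapping in the leading principal components.
- Training counts: NB dispersion 0.3 (human-cohort heterogeneity, not
  technical replicates) with log-normal depth factors (SD 0.2).
- Test intensities: `log2(mu 2^{effect+latent} + floor) + N(0, 0.8)`.
- Platform shift (disease-independent by construction): per-gene
  affine jitter on the log2 scale (slope SD 0.3 around 1, offset SD 3 —
  cross-technology per-gene levels are essentially incomparable), a
  global monotone compression (x → x^0.8 on the linear scale), and an
  array detection floor at the median baseline (~50% of transcripts
  below background, matching typical array present-call rates). The
  floor is the asymmetric ingredient: sub-floor genes carry no array
  signal, which turns trained raw-expression features into noise,
  while the enrichment walk's `r^τ` weighting automatically
  down-weights dead mid-rank genes, so set features degrade
  gracefully. Purely affine distortions, by contrast, leave per-gene
  information intact and barely move a random forest's ranking — they
  cost calibration, not AUC.

What the synthetic benchmarks show: the direction and rough size of
the cross-platform effect under a controlled, disease-independent
shift, null calibration, and recovery of a planted set-size optimum.
What they do not show: performance on real cohorts, where effect
heterogeneity between populations, probe-level cross-hybridization,
normalization pipelines, and confounded batch structure all add
failure modes the generator does not model.

## Problem sizes and the reduced profile

Simulation studies and the acceptance script use
`PipelineConfig.fast_profile`: a 6-value size grid × 20 scan reps per
direction, a 2 × 2 forest grid with 200 trees, and 5-fold
single-repeat CV, on the generator's default sizes (2000 genes,
60 + 60 training and 40 + 40 test samples, 100 + 100 DE genes). These
sizes were chosen so that many seeded replicates run on a single CPU;
the full-size defaults (24-size grid, 500 reps, 1000 trees, 10 × 3 CV)
are the recommended settings for real analyses.

## Determinism

Every stochastic stage draws from a generator spawned from the single
config seed via `numpy.random.SeedSequence`, and reruns with the same
config produce byte-identical manifests and metric reports. Wall-clock
timestamps in the run manifest are opt-in for exactly this reason.

## Known limitations

- The DE engine is a Welch t-test, not a count model; very small
  cohorts or strongly dispersed genes are better served by injecting a
  DESeq2/limma table.
- The scan's chosen size inherits the plateau rule's 95% threshold;
  flat significance curves (weak signal) make the choice unstable
  between adjacent sizes (the chosen range is reported for exactly
  this reason).
- Balancing before CV (see above).
- Enrichment features built from heavily overlapping sets are strongly
  collinear; the forest cannot exploit gene-level contrasts to cancel
  latent factors the way raw-expression models sometimes can, which
  costs a few AUC points in the same-platform setting — the price of
  the representation's transfer robustness.
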