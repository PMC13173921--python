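# wbtdc — whole-blood transcriptomics disease classification

`wbtdc` builds disease classifiers from whole-blood gene-expression
matrices that keep working when the test cohort comes from a different
study — or a different assay technology — than the training cohort.

Whole-blood transcriptomes are attractive for non-invasive diagnosis but
notoriously hard to model across cohorts: samples cluster by study and
platform rather than by disease status, per-gene effects are weak
relative to between-subject variability (dominated by immune-cell
composition), and raw expression values are not comparable between
RNA-seq counts and microarray intensities. `wbtdc` addresses this with a
rank-based feature representation: instead of feeding gene expression
values to the classifier, it feeds per-sample **gene-set enrichment
scores** computed by a from-scratch GSVA (gene set variation analysis)
scorer over gene sets resampled from the training cohort's top
differentially expressed genes. Because the scores depend only on
within-dataset ranks, they are exactly invariant to per-gene affine
distortions of the input — the dominant component of platform shift.

## The method

For gene *i* with values `x_i1..x_in` across the *n* samples of one
dataset, the Gaussian-kernel CDF places each sample on a comparable
scale (bandwidth `h_i = s_i / 4`, the per-gene sample SD over 4):

```
z_ij = (1/n) Σ_k Φ((x_ij − x_ik) / h_i)
```

Per sample, genes are ranked by `z` (descending) and weighted by their
distance from the middle of the list, `r_ij = |p/2 − rank_ij|`. For a
gene set γ, a Kolmogorov–Smirnov-like walk over the ranked list
accumulates normalized in-set weights `r^τ` against a uniform
out-of-set penalty `1/(p − |γ|)`; the enrichment score is the signed
sum of the walk's extremes (`max(0, max ν) + min(0, min ν)`), in [−1, 1].

The gene sets themselves are data-driven: differential expression
(Welch *t* on log2-scale values, Benjamini–Hochberg correction) ranks
genes by |log2FC|; a resampling scan over candidate set sizes (default
24 sizes from 10 to 1000, 500 subsets per direction per size, Wilcoxon
rank-sum separation of disease vs control scores) picks the size where
separation stabilizes; then 100 upregulated + 100 downregulated sets of
that size are sampled from the top-200 pools. Class imbalance is
handled by ROSE-style smoothed-bootstrap oversampling of the training
minority class, and a random forest is tuned by repeated stratified
cross-validation over features-per-split and min-samples-to-split. A
benchmark arm feeds the raw expression of the top 100 + 100 DEGs
through the identical protocol, isolating the effect of the feature
representation.

## Worked example

No data downloads are needed: the package ships a synthetic cohort-pair
generator that emulates the cross-platform setting (RNA-seq-like
training counts, microarray-like test intensities, shared disease
signal, latent cell-composition variation, and a disease-independent
platform shift).

```python
from wbtdc import PipelineConfig, run_wbt_dc, simulate_cohort_pair

train_m, train_p, test_m, test_p, truth = simulate_cohort_pair(seed=3)
cfg = PipelineConfig.fast_profile(seed=3)
res = run_wbt_dc(cfg, train_m, train_p, test_m, test_p)
print(f"enrichment-feature arm: AUC={res.metrics_wbtdc.roc_auc:.3f}")
print(f"conventional arm:       AUC={res.metrics_conventional.roc_auc:.3f}")
print(f"chosen gene-set size:   {res.scan.chosen_size}")
```

Output:

```
enrichment-feature arm: AUC=0.993
conventional arm:       AUC=0.675
chosen gene-set size:   50
```

The enrichment-feature arm retains higher test AUC under the platform
shift; with the shift switched off (`platform_shift=None`) both arms
score above 0.9. `examples/` contains one short script per capability
(simulation, preprocessing, differential expression, the size scan,
GSVA scoring, balancing, classification, and the full pipeline), and the
`wbtdc` command exposes the same stages from the shell
(`wbtdc simulate`, `wbtdc run`, ...).

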