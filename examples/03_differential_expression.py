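"""Differential expression and ranked DEG pools.

Simulates a cohort, transforms the counts, runs the Welch-t/BH engine
and prints the direction calls and the top of each DEG pool.
"""

from wbtdc import (
    differential_expression,
    rank_degs,
    simulate_cohort_pair,
    transform_counts,
)

train_m, train_p, *_ = simulate_cohort_pair(seed=11)
transformed, _ = transform_counts(train_m)
de = differential_expression(transformed, train_p, padj_cutoff=0.05)

counts = de.table["direction"].value_counts()
print("direction calls:", counts.to_dict())

pools = rank_degs(de, pool_size=200)
print("top 5 upregulated (by |log2FC|):", pools.up[:5])
print("top 5 downregulated:            ", pools.down[:5])
# These pools are the sampling universe for the gene-set features; the
# |log2FC| ranking concentrates the pipeline on the strongest markers.
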