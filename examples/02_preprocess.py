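"""Preprocess matrices: globin removal, probe collapse, IQR filter,
count transform.

Shows each preprocessing stage on small inline matrices and prints the
gene counts in and out.
"""

import numpy as np

from wbtdc import (
    ExpressionMatrix,
    ProbeMap,
    collapse_probes,
    iqr_filter,
    remove_rbc_genes,
    transform_counts,
)

# globin removal: HBB/HBA1/HBA2 dominate whole-blood RNA
m = ExpressionMatrix(
    ["HBB", "HBA1", "IFNG", "TNF"], ["s1", "s2"],
    [[9000, 9500], [8000, 8200], [12, 15], [30, 28]], "counts",
)
clean = remove_rbc_genes(m)
print(f"globin removal: {m.n_genes} -> {clean.n_genes} genes")

# probe collapse: highest-mean probe represents the gene
probes = ExpressionMatrix(
    ["p1", "p2", "p3"], ["s1", "s2"],
    [[5.0, 5.2], [7.1, 7.3], [6.0, 6.1]], "log2_intensity",
)
collapsed = collapse_probes(probes, ProbeMap({"p1": "TNF", "p2": "TNF", "p3": "IL6"}))
print(f"probe collapse: {probes.n_genes} probes -> {collapsed.n_genes} genes "
      f"(TNF kept probe mean {collapsed.values[collapsed.gene_ids.index('TNF')].mean():.2f})")

# IQR filter: drop the least variable quartile (noise on arrays)
rng = np.random.default_rng(0)
arr = ExpressionMatrix(
    [f"g{i}" for i in range(40)], [f"s{j}" for j in range(8)],
    rng.normal(8, np.linspace(0.1, 2.0, 40)[:, None], size=(40, 8)),
    "log2_intensity",
)
filtered = iqr_filter(arr, 0.25)
print(f"IQR filter: {arr.n_genes} -> {filtered.n_genes} genes")

# count transform: median-of-ratios size factors + log2(x/sf + 1)
counts = ExpressionMatrix(
    [f"g{i}" for i in range(60)], ["a", "b"],
    np.column_stack([rng.poisson(100, 60), rng.poisson(200, 60)]).astype(float),
    "counts",
)
transformed, params = transform_counts(counts)
print(f"size factors: {np.round(params.size_factors, 3)} "
      "(sample b sequenced ~2x deeper; factors correct for depth)")
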