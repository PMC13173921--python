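"""Matrix-level preprocessing.

Whole-blood RNA is dominated by erythrocyte globin transcripts; the three
globin genes (HBB, HBA2, HBA1) are removed from every dataset up front so
their overwhelming abundance does not distort ranks or fold changes.
Microarray-style matrices are probe-collapsed (highest-mean probe wins)
and noise-filtered by dropping the lowest quartile of per-gene IQRs.
RNA-seq counts are placed on a stable log2 scale by median-of-ratios
normalization followed by log2(x/sf + 1) — a variance-stabilizing
stand-in that preserves the per-gene distributions and within-sample
ranks the downstream enrichment scorer consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import ExpressionMatrix, ProbeMap, ValidationError

DEFAULT_RBC_GENES = frozenset({"HBB", "HBA2", "HBA1"})


@dataclass
class TransformParams:
    """Normalization bookkeeping returned by :func:`transform_counts`.

    size_factors are per-sample scale estimates normalized to geometric
    mean 1; reference_gene_count is how many all-positive genes backed the
    median-of-ratios reference (0 when the library-size fallback fired).
    """

    size_factors: np.ndarray
    pseudocount: float
    reference_gene_count: int


def remove_rbc_genes(
    m: ExpressionMatrix, rbc_genes: frozenset[str] | set[str] = DEFAULT_RBC_GENES
) -> ExpressionMatrix:
    """Drop red-blood-cell globin genes; absent genes are a no-op."""
    keep = [g for g in m.gene_ids if g not in rbc_genes]
    removed = m.n_genes - len(keep)
    if removed == 0:
        return m
    warnings.warn(f"removed {removed} red-blood-cell genes", stacklevel=2)
    return m.subset_genes(keep)


def restrict_to_coding(m: ExpressionMatrix, coding_list: set[str]) -> ExpressionMatrix:
    """Keep protein-coding genes; for counts, additionally drop all-zero rows."""
    if not coding_list:
        raise ValidationError("coding_list must be nonempty")
    out = m.subset_genes([g for g in m.gene_ids if g in coding_list])
    if out.value_scale == "counts":
        nonzero = out.values.sum(axis=1) > 0
        out = out.subset_genes([g for g, nz in zip(out.gene_ids, nonzero) if nz])
    if out.n_genes == 0:
        raise ValidationError("no genes survive the coding-gene restriction")
    return out


def collapse_probes(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """One row per gene: the probe with the highest across-sample mean.

    Unmapped probes are dropped with a warning; exact mean ties break to
    the lexicographically smallest probe ID. Output rows are sorted by
    gene ID for determinism.
    """
    unmapped = [p for p in m.gene_ids if p not in pm.mapping]
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} probes without a gene mapping", stacklevel=2
        )
    means = m.values.mean(axis=1)
    # best (probe index) per gene under (-mean, probe_id) ordering
    best: dict[str, int] = {}
    for i, probe in enumerate(m.gene_ids):
        gene = pm.mapping.get(probe)
        if gene is None:
            continue
        j = best.get(gene)
        if (
            j is None
            or means[i] > means[j]
            or (means[i] == means[j] and probe < m.gene_ids[j])
        ):
            best[gene] = i
    genes = sorted(best)
    idx = [best[g] for g in genes]
    return ExpressionMatrix(
        genes, list(m.sample_ids), m.values[idx, :], m.value_scale, m.platform_tag
    )


def gene_iqr(values: np.ndarray) -> np.ndarray:
    """Per-gene interquartile range (linear-interpolation quantiles)."""
    q75, q25 = np.percentile(values, [75, 25], axis=1)
    return q75 - q25


def iqr_filter(m: ExpressionMatrix, drop_fraction: float = 0.25) -> ExpressionMatrix:
    """Remove genes whose IQR falls in the lowest ``drop_fraction`` quantile.

    Inclusive cutoff: genes with IQR <= the empirical ``drop_fraction``
    quantile of all gene IQRs are removed, so ties at the cutoff all go.
    ``drop_fraction = 0`` is an explicit no-op.
    """
    if not 0 <= drop_fraction < 1:
        raise ValidationError("drop_fraction must lie in [0, 1)")
    if m.n_samples < 4:
        raise ValidationError("IQR filter needs at least 4 samples")
    if drop_fraction == 0:
        return m
    iqrs = gene_iqr(m.values)
    cutoff = np.quantile(iqrs, drop_fraction)
    keep = iqrs > cutoff
    if not keep.any():
        raise ValidationError(
            "IQR filter would remove every gene (all IQRs tie at the cutoff)"
        )
    return m.subset_genes([g for g, k in zip(m.gene_ids, keep) if k])


def transform_counts(
    m: ExpressionMatrix, pseudocount: float = 1.0, min_reference_genes: int = 50
) -> tuple[ExpressionMatrix, TransformParams]:
    """Normalize counts and move to log2 scale: log2(count/sf + pseudocount).

    Size factors come from the median-of-ratios rule (reference = per-gene
    geometric mean over genes positive in every sample). When fewer than
    ``min_reference_genes`` genes are all-positive the library-size
    fallback is used. Either way factors are normalized to geometric
    mean 1 so the output scale is depth-independent.
    """
    if m.value_scale != "counts":
        raise ValidationError("transform_counts requires a counts matrix")
    totals = m.values.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(m.sample_ids, totals) if t == 0]
        raise ValidationError(f"samples with zero total count: {bad[:5]}")

    all_pos = (m.values > 0).all(axis=1)
    n_ref = int(all_pos.sum())
    if n_ref >= min_reference_genes:
        logs = np.log(m.values[all_pos, :])
        ref_log = logs.mean(axis=1)  # log geometric mean per gene
        sf = np.exp(np.median(logs - ref_log[:, None], axis=0))
    else:
        sf = totals.astype(float)
        n_ref = 0
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    transformed = np.log2(m.values / sf[None, :] + pseudocount)
    out = m.replace_values(transformed, value_scale="transformed")
    return out, TransformParams(sf, pseudocount, n_ref)
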