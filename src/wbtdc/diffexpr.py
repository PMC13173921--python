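"""Differential expression and ranked DEG pools.

The engine is deliberately simple: on log2-scale values, the per-gene fold
change is the difference of group means and the p-value a two-sided Welch
t-test, corrected by Benjamini-Hochberg. Downstream stages only consume the
direction calls, the |log2FC| ranking and the padj < cutoff gate, so a
full count-model GLM or moderated-t engine is unnecessary here; an
externally computed DE table (e.g. from DESeq2 or limma) can be injected
via :func:`read_de_table` to reproduce those engines exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix, PhenotypeTable, ValidationError

_VAR_FLOOR = 1e-12  # variance floor for degenerate zero-variance genes


@dataclass
class DeTable:
    """Per-gene DE results: log2fc (disease − control), p, BH padj, direction."""

    table: pd.DataFrame  # columns: gene_id, log2fc, pvalue, padj, direction

    REQUIRED = ("gene_id", "log2fc", "pvalue", "padj", "direction")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"DE table missing columns: {missing}")
        if self.table["gene_id"].duplicated().any():
            raise ValidationError("DE table has duplicate gene IDs")
        bad = ~self.table["direction"].isin(["up", "down", "ns"])
        if bad.any():
            raise ValidationError(
                f"invalid direction values: {self.table.loc[bad, 'direction'].unique()}"
            )
        self.table = self.table.reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_de_table(path: str | Path) -> DeTable:
    """Load an externally computed DE table (TSV with the DeTable columns)."""
    return DeTable(pd.read_csv(path, sep="\t"))


@dataclass
class RankedDegPools:
    """Top up/down gene lists ordered by |log2fc| descending (ties: gene ID)."""

    up: list[str]
    down: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(f"up/down pools overlap: {sorted(overlap)[:5]}")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvalues must be a nonempty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t-test per row; zero-variance rows handled.

    Both groups constant and equal → p = 1; otherwise the pooled standard
    error is floored at sqrt(_VAR_FLOOR) so a real mean shift still yields
    a (tiny) p-value.
    """
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 <= 0
    se2 = np.where(degenerate, _VAR_FLOOR, se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            np.where(v1 > 0, (v1 / n1) ** 2 / (n1 - 1), 0)
            + np.where(v2 > 0, (v2 / n2) ** 2 / (n2 - 1), 0)
        )
    df = np.where(degenerate, n1 + n2 - 2, df)
    df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def differential_expression(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    padj_cutoff: float = 0.05,
) -> DeTable:
    """Per-gene Welch t DE on a log2-like matrix.

    direction = up iff padj < cutoff and log2fc > 0; down iff padj < cutoff
    and log2fc < 0; ns otherwise.
    """
    if m.value_scale == "counts":
        raise ValidationError(
            "differential_expression needs a log2-like matrix; run transform_counts first"
        )
    pheno.require_both_levels()
    dz = pheno.is_disease(m.sample_ids)
    if dz.sum() < 2 or (~dz).sum() < 2:
        raise ValidationError("need at least 2 samples per group")
    x, y = m.values[:, dz], m.values[:, ~dz]
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    pvalue = _welch(x, y)
    padj = bh_adjust(pvalue)
    direction = np.where(
        (padj < padj_cutoff) & (log2fc > 0),
        "up",
        np.where((padj < padj_cutoff) & (log2fc < 0), "down", "ns"),
    )
    return DeTable(
        pd.DataFrame(
            {
                "gene_id": m.gene_ids,
                "log2fc": log2fc,
                "pvalue": pvalue,
                "padj": padj,
                "direction": direction,
            }
        )
    )


def _ordered(df: pd.DataFrame) -> list[str]:
    df = df.assign(absfc=df["log2fc"].abs())
    df = df.sort_values(["absfc", "gene_id"], ascending=[False, True])
    return list(df["gene_id"])


def rank_degs(
    de: DeTable, pool_size: int = 200, allow_padding: bool = True
) -> RankedDegPools:
    """Top ``pool_size`` up and down genes by |log2fc|.

    When a direction has fewer than ``pool_size`` significant genes the pool
    is padded with non-significant genes of the matching fold-change sign
    (still ranked by |log2fc|) and a warning is raised; with
    ``allow_padding=False`` an empty significant list is an error instead.
    """
    t = de.table
    pools: dict[str, list[str]] = {}
    for direction, sign in (("up", 1), ("down", -1)):
        sig = t[t["direction"] == direction]
        ordered = _ordered(sig)
        if len(ordered) < pool_size:
            if not allow_padding and len(ordered) == 0:
                raise ValidationError(
                    f"no significant {direction}-regulated genes; consider relaxing "
                    "the padj cutoff or supplying an external DE table"
                )
            pad_from = t[(t["direction"] == "ns") & (sign * t["log2fc"] > 0)]
            pad = [g for g in _ordered(pad_from) if g not in set(ordered)]
            needed = pool_size - len(ordered)
            if len(ordered) < pool_size:
                warnings.warn(
                    f"only {len(ordered)} significant {direction} genes; padding "
                    f"with {min(needed, len(pad))} non-significant same-sign genes",
                    stacklevel=2,
                )
            ordered = ordered + pad[:needed]
        if not ordered:
            raise ValidationError(
                f"no genes available for the {direction} pool at all"
            )
        pools[direction] = ordered[:pool_size]
    return RankedDegPools(up=pools["up"], down=pools["down"])
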