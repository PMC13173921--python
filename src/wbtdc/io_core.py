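"""Tabular I/O and the typed containers every pipeline stage exchanges.

The universal currency is :class:`ExpressionMatrix` — a genes × samples
numeric matrix tagged with the scale its values live on (``counts`` for
RNA-seq-like data, ``log2_intensity`` for microarray-like data,
``transformed`` for normalized log2 counts).  Matrices travel as
tab-separated UTF-8 text with genes as rows, the dominant orientation of
public series matrices; ``transpose=True`` handles samples-as-rows files.

Missing values are rejected at load time rather than imputed: the pipeline
has no imputation model and silently guessing one would contaminate every
downstream rank statistic.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

VALUE_SCALES = ("counts", "log2_intensity", "transformed")

DEFAULT_SIZE_GRID = (
    10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 125, 150,
    175, 200, 250, 300, 350, 400, 500, 600, 700, 800, 900, 1000,
)


class ValidationError(ValueError):
    """Raised when an artifact violates its container invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix with a value-scale tag.

    Parameters
    ----------
    gene_ids
        Unique row identifiers (genes or, pre-collapse, probes).
    sample_ids
        Unique column identifiers.
    values
        2-D float array, shape ``(len(gene_ids), len(sample_ids))``.
    value_scale
        One of ``counts``, ``log2_intensity``, ``transformed``.
    platform_tag
        Free-text provenance string (e.g. ``"rnaseq"``, ``"illumina_array"``).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_scale: str
    platform_tag: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if self.value_scale not in VALUE_SCALES:
            raise ValidationError(
                f"value_scale must be one of {VALUE_SCALES}, got {self.value_scale!r}"
            )
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"missing value at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.value_scale == "counts":
            if (self.values < 0).any():
                raise ValidationError("count matrix contains negative values")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("count matrix contains non-integral values")

    # -- convenience ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, value_scale: str, platform_tag: str = ""
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            value_scale=value_scale,
            platform_tag=platform_tag,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` keeping the current row order."""
        keep = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :],
            self.value_scale,
            self.platform_tag,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``samples`` in the given order."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.sample_ids[j] for j in idx],
            self.values[:, idx],
            self.value_scale,
            self.platform_tag,
        )

    def replace_values(self, values: np.ndarray, value_scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.sample_ids),
            values,
            value_scale or self.value_scale,
            self.platform_tag,
        )


@dataclass
class PhenotypeTable:
    """Sample → {disease, control} assignment."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample IDs")
        if len(self.labels) != len(self.sample_ids):
            raise ValidationError("labels and sample_ids length mismatch")
        norm = []
        for lab in self.labels:
            low = str(lab).strip().lower()
            if low not in ("disease", "control"):
                raise ValidationError(
                    f"unknown phenotype label {lab!r}: expected 'disease' or 'control'"
                )
            norm.append(low)
        self.labels = norm

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def label_map(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.labels))

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        m = self.label_map
        return np.array([m[s] for s in samples])

    def is_disease(self, samples: Sequence[str] | None = None) -> np.ndarray:
        samples = self.sample_ids if samples is None else samples
        return self.labels_for(samples) == "disease"

    def subset(self, samples: Sequence[str]) -> "PhenotypeTable":
        m = self.label_map
        return PhenotypeTable(list(samples), [m[s] for s in samples])

    def require_both_levels(self) -> None:
        levels = set(self.labels)
        if levels != {"disease", "control"}:
            raise ValidationError(
                f"training use requires both label levels, found {sorted(levels)}"
            )


@dataclass
class ProbeMap:
    """probe → gene mapping; many probes may map to one gene."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def read_expression(
    path: str | Path,
    value_scale: str,
    platform_tag: str = "",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Load a TSV expression matrix (first column IDs, header sample IDs).

    Non-numeric or missing cells are rejected with the offending
    row/column coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        raw = raw.T
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        cell = raw.iat[i, j]
        raise ValidationError(
            f"non-numeric cell {cell!r} at row {raw.index[i]!r} "
            f"(row {i + 2}), column {raw.columns[j]!r} (column {j + 2}) in {path}"
        )
    return ExpressionMatrix.from_frame(numeric, value_scale, platform_tag)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_phenotype(
    path: str | Path, expression: ExpressionMatrix | None = None
) -> tuple[PhenotypeTable, list[str]]:
    """Load a two-column (sample_id, label) TSV/CSV.

    Labels are normalized case-insensitively to ``disease``/``control``.
    Returns the table plus a warning list of samples absent from
    ``expression`` (empty if no matrix was supplied).
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValidationError("phenotype file needs two columns: sample_id, label")
    first = str(df.iloc[0, 0]).strip().lower()
    if first in ("sample_id", "sample", "id"):  # tolerate a header row
        df = df.iloc[1:]
    table = PhenotypeTable(list(df.iloc[:, 0]), list(df.iloc[:, 1]))
    missing: list[str] = []
    if expression is not None:
        present = set(expression.sample_ids)
        missing = [s for s in table.sample_ids if s not in present]
        if missing:
            warnings.warn(
                f"{len(missing)} phenotype samples absent from expression matrix: "
                f"{missing[:5]}", stacklevel=2,
            )
    return table, missing


def write_phenotype(pheno: PhenotypeTable, path: str | Path) -> None:
    pd.DataFrame({"sample_id": pheno.sample_ids, "label": pheno.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_probe_map(path: str | Path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError("probe map needs two columns: probe_id, gene_id")
    first = str(df.iloc[0, 0]).strip().lower()
    if first in ("probe_id", "probe"):
        df = df.iloc[1:]
    probes = list(df.iloc[:, 0])
    _check_unique(probes, "probe IDs")
    return ProbeMap(dict(zip(probes, df.iloc[:, 1])))


def read_gene_list(path: str | Path) -> set[str]:
    """One gene ID per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def align(
    m: ExpressionMatrix, pheno: PhenotypeTable
) -> tuple[ExpressionMatrix, PhenotypeTable]:
    """Restrict matrix and phenotype to their sample intersection.

    Ordering follows the matrix's column order; idempotent.
    """
    keep = [s for s in m.sample_ids if s in set(pheno.sample_ids)]
    if not keep:
        raise ValidationError("expression matrix and phenotype share no samples")
    dropped_m = m.n_samples - len(keep)
    dropped_p = len(pheno) - len(keep)
    if dropped_m or dropped_p:
        warnings.warn(
            f"align dropped {dropped_m} matrix samples and {dropped_p} phenotype samples",
            stacklevel=2,
        )
    return m.subset_samples(keep), pheno.subset(keep)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable the pipeline exposes, with the defaults used throughout.

    A single ``seed`` feeds a :class:`numpy.random.SeedSequence`; each
    stochastic stage receives its own spawned generator, so any one stage
    is reproducible independently of the others.
    """

    padj_cutoff: float = 0.05
    pool_size: int = 200
    n_sets_per_direction: int = 100
    size_grid: tuple[int, ...] = DEFAULT_SIZE_GRID
    scan_reps_per_direction: int = 500
    # GSVA
    gsva_tau: float = 1.0
    gsva_es_mode: str = "signed_diff"
    # random forest
    rf_n_trees: int = 1000
    rf_mtry_candidates: tuple[int, ...] | None = None  # None -> sqrt(d)-centred default
    rf_min_n_candidates: tuple[int, ...] = (2, 5, 10, 20)
    cv_folds: int = 10
    cv_repeats: int = 3
    # balancing
    balance: bool = True
    balance_shrink: float = 1.0
    # preprocessing
    rbc_genes: tuple[str, ...] = ("HBB", "HBA2", "HBA1")
    iqr_drop_fraction: float = 0.25
    iqr_on_rnaseq: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.padj_cutoff < 1:
            raise ValidationError("padj_cutoff must lie in (0, 1)")
        for name in ("pool_size", "n_sets_per_direction", "scan_reps_per_direction",
                     "rf_n_trees", "cv_folds", "cv_repeats"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        self.size_grid = tuple(int(s) for s in self.size_grid)
        if any(s <= 0 for s in self.size_grid):
            raise ValidationError("size_grid values must be positive")
        self.rf_min_n_candidates = tuple(int(v) for v in self.rf_min_n_candidates)
        if self.rf_mtry_candidates is not None:
            self.rf_mtry_candidates = tuple(int(v) for v in self.rf_mtry_candidates)
        self.rbc_genes = tuple(str(g) for g in self.rbc_genes)

    @classmethod
    def fast_profile(cls, seed: int = 0) -> "PipelineConfig":
        """Reduced problem-size profile for simulation studies.

        A 6-value size grid with 20 scan reps per direction, a 2×2 forest
        grid with 200 trees, and 5-fold single-repeat CV — small enough to
        run many seeded replicates on one CPU while exercising every stage.
        """
        return cls(
            size_grid=(10, 20, 50, 100, 150, 200),
            scan_reps_per_direction=20,
            rf_n_trees=200,
            rf_mtry_candidates=(15, 28),
            rf_min_n_candidates=(2, 10),
            cv_folds=5,
            cv_repeats=1,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
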