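"""End-to-end orchestration of the classification pipeline.

Order of stages: preprocess → differential expression → set-size scan →
gene-set sampling → enrichment scoring → class balancing → tuned
random-forest fit → prediction on the held-out cohort → metrics, with a
parallel benchmark arm that feeds raw top-DEG expression values through
the identical balancing/tuning protocol.

Information-flow hygiene is enforced, not assumed: the test cohort never
touches DE, the scan, set sampling, balancing, or tuning, and the run
aborts if train and test share a sample ID. Every stage logs row/column
counts and a content checksum into a :class:`RunManifest`; two runs with
the same config and seed produce byte-identical manifests (wall-clock
timestamps are opt-in for exactly that reason).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balance import rose_oversample
from .classify import (
    MetricsReport,
    RfGrid,
    TunedModel,
    compute_metrics,
    conventional_features,
    predict_scores,
    tune_and_fit,
)
from .diffexpr import DeTable, differential_expression, rank_degs
from .genesets import SizeScanResult, sample_gene_sets, scan_set_sizes
from .gsva import GsvaParams, gsva_scores
from .io_core import (
    ExpressionMatrix,
    PhenotypeTable,
    PipelineConfig,
    ValidationError,
    align,
)
from .preprocess import iqr_filter, remove_rbc_genes, transform_counts


def _checksum(obj) -> str:
    if isinstance(obj, ExpressionMatrix):
        payload = obj.to_frame().to_csv(sep="\t", float_format="%.10g")
    elif isinstance(obj, pd.DataFrame):
        payload = obj.to_csv(sep="\t", float_format="%.10g")
    elif isinstance(obj, np.ndarray):
        payload = np.array2string(obj, precision=10, threshold=10**7)
    else:
        payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Config snapshot, seed, and per-stage I/O accounting with checksums."""

    config: dict
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    timestamps: dict = field(default_factory=dict)

    def log(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
                "timestamps": self.timestamps,
            },
            sort_keys=True,
            indent=1,
            default=str,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.json())


@dataclass
class PipelineResult:
    metrics_wbtdc: MetricsReport
    metrics_conventional: MetricsReport
    manifest: RunManifest
    de_table: DeTable
    scan: SizeScanResult
    model_wbtdc: TunedModel
    model_conventional: TunedModel


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Independent per-stage integer seeds (< 2^31) from the run seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _prepare(m: ExpressionMatrix, cfg: PipelineConfig, manifest: RunManifest, tag: str) -> ExpressionMatrix:
    """Globin removal, microarray IQR filter, count transform — per cohort."""
    m = remove_rbc_genes(m, set(cfg.rbc_genes))
    if m.value_scale == "log2_intensity" or (
        m.value_scale == "counts" and cfg.iqr_on_rnaseq
    ):
        if cfg.iqr_drop_fraction > 0 and m.n_samples >= 4:
            before = m.n_genes
            m = iqr_filter(m, cfg.iqr_drop_fraction)
            manifest.log(
                f"iqr_filter[{tag}]", genes_in=before, genes_out=m.n_genes,
                checksum=_checksum(m),
            )
    if m.value_scale == "counts":
        m, params = transform_counts(m)
        manifest.log(
            f"transform_counts[{tag}]",
            reference_gene_count=params.reference_gene_count,
            size_factor_range=[float(params.size_factors.min()),
                               float(params.size_factors.max())],
            checksum=_checksum(m),
        )
    return m


def run_wbt_dc(
    config: PipelineConfig,
    train_matrix: ExpressionMatrix,
    train_pheno: PhenotypeTable,
    test_matrix: ExpressionMatrix,
    test_pheno: PhenotypeTable,
    workdir: str | Path | None = None,
    record_timestamps: bool = False,
) -> PipelineResult:
    """Run both arms end to end and report test-set metrics for each.

    All randomness derives from ``config.seed`` via independently spawned
    per-stage generators; reruns are bit-reproducible.
    """
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    if record_timestamps:
        manifest.timestamps["started"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    seeds = _stage_seeds(config.seed)

    train_matrix, train_pheno = align(train_matrix, train_pheno)
    test_matrix, test_pheno = align(test_matrix, test_pheno)
    overlap = set(train_matrix.sample_ids) & set(test_matrix.sample_ids)
    if overlap:
        raise ValidationError(
            f"train and test cohorts share sample IDs: {sorted(overlap)[:5]}"
        )
    train_pheno.require_both_levels()
    manifest.log(
        "align", n_train=train_matrix.n_samples, n_test=test_matrix.n_samples,
        train_checksum=_checksum(train_matrix), test_checksum=_checksum(test_matrix),
    )

    train_m = _prepare(train_matrix, config, manifest, "train")
    test_m = _prepare(test_matrix, config, manifest, "test")

    # ---- training-side feature construction (test never enters) -----
    de = differential_expression(train_m, train_pheno, config.padj_cutoff)
    n_up = int((de.table["direction"] == "up").sum())
    n_down = int((de.table["direction"] == "down").sum())
    manifest.log("differential_expression", n_up=n_up, n_down=n_down,
                 checksum=_checksum(de.table))

    pools = rank_degs(de, config.pool_size)
    gsva_params = GsvaParams(tau=config.gsva_tau, es_mode=config.gsva_es_mode)

    def _pools_for(perm_pheno):  # selection-aware permutation calibration
        perm_de = differential_expression(train_m, perm_pheno, config.padj_cutoff)
        return rank_degs(perm_de, config.pool_size)

    scan = scan_set_sizes(
        train_m, train_pheno, pools,
        grid=config.size_grid,
        reps_per_direction=config.scan_reps_per_direction,
        seed=seeds[0],
        gsva_params=gsva_params,
        pool_builder=_pools_for,
    )
    manifest.log(
        "scan_set_sizes", chosen_size=scan.chosen_size,
        chosen_range=list(scan.chosen_range),
        stable_significance=scan.stable_significance,
        normality_pvalue=round(scan.normality_pvalue, 6),
        checksum=_checksum(scan.records),
    )

    sets = sample_gene_sets(
        pools, scan.chosen_size,
        n_up=config.n_sets_per_direction, n_down=config.n_sets_per_direction,
        seed=seeds[1],
    )
    manifest.log("sample_gene_sets", n_sets=len(sets), set_size=scan.chosen_size,
                 checksum=sets.checksum())

    # each cohort is scored on its own matrix: per-dataset enrichment
    es_train = gsva_scores(train_m, sets, gsva_params)
    es_test = gsva_scores(test_m, sets, gsva_params)
    manifest.log("gsva_scores", train_checksum=_checksum(es_train.to_frame()),
                 test_checksum=_checksum(es_test.to_frame()))

    result = {}
    for arm, (ftr_train, ftr_test) in {
        "wbtdc": (es_train.features(), es_test.features()),
        "conventional": conventional_features(
            train_m, test_m, de, n_per_direction=config.n_sets_per_direction
        ),
    }.items():
        labels = train_pheno.labels_for(list(ftr_train.index))
        if config.balance:
            balanced = rose_oversample(
                ftr_train, labels, seed=seeds[2], shrink=config.balance_shrink
            )
            assert not set(balanced.source_sample_ids) & set(test_m.sample_ids)
            ftr_fit, labels_fit = balanced.features, balanced.labels
            manifest.log(f"balance[{arm}]",
                         n_synthetic=int(balanced.synthetic_flags.sum()),
                         checksum=_checksum(balanced.features))
        else:
            ftr_fit, labels_fit = ftr_train, labels
        grid = RfGrid.default_for(
            ftr_fit.shape[1],
            mtry_candidates=config.rf_mtry_candidates,
            min_n_candidates=config.rf_min_n_candidates,
            n_trees=config.rf_n_trees,
        )
        model = tune_and_fit(
            ftr_fit, labels_fit, grid,
            folds=config.cv_folds, repeats=config.cv_repeats, seed=seeds[3],
        )
        scores = predict_scores(model, ftr_test)
        metrics = compute_metrics(scores, test_pheno.labels_for(list(ftr_test.index)))
        manifest.log(
            f"evaluate[{arm}]", best_params=list(model.best_params),
            accuracy=round(metrics.accuracy, 10),
            balanced_accuracy=round(metrics.balanced_accuracy, 10),
            roc_auc=round(metrics.roc_auc, 10),
            checksum=_checksum(np.round(scores, 12)),
        )
        result[arm] = (metrics, model)

    if record_timestamps:
        manifest.timestamps["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    out = PipelineResult(
        metrics_wbtdc=result["wbtdc"][0],
        metrics_conventional=result["conventional"][0],
        manifest=manifest,
        de_table=de,
        scan=scan,
        model_wbtdc=result["wbtdc"][1],
        model_conventional=result["conventional"][1],
    )
    if workdir is not None:
        _persist(out, Path(workdir))
    return out


def _persist(res: PipelineResult, workdir: Path) -> None:
    workdir.mkdir(parents=True, exist_ok=True)
    res.manifest.write(workdir / "manifest.json")
    res.de_table.to_tsv(workdir / "de_table.tsv")
    res.scan.to_tsv(workdir / "size_scan.tsv")
    for arm, metrics in (
        ("wbtdc", res.metrics_wbtdc),
        ("conventional", res.metrics_conventional),
    ):
        (workdir / f"metrics_{arm}.json").write_text(
            json.dumps(metrics.to_dict(), sort_keys=True, indent=1)
        )
        pd.DataFrame(
            metrics.roc_points, columns=["fpr", "tpr", "threshold"]
        ).to_csv(workdir / f"roc_{arm}.tsv", sep="\t", index=False)
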