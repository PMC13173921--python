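"""Smoothed-bootstrap class balancing (ROSE-style) for training features.

Synthetic minority-class samples are drawn by picking a real minority row
uniformly at random and perturbing every feature with independent
Gaussian noise whose scale follows the multivariate-normal rule-of-thumb
bandwidth. Balancing is a training-side operation only; the pipeline
asserts test samples never pass through it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ValidationError


@dataclass
class BalancedSet:
    """Training features after minority oversampling.

    Original rows are preserved verbatim; synthetic rows (flagged) exist
    only in the minority class and bring the class counts to equality.
    ``source_sample_ids`` records which real samples fed the stage, for
    the pipeline's train/test-disjointness audit.
    """

    features: pd.DataFrame
    labels: np.ndarray
    synthetic_flags: np.ndarray
    seed: int
    source_sample_ids: list[str]


def rose_bandwidths(minority: np.ndarray, shrink: float = 1.0) -> np.ndarray:
    """Per-feature smoothing SDs h_q = shrink · σ_q · (4/((d+2)·n))^(1/(d+4))."""
    n, d = minority.shape
    sigma = minority.std(axis=0, ddof=1)
    return shrink * sigma * (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))


def rose_oversample(
    features: pd.DataFrame,
    labels: np.ndarray | list[str],
    seed: int = 0,
    shrink: float = 1.0,
) -> BalancedSet:
    """Oversample the minority class to the majority count.

    ``shrink`` scales the kernel bandwidth; 0 degenerates to a plain
    bootstrap (exact duplicates). Already-balanced input passes through
    unchanged. Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=float))
    if not np.isfinite(features.to_numpy()).all():
        raise ValidationError("features must be finite")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValidationError(f"need exactly two classes, found {list(classes)}")
    if counts.min() < 2:
        raise ValidationError("each class needs >= 2 rows (bandwidth undefined)")

    n_needed = int(counts.max() - counts.min())
    source_ids = [str(i) for i in features.index]
    if n_needed == 0:
        return BalancedSet(
            features.copy(), labels.copy(),
            np.zeros(len(labels), dtype=bool), seed, source_ids,
        )

    minority_class = classes[np.argmin(counts)]
    minority = features.to_numpy(dtype=float)[labels == minority_class]
    h = rose_bandwidths(minority, shrink)

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, minority.shape[0], size=n_needed)
    noise = rng.standard_normal((n_needed, minority.shape[1])) * h[None, :]
    synth = minority[picks] + noise

    synth_index = [f"synthetic_{minority_class}_{k + 1}" for k in range(n_needed)]
    out_features = pd.concat(
        [features, pd.DataFrame(synth, index=synth_index, columns=features.columns)]
    )
    out_labels = np.concatenate([labels, np.repeat(minority_class, n_needed)])
    flags = np.concatenate(
        [np.zeros(len(labels), dtype=bool), np.ones(n_needed, dtype=bool)]
    )
    return BalancedSet(out_features, out_labels, flags, seed, source_ids)
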