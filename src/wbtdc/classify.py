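"""Random-forest training, tuning, prediction, metrics, and the
conventional-features benchmark arm.

Tuning follows repeated stratified k-fold cross-validation (default
10-fold × 3 repeats) over a small grid of the two hyperparameters that
matter most for forests on wide expression features: the number of
features considered per split (``mtry``) and the minimum samples required
to split a node (``min_n``). The grid point with the highest mean CV
accuracy wins (ties → smaller mtry, then smaller min_n) and is refit on
the full training set. The disease-class probability of a sample is the
fraction of trees voting disease.

The benchmark arm swaps the enrichment-score features for the raw
expression values of the top 100 up + 100 down DEGs, keeping every other
protocol choice identical, so any performance difference is attributable
to the feature representation alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold

from .diffexpr import DeTable, rank_degs
from .io_core import ExpressionMatrix, ValidationError

POSITIVE = "disease"


@dataclass
class RfGrid:
    """Hyperparameter candidates; ``n_trees`` is fixed, not tuned."""

    mtry_candidates: tuple[int, ...]
    min_n_candidates: tuple[int, ...] = (2, 5, 10, 20)
    n_trees: int = 1000

    @classmethod
    def default_for(
        cls,
        d: int,
        mtry_candidates: tuple[int, ...] | None = None,
        min_n_candidates: tuple[int, ...] = (2, 5, 10, 20),
        n_trees: int = 1000,
    ) -> "RfGrid":
        """√d-centred mtry grid clipped to [1, d], deduplicated."""
        if mtry_candidates is None:
            root = math.ceil(math.sqrt(d))
            raw = [root // 2, root, 2 * root, d // 4]
            mtry_candidates = tuple(sorted({min(max(1, v), d) for v in raw}))
        return cls(tuple(mtry_candidates), tuple(min_n_candidates), n_trees)


@dataclass
class TunedModel:
    best_params: tuple[int, int]  # (mtry, min_n)
    cv_table: pd.DataFrame  # mtry, min_n, mean_accuracy, sd_accuracy
    model: RandomForestClassifier
    feature_names: list[str]
    seed: int


@dataclass
class MetricsReport:
    accuracy: float
    balanced_accuracy: float
    roc_auc: float | None
    roc_points: list[tuple[float, float, float]]  # (fpr, tpr, threshold)
    confusion: np.ndarray  # rows: truth (control, disease); cols: predicted
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "roc_auc": self.roc_auc,
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test,
            "roc_points": [list(p) for p in self.roc_points],
        }


def _as_binary(labels: np.ndarray | list[str]) -> np.ndarray:
    y = np.asarray(labels)
    bad = ~np.isin(y, [POSITIVE, "control"])
    if bad.any():
        raise ValidationError(f"unknown labels: {np.unique(y[bad])}")
    return (y == POSITIVE).astype(int)


def tune_and_fit(
    features: pd.DataFrame,
    labels: np.ndarray | list[str],
    grid: RfGrid | None = None,
    folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> TunedModel:
    """Repeated stratified CV over the grid; refit the winner on all rows."""
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=float))
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("features must be finite")
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels contain a single class")
    grid = grid or RfGrid.default_for(X.shape[1])

    min_class = int(np.bincount(y).min())
    eff_folds = folds
    if min_class < folds:
        eff_folds = max(2, min_class)
        warnings.warn(
            f"reducing CV folds from {folds} to {eff_folds} (smallest class has "
            f"{min_class} samples)", stacklevel=2,
        )

    cv = RepeatedStratifiedKFold(
        n_splits=eff_folds, n_repeats=repeats, random_state=seed
    )
    splits = list(cv.split(X, y))
    rows = []
    for mtry in grid.mtry_candidates:
        for min_n in grid.min_n_candidates:
            if min_n > X.shape[0]:
                continue
            accs = []
            for tr, te in splits:
                clf = RandomForestClassifier(
                    n_estimators=grid.n_trees,
                    max_features=min(mtry, X.shape[1]),
                    min_samples_split=min_n,
                    random_state=seed,
                    n_jobs=1,
                )
                clf.fit(X[tr], y[tr])
                accs.append(float((clf.predict(X[te]) == y[te]).mean()))
            rows.append(
                {
                    "mtry": mtry,
                    "min_n": min_n,
                    "mean_accuracy": float(np.mean(accs)),
                    "sd_accuracy": float(np.std(accs, ddof=1)),
                }
            )
    cv_table = pd.DataFrame(rows)
    # highest mean accuracy; ties -> smaller mtry, then smaller min_n
    best = cv_table.sort_values(
        ["mean_accuracy", "mtry", "min_n"], ascending=[False, True, True]
    ).iloc[0]
    best_params = (int(best["mtry"]), int(best["min_n"]))
    final = RandomForestClassifier(
        n_estimators=grid.n_trees,
        max_features=min(best_params[0], X.shape[1]),
        min_samples_split=best_params[1],
        random_state=seed,
        n_jobs=1,
    )
    final.fit(X, y)
    return TunedModel(
        best_params=best_params,
        cv_table=cv_table,
        model=final,
        feature_names=[str(c) for c in features.columns],
        seed=seed,
    )


def predict_scores(model: TunedModel, test_features: pd.DataFrame) -> np.ndarray:
    """Disease probabilities on name-aligned test features.

    Columns are matched by name: extras dropped with a warning, missing
    columns are an error naming the first few.
    """
    test_features = test_features.rename(columns=str)
    cols = list(test_features.columns)
    missing = [f for f in model.feature_names if f not in set(cols)]
    if missing:
        raise ValidationError(f"test features missing columns: {missing[:10]}")
    extra = [c for c in cols if c not in set(model.feature_names)]
    if extra:
        warnings.warn(f"dropping {len(extra)} extra test feature columns", stacklevel=2)
    X = test_features.loc[:, model.feature_names].to_numpy(dtype=float)
    pos = list(model.model.classes_).index(1)
    return model.model.predict_proba(X)[:, pos]


def mann_whitney_auc(scores: np.ndarray, truth01: np.ndarray) -> float:
    """ROC-AUC via the Mann-Whitney identity; ties get half credit."""
    ranks = rankdata(scores)  # average ranks handle ties
    n_pos = int(truth01.sum())
    n_neg = truth01.size - n_pos
    u = ranks[truth01 == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    scores: np.ndarray,
    truth: np.ndarray | list[str],
    threshold: float = 0.5,
    require_auc: bool = True,
) -> MetricsReport:
    """Accuracy / balanced accuracy at ``threshold``; AUC and ROC points.

    With one-class truth the AUC is undefined: an error by default, or
    ``roc_auc=None`` with empty ROC when ``require_auc=False``.
    """
    scores = np.asarray(scores, dtype=float)
    if (scores < 0).any() or (scores > 1).any():
        raise ValidationError("scores must lie in [0, 1]")
    y = _as_binary(truth)
    pred = (scores >= threshold).astype(int)
    accuracy = float((pred == y).mean())
    # confusion rows: truth control/disease, cols: predicted control/disease
    confusion = np.array(
        [
            [int(((y == 0) & (pred == 0)).sum()), int(((y == 0) & (pred == 1)).sum())],
            [int(((y == 1) & (pred == 0)).sum()), int(((y == 1) & (pred == 1)).sum())],
        ]
    )
    both = len(np.unique(y)) == 2
    if both:
        sens = confusion[1, 1] / confusion[1].sum()
        spec = confusion[0, 0] / confusion[0].sum()
        balanced = float((sens + spec) / 2.0)
        auc = mann_whitney_auc(scores, y)
        fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
        roc_points = list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))
    else:
        if require_auc:
            raise ValidationError("AUC undefined: truth contains a single class")
        balanced, auc, roc_points = accuracy, None, []
    return MetricsReport(
        accuracy=accuracy,
        balanced_accuracy=balanced,
        roc_auc=auc,
        roc_points=roc_points,
        confusion=confusion,
        n_test=int(y.size),
    )


def conventional_features(
    m_train: ExpressionMatrix,
    m_test: ExpressionMatrix,
    de: DeTable,
    n_per_direction: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benchmark features: expression of the top up/down DEGs.

    Genes absent from the test matrix are dropped from both arms (warning);
    fewer than 10 shared genes is an error.
    """
    pools = rank_degs(de, pool_size=n_per_direction)
    selected = pools.up + pools.down
    test_genes = set(m_test.gene_ids)
    shared = [g for g in selected if g in test_genes]
    dropped = len(selected) - len(shared)
    if dropped:
        warnings.warn(
            f"{dropped} selected genes absent from the test matrix; "
            "dropped from both arms", stacklevel=2,
        )
    if len(shared) < min(10, len(selected)):
        raise ValidationError(
            f"only {len(shared)} selected genes shared with the test matrix"
        )
    train = m_train.to_frame().T.loc[:, shared]
    test = m_test.to_frame().T.loc[:, shared]
    return train, test
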