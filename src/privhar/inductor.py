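"""Wrapper fitness: random-forest cross-validation on weighted features.

For each candidate weight vector, three 90-tree random forests (gender, age
group, action) are trained under stratified k-fold cross-validation on the
element-wise weighted feature matrix.  The returned objective vector is
(gender accuracy, age accuracy, 1 - action accuracy) — all minimised.

Fold assignment is computed once per run and reused for every candidate, so
objective differences between candidates are not confounded by fold noise.
Each (candidate, fold, task) training gets a deterministic classifier seed,
which makes parallel evaluation bit-identical to sequential evaluation.

Note on weight sensitivity: multiplying a feature by a positive constant is
order-preserving, so tree-based classifiers are insensitive to weights
except where weighting collapses values at floating-point precision or to
exact zero.  ``InductorSpec.weight_quantization_step`` optionally rounds
each weighted feature to a grid whose step is ``step * sigma_f`` (the
population standard deviation of the unweighted feature column), off by
default.  Under this transform a feature at weight w retains roughly
``4 w / step`` distinguishable levels across its +/-2 sigma span, so small
weights progressively destroy feature resolution and the genome becomes
monotonically informative for the wrapper.  The grid is tied to the
feature's own scale (not an absolute value) because several of the 62
features are unbounded ratios whose resolution an absolute grid would
never degrade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .config import InductorSpec
from .features import FEATURE_NAMES, apply_weights
from .types import TASKS, ObjectiveVector


@dataclass
class TrainingCounter:
    """Counts individual random-forest training runs (one per fold per task
    per evaluated candidate)."""

    count: int = 0

    def increment(self, by: int = 1) -> None:
        self.count += by


@dataclass
class ConfusionMatrix:
    """Aggregated cross-validation confusion counts for one task."""

    labels: list
    counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def row_percentages(self) -> pd.DataFrame:
        """Rows as % of the total number of samples per (true) category."""
        counts = self.counts.astype(float)
        row_sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
        return pd.DataFrame(pct, index=self.labels, columns=self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def feature_array(matrix: pd.DataFrame) -> np.ndarray:
    """The 62 feature columns of a feature matrix, in canonical order."""
    return matrix[list(FEATURE_NAMES)].to_numpy(dtype=float)


def make_folds(matrix: pd.DataFrame, spec: InductorSpec) -> np.ndarray:
    """Stratified fold assignment (one fold index per row), deterministic
    given ``spec.seed``.

    Stratifies on ``spec.stratify_by``; with ``group_by_subject`` all
    windows of a subject stay in one fold.
    """
    labels = matrix[spec.stratify_by].to_numpy()
    counts = pd.Series(labels).value_counts()
    too_small = counts[counts < spec.k_folds]
    if len(too_small):
        raise ValueError(
            f"classes with fewer than k={spec.k_folds} members in "
            f"{spec.stratify_by!r}: {sorted(map(str, too_small.index))}"
        )
    if spec.k_folds > len(matrix):
        raise ValueError("k_folds exceeds the number of samples")
    dummy_x = np.zeros((len(matrix), 1))
    if spec.group_by_subject:
        splitter = StratifiedGroupKFold(
            n_splits=spec.k_folds, shuffle=True, random_state=spec.seed
        )
        split = splitter.split(dummy_x, labels, groups=matrix["subject_id"].to_numpy())
    else:
        splitter = StratifiedKFold(
            n_splits=spec.k_folds, shuffle=True, random_state=spec.seed
        )
        split = splitter.split(dummy_x, labels)
    assignment = np.empty(len(matrix), dtype=int)
    for fold, (_, test_idx) in enumerate(split):
        assignment[test_idx] = fold
    return assignment


def derive_classifier_seed(run_seed: int, eval_index: int, fold: int, task: str) -> int:
    """Deterministic per-(candidate, fold, task) classifier seed."""
    task_idx = TASKS.index(task)
    h = (
        np.uint64(run_seed) * np.uint64(1000003)
        + np.uint64(eval_index) * np.uint64(8191)
        + np.uint64(fold) * np.uint64(131)
        + np.uint64(task_idx)
    )
    return int(h % np.uint64(2**31 - 1))


def _weighted(matrix_x: np.ndarray, weights: np.ndarray, spec: InductorSpec) -> np.ndarray:
    xw = apply_weights(matrix_x, weights)
    step = spec.weight_quantization_step
    if step is not None:
        scale = matrix_x.std(axis=0)
        scale[scale == 0.0] = 1.0
        grid = step * scale
        # quantize deviations about the (weighted) column mean, so a feature
        # collapses to a constant once its weighted spread fits in one cell
        center = matrix_x.mean(axis=0) * weights
        xw = center + np.round((xw - center) / grid) * grid
    return xw


def _train_one_fold(
    xw: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    fold: int,
    spec: InductorSpec,
    rf_seed: int,
    class_labels: np.ndarray,
):
    train = folds != fold
    test = ~train
    y_train = y[train]
    if len(np.unique(y_train)) < 2:
        raise ValueError(
            f"degenerate training split: fold {fold} leaves a single-class "
            "training set"
        )
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees, random_state=rf_seed, n_jobs=1
    )
    clf.fit(xw[train], y_train)
    pred = clf.predict(xw[test])
    acc = float(np.mean(pred == y[test]))
    conf = _sk_confusion(y[test], pred, labels=class_labels)
    return acc, conf


def cv_accuracy(
    matrix: pd.DataFrame,
    weights: np.ndarray,
    task_label: str,
    spec: InductorSpec,
    folds: np.ndarray | None = None,
    counter: TrainingCounter | None = None,
    eval_index: int = 0,
    n_jobs: int = 1,
) -> tuple[float, ConfusionMatrix]:
    """k-fold cross-validated accuracy of one task classifier under the
    given feature weights.

    Trains k fresh forests (one per held-out fold); the reported accuracy is
    the mean of the k per-fold test accuracies, and the confusion matrix
    aggregates all held-out predictions.
    """
    if folds is None:
        folds = make_folds(matrix, spec)
    x = feature_array(matrix)
    xw = _weighted(x, np.asarray(weights, dtype=float), spec)
    y = matrix[task_label].to_numpy()
    class_labels = np.unique(y)

    jobs = [
        (fold, derive_classifier_seed(spec.seed, eval_index, fold, task_label))
        for fold in range(spec.k_folds)
    ]
    if n_jobs == 1:
        results = [
            _train_one_fold(xw, y, folds, fold, spec, rf_seed, class_labels)
            for fold, rf_seed in jobs
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_train_one_fold)(xw, y, folds, fold, spec, rf_seed, class_labels)
            for fold, rf_seed in jobs
        )
    if counter is not None:
        counter.increment(spec.k_folds)
    accs = [acc for acc, _ in results]
    total_conf = np.sum([conf for _, conf in results], axis=0)
    return float(np.mean(accs)), ConfusionMatrix(list(class_labels), total_conf)


def evaluate_objectives(
    matrix: pd.DataFrame,
    weights: np.ndarray,
    spec: InductorSpec,
    folds: np.ndarray | None = None,
    counter: TrainingCounter | None = None,
    eval_index: int = 0,
    n_jobs: int = 1,
) -> ObjectiveVector:
    """Run the three task classifiers and return the minimised objectives
    (gender accuracy, age accuracy, 1 - action accuracy)."""
    for task in TASKS:
        if task not in matrix.columns:
            raise ValueError(f"feature matrix lacks the {task!r} label column")
    if folds is None:
        folds = make_folds(matrix, spec)
    accs = {}
    for task in TASKS:
        accs[task], _ = cv_accuracy(
            matrix,
            weights,
            task,
            spec,
            folds=folds,
            counter=counter,
            eval_index=eval_index,
            n_jobs=n_jobs,
        )
    return ObjectiveVector(
        gender_obj=accs["gender"],
        age_obj=accs["age_group"],
        action_obj=1.0 - accs["activity"],
    )


def export_confusion(conf: ConfusionMatrix, path_counts, path_percent=None) -> None:
    """Write a confusion matrix as CSV (counts, and optionally the
    row-percentage convention: % of the total number of samples per category)."""
    conf.as_frame().to_csv(path_counts)
    if path_percent is not None:
        conf.row_percentages().round(1).to_csv(path_percent)
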