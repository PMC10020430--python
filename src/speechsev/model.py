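"""Severity prediction: splits, boosted trees, metrics and importances.

The 0-5 severity item is modeled as 6-class classification with a
gradient-boosted tree ensemble. Evaluation follows a hold-out plus 6-fold
cross-validation design: metrics are reported for the pooled out-of-fold
predictions and, separately, for a model trained on all cross-validation
data and applied once to the hold-out subjects. Feature importance is the
per-fold mean gain per tree that used a feature, averaged across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier

from .errors import ConsistencyError, InputError, ParameterError

logger = logging.getLogger(__name__)

N_CLASSES = 6  # severity labels 0-5; 6 (anarthria) is excluded upstream


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix with integer severity labels and subject ids."""

    features: pd.DataFrame  # one row per assessment, named feature columns
    labels: np.ndarray  # int in 0-5, one per row
    subject_ids: np.ndarray  # str, one per row

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        subject_ids = np.asarray(self.subject_ids, dtype=object)
        if not (len(self.features) == labels.size == subject_ids.size):
            raise InputError("features, labels and subject_ids must align")
        if labels.size == 0:
            raise InputError("dataset is empty")
        if labels.min() < 0 or labels.max() >= N_CLASSES:
            raise InputError(
                f"labels must be in 0-{N_CLASSES - 1} (anarthria is excluded "
                "from modeling); got range "
                f"[{labels.min()}, {labels.max()}]"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subject_ids", subject_ids)

    @property
    def n(self) -> int:
        return self.labels.size

    def subset_by_subjects(self, ids: Sequence[str]) -> "LabeledDataset":
        mask = np.isin(self.subject_ids, list(ids))
        return LabeledDataset(
            features=self.features.loc[mask].reset_index(drop=True),
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
        )


@dataclass(frozen=True)
class SplitPlan:
    """Hold-out subjects plus disjoint CV folds covering the remainder."""

    holdout_ids: tuple[str, ...]
    folds: tuple[tuple[str, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        seen: set[str] = set(self.holdout_ids)
        if len(seen) != len(self.holdout_ids):
            raise ConsistencyError("duplicate subjects in hold-out")
        for fold in self.folds:
            for sid in fold:
                if sid in seen:
                    raise ConsistencyError(f"subject {sid!r} in two split groups")
                seen.add(sid)

    @property
    def cv_ids(self) -> tuple[str, ...]:
        return tuple(sid for fold in self.folds for sid in fold)


@dataclass(frozen=True)
class GbtParams:
    """Hyperparameters of the boosted ensemble (small-sample-safe defaults)."""

    n_estimators: int = 200
    max_depth: int = 3
    learning_rate: float = 0.1
    subsample: float = 1.0


@dataclass
class FittedModel:
    """A fitted ensemble plus the feature schema it was trained on."""

    estimator: GradientBoostingClassifier
    feature_names: tuple[str, ...]
    classes: np.ndarray


def make_split(
    ds: LabeledDataset, holdout_n: int, n_folds: int, seed: int
) -> SplitPlan:
    """Deterministic subject-level stratified split.

    A subject's repeat assessments always travel together; hold-out
    subjects are drawn evenly across the label-sorted subject list and the
    remainder is dealt round-robin into ``n_folds`` folds, which keeps both
    parts approximately label-stratified.
    """
    if holdout_n < 0:
        raise ParameterError("holdout_n must be >= 0")
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    subjects: dict[str, int] = {}
    for sid, label in zip(ds.subject_ids, ds.labels):
        subjects.setdefault(str(sid), int(label))
    n_subjects = len(subjects)
    if n_subjects < holdout_n + n_folds:
        raise InputError(
            f"{n_subjects} subjects cannot fill a hold-out of {holdout_n} "
            f"plus {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(subjects))
    rng.shuffle(ids)
    # stable sort by label keeps the within-label shuffle
    ids = ids[np.argsort([subjects[s] for s in ids], kind="stable")]

    holdout: list[str] = []
    if holdout_n > 0:
        step = n_subjects / holdout_n
        positions = {int(step / 2 + i * step) for i in range(holdout_n)}
        holdout = [sid for i, sid in enumerate(ids) if i in positions]
    remaining = [sid for sid in ids if sid not in set(holdout)]
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for i, sid in enumerate(remaining):
        folds[i % n_folds].append(sid)
    return SplitPlan(
        holdout_ids=tuple(holdout),
        folds=tuple(tuple(f) for f in folds),
        seed=seed,
    )


def train_gbt(
    train: LabeledDataset, params: GbtParams | None = None, seed: int = 0
) -> FittedModel:
    """Fit the multiclass boosted-tree ensemble; deterministic given seed."""
    params = params or GbtParams()
    if np.unique(train.labels).size < 2:
        raise InputError("training set has fewer than 2 distinct labels")
    est = GradientBoostingClassifier(
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        subsample=params.subsample,
        random_state=seed,
    )
    est.fit(train.features.to_numpy(), train.labels)
    return FittedModel(
        estimator=est,
        feature_names=tuple(train.features.columns),
        classes=est.classes_,
    )


def predict(model: FittedModel, features: pd.DataFrame) -> np.ndarray:
    """Predict integer labels; columns are matched by name."""
    if len(features) == 0:
        return np.array([], dtype=int)
    if set(features.columns) != set(model.feature_names):
        missing = set(model.feature_names) - set(features.columns)
        extra = set(features.columns) - set(model.feature_names)
        raise ConsistencyError(
            f"feature schema mismatch (missing={sorted(missing)[:3]}..., "
            f"extra={sorted(extra)[:3]}...)"
        )
    x = features.loc[:, list(model.feature_names)].to_numpy()
    return model.estimator.predict(x).astype(int)


def accuracy_tol(true: Sequence[int], pred: Sequence[int], tol: int = 0) -> float:
    """Fraction of predictions within ``tol`` points of the true label."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.size == 0 or true.size != pred.size:
        raise InputError("need equal, non-zero numbers of true and predicted labels")
    return float(np.mean(np.abs(true - pred) <= tol))


def spearman_r(true: Sequence[int], pred: Sequence[int]) -> float:
    """Spearman rank correlation; NaN (with a flag) for constant input."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.size < 2 or true.size != pred.size:
        raise InputError("need >= 2 paired labels")
    if np.unique(true).size < 2 or np.unique(pred).size < 2:
        logger.warning("spearman_r: constant input, correlation undefined")
        return float("nan")
    return float(stats.spearmanr(true, pred).statistic)


def bootstrap_ci(
    true: Sequence[int],
    pred: Sequence[int],
    metric: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI of ``metric`` over paired bootstrap resamples.

    Resamples where the metric is undefined (NaN, e.g. a constant draw for
    a rank metric) are skipped; the skip count is logged.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    true = np.asarray(true)
    pred = np.asarray(pred)
    rng = np.random.default_rng(seed)
    values = []
    n_skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, true.size, size=true.size)
        v = metric(true[idx], pred[idx])
        if np.isnan(v):
            n_skipped += 1
        else:
            values.append(v)
    if n_skipped:
        logger.info("bootstrap_ci: skipped %d degenerate resamples", n_skipped)
    if not values:
        return (float("nan"), float("nan"))
    low, high = np.percentile(values, [2.5, 97.5])
    return float(low), float(high)


def permutation_test(
    true: Sequence[int],
    pred: Sequence[int],
    n_perm: int = 1999,
    seed: int = 0,
    tol: int = 1,
) -> tuple[float, float]:
    """Label-permutation test of the ±``tol`` accuracy.

    Returns ``(p, z)``: the exact permutation p-value
    ``(1 + #{permuted >= observed}) / (1 + n_perm)`` and a
    normal-approximation z from the permutation null's mean and SD.
    """
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    true = np.asarray(true)
    pred = np.asarray(pred)
    observed = accuracy_tol(true, pred, tol=tol)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    shuffled = true.copy()
    for i in range(n_perm):
        rng.shuffle(shuffled)
        null[i] = accuracy_tol(shuffled, pred, tol=tol)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    sd = null.std()
    z = float((observed - null.mean()) / sd) if sd > 0 else float("inf")
    return float(p), z


def confusion_matrix(true: Sequence[int], pred: Sequence[int]) -> np.ndarray:
    """6x6 count grid, rows = true label 0-5, columns = predicted."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.size and (
        true.min() < 0 or true.max() >= N_CLASSES
        or pred.min() < 0 or pred.max() >= N_CLASSES
    ):
        raise InputError(f"labels must be in 0-{N_CLASSES - 1}")
    grid = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(true, pred):
        grid[t, p] += 1
    return grid


def _per_tree_gains(model: FittedModel) -> list[dict[int, float]]:
    """Impurity-decrease (gain) per feature for every tree in the ensemble."""
    records = []
    for stage in model.estimator.estimators_:
        for tree_est in np.ravel(stage):
            t = tree_est.tree_
            gains: dict[int, float] = {}
            for node in range(t.node_count):
                left, right = t.children_left[node], t.children_right[node]
                if left == -1:  # leaf
                    continue
                gain = (
                    t.weighted_n_node_samples[node] * t.impurity[node]
                    - t.weighted_n_node_samples[left] * t.impurity[left]
                    - t.weighted_n_node_samples[right] * t.impurity[right]
                )
                feat = int(t.feature[node])
                gains[feat] = gains.get(feat, 0.0) + float(gain)
            records.append(gains)
    return records


def feature_importance(per_fold_models: Sequence[FittedModel]) -> dict[str, float]:
    """Mean (across folds) of the per-fold average gain per tree using a feature.

    Within a fold, each feature's score is the mean of its gain over the
    trees that split on it (0 if no tree used it); fold scores are then
    averaged and the result is sorted descending.
    """
    if not per_fold_models:
        raise InputError("need at least one fitted model")
    names = per_fold_models[0].feature_names
    fold_scores = np.zeros((len(per_fold_models), len(names)))
    for k, model in enumerate(per_fold_models):
        if model.feature_names != names:
            raise ConsistencyError("models trained on different feature schemas")
        totals = np.zeros(len(names))
        counts = np.zeros(len(names))
        for gains in _per_tree_gains(model):
            for feat, gain in gains.items():
                totals[feat] += gain
                counts[feat] += 1
        used = counts > 0
        fold_scores[k, used] = totals[used] / counts[used]
    mean_scores = fold_scores.mean(axis=0)
    order = np.argsort(-mean_scores, kind="stable")
    return {names[i]: float(mean_scores[i]) for i in order}


@dataclass
class EvaluationReport:
    """Metrics of one evaluation split."""

    n: int
    accuracy: float
    accuracy_tol1: float
    spearman: float
    ci95: dict[str, tuple[float, float]]
    confusion: np.ndarray
    permutation_p: float | None = None
    permutation_z: float | None = None

    def to_dict(self) -> dict:
        def _num(v):
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "accuracy_tol1": self.accuracy_tol1,
            "spearman_r": _num(self.spearman),
            "ci95": {k: [_num(v[0]), _num(v[1])] for k, v in self.ci95.items()},
            "permutation_p": _num(self.permutation_p),
            "permutation_z": _num(self.permutation_z),
            "confusion": self.confusion.tolist(),
        }


@dataclass
class ExperimentResult:
    pooled_cv: EvaluationReport
    holdout: EvaluationReport | None
    importance: dict[str, float]
    split: SplitPlan
    oof_true: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    oof_pred: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _evaluate(
    true: np.ndarray,
    pred: np.ndarray,
    n_boot: int,
    seed: int,
    n_perm: int | None = None,
) -> EvaluationReport:
    report = EvaluationReport(
        n=int(true.size),
        accuracy=accuracy_tol(true, pred, tol=0),
        accuracy_tol1=accuracy_tol(true, pred, tol=1),
        spearman=spearman_r(true, pred),
        ci95={
            "accuracy": bootstrap_ci(
                true, pred, lambda t, p: accuracy_tol(t, p, 0), n_boot, seed
            ),
            "accuracy_tol1": bootstrap_ci(
                true, pred, lambda t, p: accuracy_tol(t, p, 1), n_boot, seed + 1
            ),
            "spearman_r": bootstrap_ci(
                true, pred, _safe_spearman, n_boot, seed + 2
            ),
        },
        confusion=confusion_matrix(true, pred),
    )
    if n_perm is not None:
        report.permutation_p, report.permutation_z = permutation_test(
            true, pred, n_perm=n_perm, seed=seed + 3
        )
    return report


def _safe_spearman(t: np.ndarray, p: np.ndarray) -> float:
    if np.unique(t).size < 2 or np.unique(p).size < 2:
        return float("nan")
    return float(stats.spearmanr(t, p).statistic)


def run_experiment(
    ds: LabeledDataset,
    holdout_n: int = 10,
    n_folds: int = 6,
    params: GbtParams | None = None,
    seed: int = 0,
    n_boot: int = 2000,
    n_perm: int = 1999,
) -> ExperimentResult:
    """Hold-out + k-fold cross-validation experiment.

    Per fold, a model trained on the other folds predicts the fold's
    assessments; pooled out-of-fold predictions give the cross-validation
    report (with a label-permutation test). A final model trained on all
    cross-validation data is evaluated once on the hold-out subjects.
    """
    params = params or GbtParams()
    split = make_split(ds, holdout_n=holdout_n, n_folds=n_folds, seed=seed)
    cv_ds = ds.subset_by_subjects(split.cv_ids)

    oof_true: list[np.ndarray] = []
    oof_pred: list[np.ndarray] = []
    fold_models: list[FittedModel] = []
    for k, fold_ids in enumerate(split.folds):
        train_ids = [sid for j, f in enumerate(split.folds) if j != k for sid in f]
        train_ds = cv_ds.subset_by_subjects(train_ids)
        val_ds = cv_ds.subset_by_subjects(fold_ids)
        model = train_gbt(train_ds, params, seed=seed)
        fold_models.append(model)
        oof_true.append(val_ds.labels)
        oof_pred.append(predict(model, val_ds.features))
        logger.info("fold %d: train n=%d, validate n=%d", k + 1, train_ds.n, val_ds.n)

    true_cv = np.concatenate(oof_true)
    pred_cv = np.concatenate(oof_pred)
    pooled = _evaluate(true_cv, pred_cv, n_boot, seed, n_perm=n_perm)

    holdout_report = None
    if split.holdout_ids:
        final = train_gbt(cv_ds, params, seed=seed)
        hold_ds = ds.subset_by_subjects(split.holdout_ids)
        hold_pred = predict(final, hold_ds.features)
        holdout_report = _evaluate(hold_ds.labels, hold_pred, n_boot, seed + 100)

    return ExperimentResult(
        pooled_cv=pooled,
        holdout=holdout_report,
        importance=feature_importance(fold_models),
        split=split,
        oof_true=true_cv,
        oof_pred=pred_cv,
    )
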