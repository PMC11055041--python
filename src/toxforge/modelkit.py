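"""Cross-validated model evaluation and benchmark-table comparison.

Regression endpoints are scored with RMSE, classification endpoints with
ROC AUC, both under k-fold cross-validation (default five-fold, seeded
shuffle, stratified by label for classification).  Learners plug in through
a minimal ``fit``/``predict`` contract, so gradient-boosting libraries are
optional adapters rather than dependencies of the core; a nearest-neighbour
baseline and a mean predictor ship for dependency-free testing.

A :class:`MetricTable` holds per-target metric values and sample counts in
the shape of a published benchmark table (one row per target, one column
per model), and supports cross-model win counting, sample-size
stratification, and metric-vs-size profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics
from sklearn.model_selection import KFold, StratifiedKFold

from .molio import Task

__all__ = [
    "rmse",
    "roc_auc",
    "MetricTable",
    "EvalConfig",
    "CVResult",
    "ComparisonResult",
    "cross_validate",
    "compare_models",
    "metric_size_profile",
    "count_rows_above",
    "NotFittedError",
    "MeanLearner",
    "NearestNeighborLearner",
    "SklearnLearner",
    "XGBoostLearner",
]


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error; zero iff the two vectors are identical."""
    y, yhat = np.asarray(observed, float), np.asarray(predicted, float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("observed and predicted must have equal non-zero length")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve.

    Equals the fraction of (positive, negative) pairs where the positive
    scores higher, ties counted half.  Requires both classes present.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(_skmetrics.roc_auc_score(y, np.asarray(scores, float)))


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation and improvement-threshold settings.

    The improvement thresholds (5% RMSE / 3% ROC AUC over a cited benchmark
    mean) gate whether a model counts as an improvement at all; they feed
    the competition multiplier in :mod:`toxforge.hackscore`.
    """

    k_folds: int = 5
    seed: int = 0
    stratify: bool = True
    regression_improve_threshold: float = 5.0
    classification_improve_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


class NotFittedError(RuntimeError):
    pass


class MeanLearner:
    """Predicts the training-target mean; the weakest sane regression baseline."""

    def __init__(self) -> None:
        self._mean: float | None = None

    def fit(self, features, targets) -> "MeanLearner":
        self._mean = float(np.mean(targets))
        return self

    def predict(self, features) -> np.ndarray:
        if self._mean is None:
            raise NotFittedError("predict before fit")
        return np.full(np.asarray(features).shape[0], self._mean)


class NearestNeighborLearner:
    """k-nearest-neighbour over the feature matrix (Euclidean, mean of k).

    Memorizes the training rows: with k=1 it returns the training target on
    any training row, which makes it a convenient dependency-free baseline.
    """

    def __init__(self, k: int = 1) -> None:
        self.k = k
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, features, targets) -> "NearestNeighborLearner":
        self._X = np.asarray(features, float)
        self._y = np.asarray(targets, float)
        return self

    def predict(self, features) -> np.ndarray:
        if self._X is None:
            raise NotFittedError("predict before fit")
        X = np.asarray(features, float)
        d2 = ((X[:, None, :] - self._X[None, :, :]) ** 2).sum(axis=2)
        k = min(self.k, self._X.shape[0])
        idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
        return self._y[idx].mean(axis=1)


class SklearnLearner:
    """Adapter putting any scikit-learn estimator behind the fit/predict contract.

    For classifiers, ``predict`` returns the positive-class probability so
    the output is a ranking score suitable for ROC AUC.
    """

    def __init__(self, estimator) -> None:
        self.estimator = estimator
        self._columns: list[str] | None = None
        self._fitted = False

    def fit(self, features, targets) -> "SklearnLearner":
        if isinstance(features, pd.DataFrame):
            self._columns = list(features.columns)
        self.estimator.fit(np.asarray(features, float), np.asarray(targets))
        self._fitted = True
        return self

    @property
    def feature_names(self) -> list[str] | None:
        return self._columns

    def predict(self, features) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError("predict before fit")
        X = np.asarray(features, float)
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)[:, 1]
        return np.asarray(self.estimator.predict(X), float)


def XGBoostLearner(task: Task = Task.REGRESSION, **params) -> SklearnLearner:
    """Gradient-boosted trees adapter (optional; requires xgboost)."""
    import xgboost as xgb

    params.setdefault("n_estimators", 200)
    params.setdefault("random_state", 0)
    cls = xgb.XGBRegressor if task == Task.REGRESSION else xgb.XGBClassifier
    return SklearnLearner(cls(**params))


@dataclass
class CVResult:
    task: Task
    fold_metrics: list[float]
    fold_indices: list[np.ndarray]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_metrics))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_metrics, ddof=1))


def cross_validate(
    features,
    targets,
    learner_factory: Callable[[], object],
    task: Task,
    config: EvalConfig = EvalConfig(),
) -> CVResult:
    """k-fold cross-validation with a fresh learner per fold.

    Folds partition the rows exactly once (seeded shuffle, stratified by
    label for classification when ``config.stratify``); each fold's metric —
    RMSE for regression, ROC AUC for classification — is computed on the
    held-out rows only.
    """
    X = np.asarray(features, float)
    y = np.asarray(targets, float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets must align")
    if task == Task.CLASSIFICATION and config.stratify:
        splitter = StratifiedKFold(
            n_splits=config.k_folds, shuffle=True, random_state=config.seed
        )
        splits = splitter.split(X, y)
    else:
        splitter = KFold(
            n_splits=config.k_folds, shuffle=True, random_state=config.seed
        )
        splits = splitter.split(X)
    fold_metrics: list[float] = []
    fold_indices: list[np.ndarray] = []
    for train_idx, test_idx in splits:
        learner = learner_factory()
        learner.fit(X[train_idx], y[train_idx])
        pred = learner.predict(X[test_idx])
        if task == Task.REGRESSION:
            fold_metrics.append(rmse(y[test_idx], pred))
        else:
            fold_metrics.append(roc_auc(y[test_idx].astype(int), pred))
        fold_indices.append(test_idx)
    return CVResult(task, fold_metrics, fold_indices)


@dataclass
class MetricTable:
    """Per-target, per-model metric values plus sample counts.

    The underlying frame has columns ``target``, ``task``, ``n_samples``
    followed by one column per model.  RMSE cells are non-negative, ROC AUC
    cells lie in [0, 1], ``n_samples`` >= 1.
    """

    frame: pd.DataFrame

    _META = ("target", "task", "n_samples")

    def __post_init__(self) -> None:
        missing = [c for c in self._META if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.frame["n_samples"] < 1).any():
            raise ValueError("n_samples must be >= 1")
        for _, row in self.frame.iterrows():
            task = Task(row["task"])
            for m in self.model_columns:
                v = row[m]
                if pd.isna(v):
                    continue
                if task == Task.CLASSIFICATION and not 0 <= v <= 1:
                    raise ValueError(f"ROC AUC out of [0,1]: {row['target']}={v}")
                if task == Task.REGRESSION and v < 0:
                    raise ValueError(f"negative RMSE: {row['target']}={v}")

    @property
    def model_columns(self) -> list[str]:
        return [
            c
            for c in self.frame.columns
            if c not in self._META and pd.api.types.is_numeric_dtype(self.frame[c])
        ]

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetricTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ComparisonResult:
    wins: int
    total: int

    @property
    def percent(self) -> int:
        return _round_half_away(100.0 * self.wins / self.total)


def compare_models(
    table: MetricTable,
    focal: str,
    comparators: Sequence[str],
    rows: Callable[[pd.Series], bool] | Sequence[str] | None = None,
) -> ComparisonResult:
    """Count rows where ``focal`` strictly beats every comparator.

    "Better" is lower RMSE for regression rows and higher ROC AUC for
    classification rows; ties are not wins.  ``rows`` selects a subset by
    predicate or by target names; the percentage is rounded to the nearest
    integer, half away from zero.
    """
    df = table.frame
    if rows is not None:
        if callable(rows):
            df = df[df.apply(rows, axis=1)]
        else:
            df = df[df["target"].isin(list(rows))]
    if len(df) == 0:
        raise ValueError("empty row selection")
    for model in [focal, *comparators]:
        if model not in table.frame.columns:
            raise ValueError(f"model column {model!r} not in table")
        if df[model].isna().any():
            raise ValueError(f"model {model!r} missing values in selected rows")
    wins = 0
    for _, row in df.iterrows():
        if Task(row["task"]) == Task.REGRESSION:
            win = all(row[focal] < row[c] for c in comparators)
        else:
            win = all(row[focal] > row[c] for c in comparators)
        wins += int(win)
    return ComparisonResult(wins, len(df))


def metric_size_profile(
    table: MetricTable, model: str
) -> list[tuple[int, float]]:
    """(n_samples, metric) pairs sorted by n_samples, for log-scale plots.

    Ties in ``n_samples`` keep the table's row order (stable sort).
    """
    if model not in table.frame.columns:
        raise ValueError(f"model column {model!r} not in table")
    pairs = list(zip(table.frame["n_samples"], table.frame[model]))
    pairs.sort(key=lambda p: p[0])
    return [(int(n), float(m)) for n, m in pairs]


def count_rows_above(table: MetricTable, n_min: int) -> int:
    """Number of targets whose sample count exceeds ``n_min``."""
    return int((table.frame["n_samples"] > n_min).sum())
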