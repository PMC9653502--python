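"""Binary-relevance multilabel classification and the evaluation protocol.

Three learners (logistic regression, random forest, gradient tree boosting),
repeated stratified 5-fold cross-validation, hamming loss / balanced accuracy
/ macro recall, exact-vs-partial result categorization, category-level feature
importance, and a mean-of-n wall-clock benchmark.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

MODEL_KINDS = ("logistic_regression", "random_forest", "gradient_tree_boosting")


class EvalError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise EvalError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")

    def make_estimator(self):
        params = dict(self.hyperparameters)
        if self.kind == "logistic_regression":
            defaults = dict(C=1.0, max_iter=2000, solver="lbfgs")  # L2 penalty (library default)
            defaults.update(params)
            return LogisticRegression(random_state=self.seed, **defaults)
        if self.kind == "random_forest":
            defaults = dict(n_estimators=100)
            defaults.update(params)
            return RandomForestClassifier(random_state=self.seed, **defaults)
        # max_features='sqrt' keeps boosting tractable on wide raw-term matrices
        defaults = dict(n_estimators=100, learning_rate=0.1, max_depth=3, max_features="sqrt")
        defaults.update(params)
        return GradientBoostingClassifier(random_state=self.seed, **defaults)


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    repetitions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise EvalError("folds must be >= 2")
        if self.repetitions < 1:
            raise EvalError("repetitions must be >= 1")


@dataclass
class EvalResult:
    """Aggregate metrics plus the per-repetition values they were averaged from."""

    hamming_loss: float
    balanced_accuracy: float
    recall: float
    correct_count: float
    partially_correct_count: float
    incorrect_count: float
    runtime_seconds: float
    per_repetition: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "hamming_loss": self.hamming_loss,
            "balanced_accuracy": self.balanced_accuracy,
            "recall": self.recall,
            "correct_count": self.correct_count,
            "partially_correct_count": self.partially_correct_count,
            "incorrect_count": self.incorrect_count,
            "runtime_seconds": self.runtime_seconds,
            "per_repetition": self.per_repetition,
        }


# --------------------------------------------------------------------------
# binary relevance
# --------------------------------------------------------------------------

class _ConstantModel:
    """Stand-in for labels that are single-valued in training data."""

    def __init__(self, value: int) -> None:
        self.value = value

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), self.value, dtype=np.int8)


def fit_binary_relevance(X_train, Y_train, spec: ModelSpec) -> list:
    """One independent binary classifier per label column (constant if degenerate)."""
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.asarray(Y_train, dtype=np.int8)
    models = []
    for j in range(Y_train.shape[1]):
        y = Y_train[:, j]
        if y.min() == y.max():
            # routine on cohorts with n=1-5 labels, so debug rather than warning
            log.debug("label column %d constant (%d) in training data; constant model", j, int(y[0]))
            models.append(_ConstantModel(int(y[0])))
            continue
        estimator = spec.make_estimator()
        estimator.fit(X_train, y)
        models.append(estimator)
    return models


def predict_binary_relevance(models: Sequence, X_test) -> np.ndarray:
    X_test = np.asarray(X_test, dtype=float)
    return np.column_stack([m.predict(X_test).astype(np.int8) for m in models])


def fit_predict_binary_relevance(X_train, Y_train, X_test, spec: ModelSpec) -> np.ndarray:
    """Predicted label indicator matrix for ``X_test``; deterministic given spec.seed."""
    return predict_binary_relevance(fit_binary_relevance(X_train, Y_train, spec), X_test)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def _check_shapes(Y_true, Y_pred) -> tuple[np.ndarray, np.ndarray]:
    Y_true = np.asarray(Y_true, dtype=np.int8)
    Y_pred = np.asarray(Y_pred, dtype=np.int8)
    if Y_true.shape != Y_pred.shape:
        raise EvalError(f"shape mismatch: {Y_true.shape} vs {Y_pred.shape}")
    return Y_true, Y_pred


def hamming_loss(Y_true, Y_pred) -> float:
    """Fraction of the N×L indicator cells where prediction and truth disagree."""
    Y_true, Y_pred = _check_shapes(Y_true, Y_pred)
    return float(np.mean(Y_true != Y_pred))


def balanced_accuracy(Y_true, Y_pred) -> float:
    """Macro mean of (TPR+TNR)/2 over labels with both positives and negatives."""
    Y_true, Y_pred = _check_shapes(Y_true, Y_pred)
    scores = []
    for j in range(Y_true.shape[1]):
        t, p = Y_true[:, j], Y_pred[:, j]
        pos, neg = int(t.sum()), int((1 - t).sum())
        if pos == 0 or neg == 0:
            continue
        tpr = float(((t == 1) & (p == 1)).sum()) / pos
        tnr = float(((t == 0) & (p == 0)).sum()) / neg
        scores.append((tpr + tnr) / 2)
    if not scores:
        raise EvalError("undefined balanced accuracy: every label is single-valued")
    return float(np.mean(scores))


def recall_macro(Y_true, Y_pred) -> float:
    """Macro mean of TP/(TP+FN) over labels with at least one positive."""
    Y_true, Y_pred = _check_shapes(Y_true, Y_pred)
    scores = []
    for j in range(Y_true.shape[1]):
        t, p = Y_true[:, j], Y_pred[:, j]
        pos = int(t.sum())
        if pos == 0:
            continue
        scores.append(float(((t == 1) & (p == 1)).sum()) / pos)
    if not scores:
        raise EvalError("undefined recall: no label has positives")
    return float(np.mean(scores))


def categorize_results(
    true_sets: Sequence[frozenset], pred_sets: Sequence[frozenset]
) -> dict[str, int]:
    """Correct (set equality) / partially correct (overlap) / incorrect (disjoint)."""
    if len(true_sets) != len(pred_sets):
        raise EvalError(f"length mismatch: {len(true_sets)} vs {len(pred_sets)}")
    counts = {"correct": 0, "partially_correct": 0, "incorrect": 0}
    for truth, pred in zip(true_sets, pred_sets):
        if set(pred) == set(truth):
            counts["correct"] += 1
        elif set(pred) & set(truth):
            counts["partially_correct"] += 1
        else:
            counts["incorrect"] += 1
    return counts


def relative_improvement(c_base: float, c_mapped: float) -> float:
    """100·(mapped − base)/base, rounded to one decimal."""
    if c_base <= 0:
        raise EvalError("baseline count must be positive")
    return round(100.0 * (c_mapped - c_base) / c_base, 1)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def _stratification_key(Y: np.ndarray) -> np.ndarray:
    """Each patient's rarest positive label (ties → lowest column index).

    Keeps low-prevalence labels spread across folds; plain random folds would
    routinely strand all positives of an n≤5 label in one fold.
    """
    support = Y.sum(axis=0)
    keys = np.empty(Y.shape[0], dtype=int)
    for i in range(Y.shape[0]):
        positives = np.flatnonzero(Y[i])
        keys[i] = positives[np.argmin(support[positives])]
    return keys


def _indicator_to_sets(Y: np.ndarray, labels: Sequence[str]) -> list[frozenset]:
    labels = np.asarray(labels, dtype=object)
    return [frozenset(labels[row.astype(bool)]) for row in Y]


def cross_validate(X, Y, spec: ModelSpec, cv: CVConfig, label_names: Sequence[str] | None = None) -> EvalResult:
    """Repeated stratified k-fold; per-repetition pooled metrics, then averaged."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=np.int8)
    n = X.shape[0]
    if n < cv.folds:
        raise EvalError(f"need at least {cv.folds} rows, got {n}")
    if label_names is None:
        label_names = [f"label_{j}" for j in range(Y.shape[1])]
    strat = _stratification_key(Y)
    per_repetition: list[dict] = []
    total_runtime = 0.0
    for rep in range(cv.repetitions):
        splitter = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed + rep)
        pooled_pred = np.zeros_like(Y)
        tested = np.zeros(n, dtype=bool)
        t0 = time.perf_counter()
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="The least populated class")
            folds = list(splitter.split(X, strat))
        for train_idx, test_idx in folds:
            if len(test_idx) == 0:
                raise EvalError("fold with zero test rows")
            pred = fit_predict_binary_relevance(X[train_idx], Y[train_idx], X[test_idx], spec)
            pooled_pred[test_idx] = pred
            tested[test_idx] = True
        runtime = time.perf_counter() - t0
        total_runtime += runtime
        assert tested.all(), "every patient must be tested exactly once per repetition"
        counts = categorize_results(
            _indicator_to_sets(Y, label_names), _indicator_to_sets(pooled_pred, label_names)
        )
        per_repetition.append(
            {
                "hamming_loss": hamming_loss(Y, pooled_pred),
                "balanced_accuracy": balanced_accuracy(Y, pooled_pred),
                "recall": recall_macro(Y, pooled_pred),
                "correct_count": counts["correct"],
                "partially_correct_count": counts["partially_correct"],
                "incorrect_count": counts["incorrect"],
                "runtime_seconds": runtime,
            }
        )
    mean = lambda key: float(np.mean([rep[key] for rep in per_repetition]))
    return EvalResult(
        hamming_loss=mean("hamming_loss"),
        balanced_accuracy=mean("balanced_accuracy"),
        recall=mean("recall"),
        correct_count=mean("correct_count"),
        partially_correct_count=mean("partially_correct_count"),
        incorrect_count=mean("incorrect_count"),
        runtime_seconds=total_runtime,
        per_repetition=per_repetition,
    )


# --------------------------------------------------------------------------
# feature importance and runtime benchmarking
# --------------------------------------------------------------------------

def feature_importance(
    models: Sequence,
    X: np.ndarray,
    column_categories: Sequence[str],
) -> dict[str, float]:
    """Per-label importances averaged, summed within category, normalized to 1.

    Tree models contribute impurity-based importances; logistic regression
    contributes |coefficient|·std(feature) (standardized-coefficient magnitude).
    Constant-label models contribute nothing.
    """
    X = np.asarray(X, dtype=float)
    column_categories = list(column_categories)
    per_label: list[np.ndarray] = []
    for model in models:
        if isinstance(model, _ConstantModel):
            continue
        if hasattr(model, "feature_importances_"):
            per_label.append(np.asarray(model.feature_importances_, dtype=float))
        elif hasattr(model, "coef_"):
            per_label.append(np.abs(model.coef_).ravel() * X.std(axis=0))
        else:
            raise EvalError(f"model {model!r} exposes no importances; is it fitted?")
    if not per_label:
        raise EvalError("no fitted non-constant models to read importances from")
    column_scores = np.mean(per_label, axis=0)
    totals: dict[str, float] = {}
    for score, category in zip(column_scores, column_categories):
        totals[category] = totals.get(category, 0.0) + float(score)
    grand = sum(totals.values())
    if grand <= 0:
        # uniform fallback: all-zero importances carry no information
        return {c: 1.0 / len(totals) for c in totals}
    return {c: v / grand for c, v in totals.items()}


@dataclass
class BenchmarkResult:
    mean_seconds: float
    runs: list[float]


def runtime_benchmark(task: Callable[[], object], executions: int = 7) -> BenchmarkResult:
    """Mean wall-clock time of ``task()`` over ``executions`` runs."""
    if executions < 1:
        raise EvalError("executions must be >= 1")
    runs = []
    for i in range(executions):
        t0 = time.perf_counter()
        try:
            task()
        except Exception as exc:
            raise EvalError(f"benchmark task failed on run {i}: {exc}") from exc
        runs.append(time.perf_counter() - t0)
    return BenchmarkResult(mean_seconds=float(np.mean(runs)), runs=runs)
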