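"""QSAR multiclass classification.

Feature filtering (variance < 0.1, pairwise |r| > 0.95), SMOTE class
balancing, stratified splitting, one-vs-rest classification with six
algorithm families, stratified k-fold cross-validation, and validation
metrics (accuracy, macro recall, multiclass Matthews correlation).

The default workflow balances the full dataset before splitting, which
matches the study design this package reproduces but leaks interpolated
points into the test set; ``balance_mode="train_only"`` applies SMOTE to
the training portion only and is the recommended setting for honest
external validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

DEFAULT_SEED = 42
ALGORITHMS = ("extra_trees", "random_forest", "lightgbm", "xgboost", "mlp", "gaussian_process")


# ---------------------------------------------------------------------------
# feature filtering

@dataclass(frozen=True)
class FilterTrace:
    dropped_low_variance: list[str]
    dropped_correlated: list[tuple[str, str]]  # (dropped, partner that triggered it)
    retained: list[str]


def variance_filter(matrix: pd.DataFrame, threshold: float = 0.1) -> tuple[pd.DataFrame, FilterTrace]:
    """Drop columns whose sample variance (unscaled) is below ``threshold``."""
    if matrix.shape[0] < 2:
        raise ValueError("variance filter requires at least 2 rows")
    variances = matrix.var(ddof=1)
    dropped = [c for c in matrix.columns if variances[c] < threshold]
    retained = [c for c in matrix.columns if c not in set(dropped)]
    return matrix[retained], FilterTrace(dropped, [], retained)


def correlation_filter(matrix: pd.DataFrame, threshold: float = 0.95) -> tuple[pd.DataFrame, FilterTrace]:
    """Greedy pairwise decorrelation in column order.

    Scanning columns left to right, a column is dropped when its |Pearson r|
    with an earlier retained column exceeds ``threshold``; the earlier column
    wins. Zero-variance columns must have been removed beforehand.
    """
    if matrix.shape[0] < 3:
        raise ValueError("correlation filter requires at least 3 rows")
    stds = matrix.std(ddof=1)
    zero = [c for c in matrix.columns if stds[c] == 0]
    if zero:
        raise ValueError(f"zero-variance columns present (run variance_filter first): {zero[:5]}")
    corr = np.corrcoef(matrix.to_numpy(), rowvar=False)
    cols = list(matrix.columns)
    retained_idx: list[int] = []
    dropped: list[tuple[str, str]] = []
    for j in range(len(cols)):
        partner = next(
            (i for i in retained_idx if abs(corr[i, j]) > threshold), None
        ) if len(cols) > 1 else None
        if partner is None:
            retained_idx.append(j)
        else:
            dropped.append((cols[j], cols[partner]))
    retained = [cols[i] for i in retained_idx]
    return matrix[retained], FilterTrace([], dropped, retained)


# ---------------------------------------------------------------------------
# SMOTE balancing

def smote_balance(
    matrix: pd.DataFrame | np.ndarray,
    labels: Sequence,
    seed: int = DEFAULT_SEED,
    k_neighbors: int = 5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic minority oversampling to the majority-class count.

    Every minority class is filled up to the majority count with synthetic
    rows: each is a convex combination x_i + u * (x_j - x_i) of a random
    class member x_i and one of its k nearest same-class neighbors x_j
    (Euclidean), u ~ U(0, 1). Original rows are preserved verbatim; the
    neighbor count is shrunk to (class size - 1) when necessary.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    columns = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("matrix and labels disagree on row count")
    classes, counts = np.unique(y, return_counts=True)
    majority = int(counts.max())
    rng = np.random.default_rng(seed)

    new_rows: list[np.ndarray] = []
    new_labels: list = []
    for cls, count in zip(classes, counts):
        deficit = majority - int(count)
        if deficit == 0:
            continue
        if count < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members; SMOTE needs a neighbor")
        Xc = X[y == cls]
        k = min(k_neighbors, len(Xc) - 1)
        # pairwise distances within the class; exclude self
        d2 = ((Xc[:, None, :] - Xc[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :k]
        for _ in range(deficit):
            i = int(rng.integers(len(Xc)))
            j = int(nn[i, rng.integers(k)])
            u = rng.random()
            new_rows.append(Xc[i] + u * (Xc[j] - Xc[i]))
            new_labels.append(cls)

    if new_rows:
        X_out = np.vstack([X, np.array(new_rows)])
        y_out = np.concatenate([y, np.array(new_labels)])
    else:
        X_out, y_out = X, y
    out = pd.DataFrame(X_out, columns=columns)
    return out, y_out


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitPlan:
    train_ids: list
    test_ids: list
    ratio: float
    seed: int


def split(ids: Sequence, labels: Sequence, ratio: float = 0.8, seed: int = DEFAULT_SEED) -> SplitPlan:
    """Stratified train/test split by class, reproducible for a fixed seed."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    ids = list(ids)
    train, test = train_test_split(
        ids, train_size=ratio, random_state=seed, stratify=np.asarray(labels), shuffle=True
    )
    return SplitPlan(train_ids=list(train), test_ids=list(test), ratio=ratio, seed=seed)


# ---------------------------------------------------------------------------
# models

def _base_estimator(algorithm: str, seed: int, n_estimators: int = 200):
    if algorithm == "extra_trees":
        return ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    if algorithm == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, verbosity=-1,
            deterministic=True, force_col_wise=True,
        )
    if algorithm == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1, verbosity=0)
    if algorithm == "mlp":
        return MLPClassifier(hidden_layer_sizes=(100,), max_iter=600, random_state=seed)
    if algorithm == "gaussian_process":
        return GaussianProcessClassifier(random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; supported: {list(ALGORITHMS)}")


@dataclass
class TrainedClassifier:
    """A fitted one-vs-rest multiclass model with its preprocessing scaler."""

    algorithm: str
    model: OneVsRestClassifier
    scaler: StandardScaler
    classes: list
    feature_names: list[str]
    seed: int

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        if list(matrix.columns) != self.feature_names:
            raise ValueError("query feature names do not match the training features")
        return self.model.predict(self.scaler.transform(matrix.to_numpy(dtype=float)))


# Gaussian-process training cost is cubic in rows; cap with a seeded subsample
GP_MAX_TRAIN_ROWS = 600


def train_ovr(
    matrix: pd.DataFrame,
    labels: Sequence,
    algorithm: str = "extra_trees",
    seed: int = DEFAULT_SEED,
    n_estimators: int = 200,
) -> TrainedClassifier:
    """Fit a one-vs-rest multiclass classifier (one binary learner per class).

    Features are z-scaled before fitting (tree models are scale-invariant,
    MLP and GP are not; one shared path keeps preprocessing uniform).
    """
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    X = matrix.to_numpy(dtype=float)
    if algorithm == "gaussian_process" and X.shape[0] > GP_MAX_TRAIN_ROWS:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(X.shape[0], GP_MAX_TRAIN_ROWS, replace=False))
        X, y = X[keep], y[keep]
        logger.info("gaussian_process: subsampled training set to %d rows", GP_MAX_TRAIN_ROWS)
    scaler = StandardScaler().fit(X)
    model = OneVsRestClassifier(_base_estimator(algorithm, seed, n_estimators), n_jobs=1)
    model.fit(scaler.transform(X), y)
    return TrainedClassifier(
        algorithm=algorithm,
        model=model,
        scaler=scaler,
        classes=classes,
        feature_names=list(matrix.columns),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# metrics

def confusion_matrix(y_true: Sequence, y_pred: Sequence, classes: Sequence | None = None) -> pd.DataFrame:
    """Per-class confusion grid (rows = truth, columns = prediction)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    grid = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        grid[idx[t], idx[p]] += 1
    return pd.DataFrame(grid, index=classes, columns=classes)


def metrics(confusion: pd.DataFrame) -> tuple[float, float, float]:
    """(accuracy, macro recall, multiclass MCC) from a confusion grid.

    Accuracy is trace/total; recall is the unweighted mean of per-class
    TP/(TP+FN) over classes present in the truth; MCC is the multiclass
    generalization computed from the full grid (equals the TP/TN/FP/FN
    closed form in the binary case).
    """
    grid = confusion.to_numpy(dtype=float)
    total = grid.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(grid) / total
    recalls = []
    for i in range(grid.shape[0]):
        support = grid[i].sum()
        if support == 0:
            logger.warning("class %r absent from truth; excluded from recall", confusion.index[i])
            continue
        recalls.append(grid[i, i] / support)
    recall = float(np.mean(recalls))
    t = grid.sum(axis=1)  # truth counts
    p = grid.sum(axis=0)  # prediction counts
    c = np.trace(grid)
    s = total
    num = c * s - float(t @ p)
    den = np.sqrt(s**2 - float(p @ p)) * np.sqrt(s**2 - float(t @ t))
    mcc = 0.0 if den == 0 else num / den
    mcc = min(1.0, max(-1.0, mcc))  # guard float overshoot
    return float(accuracy), recall, float(mcc)


def evaluate(clf: TrainedClassifier, matrix: pd.DataFrame, labels: Sequence) -> tuple[float, float, float]:
    pred = clf.predict(matrix)
    return metrics(confusion_matrix(labels, pred, classes=clf.classes))


def cross_validate(
    matrix: pd.DataFrame,
    labels: Sequence,
    algorithm: str = "extra_trees",
    k: int = 10,
    seed: int = DEFAULT_SEED,
    n_estimators: int = 200,
) -> dict:
    """Stratified k-fold cross-validation; per-fold and mean metrics.

    k is reduced (with a warning) when the smallest class has fewer than k
    members.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    y = np.asarray(labels)
    min_class = int(np.unique(y, return_counts=True)[1].min())
    if min_class < k:
        logger.warning("reducing CV folds from %d to %d (smallest class)", k, min_class)
        k = min_class
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    X = matrix.reset_index(drop=True)
    for train_idx, test_idx in skf.split(X, y):
        clf = train_ovr(X.iloc[train_idx], y[train_idx], algorithm, seed, n_estimators)
        folds.append(evaluate(clf, X.iloc[test_idx], y[test_idx]))
    arr = np.array(folds)
    return {
        "folds": [tuple(map(float, f)) for f in folds],
        "accuracy": float(arr[:, 0].mean()),
        "recall": float(arr[:, 1].mean()),
        "mcc": float(arr[:, 2].mean()),
        "k": k,
    }


# ---------------------------------------------------------------------------
# validation report

@dataclass
class ValidationReport:
    """Accuracy / macro recall / multiclass MCC on train, CV and test sets."""

    algorithm: str
    seed: int
    train: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    test: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, d in (("train", self.train), ("cv", self.cv), ("test", self.test)):
            if d:
                rows.append({"set": name, **{k: d[k] for k in ("accuracy", "recall", "mcc")}})
        return pd.DataFrame(rows).set_index("set")

    def to_json(self) -> str:
        return json.dumps(
            {
                "algorithm": self.algorithm,
                "seed": self.seed,
                "train": self.train,
                "cv": self.cv,
                "test": self.test,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class QSARModel:
    """End-to-end QSAR workflow over a feature matrix and class labels.

    Applies the variance and correlation filters, balances classes with
    SMOTE, splits into train/test, and fits one-vs-rest classifiers;
    ``fit`` returns a :class:`QSARResults` with the fitted classifiers and
    their validation reports.
    """

    matrix: pd.DataFrame
    labels: Sequence
    variance_threshold: float = 0.1
    correlation_threshold: float = 0.95
    split_ratio: float = 0.8
    balance_mode: str = "balance_then_split"  # or "train_only"
    cv_folds: int = 10
    seed: int = DEFAULT_SEED
    n_estimators: int = 200

    def fit(self, algorithms: Sequence[str] = ("extra_trees",)) -> "QSARResults":
        X, trace_v = variance_filter(self.matrix, self.variance_threshold)
        X, trace_c = correlation_filter(X, self.correlation_threshold)
        trace = FilterTrace(
            trace_v.dropped_low_variance, trace_c.dropped_correlated, trace_c.retained
        )
        y = np.asarray(self.labels)

        if self.balance_mode == "balance_then_split":
            Xb, yb = smote_balance(X, y, seed=self.seed)
            ids = list(range(len(yb)))
            plan = split(ids, yb, self.split_ratio, self.seed)
            X_train, y_train = Xb.iloc[plan.train_ids], yb[plan.train_ids]
            X_test, y_test = Xb.iloc[plan.test_ids], yb[plan.test_ids]
        elif self.balance_mode == "train_only":
            ids = list(range(len(y)))
            plan = split(ids, y, self.split_ratio, self.seed)
            X_train, y_train = smote_balance(
                X.iloc[plan.train_ids], y[plan.train_ids], seed=self.seed
            )
            X_test, y_test = X.iloc[plan.test_ids], y[plan.test_ids]
        else:
            raise ValueError(f"unknown balance_mode {self.balance_mode!r}")

        reports: dict[str, ValidationReport] = {}
        models: dict[str, TrainedClassifier] = {}
        for algorithm in algorithms:
            clf = train_ovr(X_train, y_train, algorithm, self.seed, self.n_estimators)
            rep = ValidationReport(algorithm=algorithm, seed=self.seed)
            for name, (Xs, ys) in (("train", (X_train, y_train)), ("test", (X_test, y_test))):
                a, r, m = evaluate(clf, Xs, ys)
                setattr(rep, name, {"accuracy": a, "recall": r, "mcc": m})
            cv = cross_validate(X_train, y_train, algorithm, self.cv_folds, self.seed, self.n_estimators)
            rep.cv = {k: cv[k] for k in ("accuracy", "recall", "mcc", "k", "folds")}
            reports[algorithm] = rep
            models[algorithm] = clf
        return QSARResults(models=models, reports=reports, filter_trace=trace, split_plan=plan)


@dataclass
class QSARResults:
    models: dict[str, TrainedClassifier]
    reports: dict[str, ValidationReport]
    filter_trace: FilterTrace
    split_plan: SplitPlan

    def summary(self) -> pd.DataFrame:
        frames = []
        for algorithm, rep in self.reports.items():
            df = rep.summary()
            df.insert(0, "algorithm", algorithm)
            frames.append(df.reset_index())
        return pd.concat(frames, ignore_index=True)
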