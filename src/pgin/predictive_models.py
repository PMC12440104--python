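"""KNN outcome classification with cross-validated evaluation.

The classifier is k-nearest-neighbours with uniform weights and Euclidean
distance (k=5 by default); predicted probability is the positive fraction
of the k nearest training points, with distance ties resolved by training
order. Discovery-cohort performance is measured on pooled out-of-fold
predictions from seeded stratified folds so one reproducible ROC curve is
reported per feature set; external validation fits once on the full
training table and scores the held-out table once. Features are not
standardized unless asked: the distance metric then weights raw feature
scales, which is documented behaviour of the default configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from .exceptions import ParameterError

logger = logging.getLogger("pgin")


@dataclass
class ClassifierResult:
    outcome: str
    features: list[str]
    probabilities: pd.Series  # per-sample predicted positive probability
    labels: pd.Series
    fold_assignments: pd.Series | None
    roc_points: np.ndarray  # (n, 2) of (FPR, TPR)
    auc: float
    accuracy: float


def _encode_features(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Numeric feature matrix; fetal sex encoded 0 (female) / 1 (male)."""
    X = pd.DataFrame(index=table.index)
    for f in features:
        if f not in table.columns:
            raise ParameterError(f"feature {f!r} missing from table")
        col = table[f]
        if f == "fetal_sex" or col.dtype == object or str(col.dtype) == "string":
            vals = col.astype(str).str.lower()
            mapping = {"female": 0.0, "male": 1.0, "false": 0.0, "true": 1.0}
            if not vals.isin(mapping).all():
                raise ParameterError(f"cannot encode categorical feature {f!r}")
            X[f] = vals.map(mapping)
        else:
            X[f] = col.astype(float)
    if X.isna().any().any():
        raise ParameterError("missing values in feature matrix")
    return X


def knn_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """Positive-class probability for each test point.

    Probability = fraction of the k Euclidean-nearest training points in
    the positive class.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train).astype(int)
    if k > len(X_train):
        raise ParameterError(f"k={k} exceeds training size {len(X_train)}")
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(X_train, y_train)
    proba = clf.predict_proba(np.asarray(X_test, float))
    classes = list(clf.classes_)
    if 1 not in classes:
        return np.zeros(len(X_test))
    return proba[:, classes.index(1)]


def _metrics(y: np.ndarray, prob: np.ndarray) -> tuple[np.ndarray, float, float]:
    fpr, tpr, _ = roc_curve(y, prob)
    roc = np.column_stack([fpr, tpr])
    return roc, float(auc(fpr, tpr)), float(np.mean((prob >= 0.5).astype(int) == y))


def cross_validate(
    table: pd.DataFrame,
    outcome: str,
    feature_sets: dict[str, list[str]] | list[str],
    k_folds: int = 5,
    k_neighbors: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> dict[str, ClassifierResult]:
    """Stratified k-fold evaluation of one or more feature sets.

    Out-of-fold probabilities are pooled into a single ROC/AUC/accuracy
    per feature set; results are returned ranked by accuracy. Folds are
    reduced (with a warning) if a class is too small to appear in every
    training split.
    """
    if isinstance(feature_sets, list):
        feature_sets = {"+".join(feature_sets): feature_sets}
    y = table[outcome].astype(bool).astype(int).to_numpy()
    n_min = int(min(np.sum(y == 0), np.sum(y == 1)))
    if n_min < 2:
        raise ParameterError(f"outcome {outcome!r} needs both classes with >= 2 samples")
    folds = k_folds
    if n_min < k_folds:
        folds = n_min
        logger.warning("cross_validate: refolding to k=%d (minority class size)", folds)
    results: dict[str, ClassifierResult] = {}
    for name, feats in feature_sets.items():
        X = _encode_features(table, feats).to_numpy()
        prob = np.empty(len(y))
        assign = np.empty(len(y), dtype=int)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            Xtr, Xte = X[tr], X[te]
            if standardize:
                scaler = StandardScaler().fit(Xtr)
                Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
            kk = min(k_neighbors, len(tr))
            prob[te] = knn_predict(Xtr, y[tr], Xte, k=kk)
            assign[te] = fold
        roc, a, acc = _metrics(y, prob)
        results[name] = ClassifierResult(
            outcome=outcome,
            features=list(feats),
            probabilities=pd.Series(prob, index=table.index),
            labels=pd.Series(y, index=table.index),
            fold_assignments=pd.Series(assign, index=table.index),
            roc_points=roc,
            auc=a,
            accuracy=acc,
        )
    return dict(sorted(results.items(), key=lambda kv: -kv[1].accuracy))


def evaluate_external(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    outcome: str,
    features: list[str],
    k: int = 5,
    standardize: bool = False,
) -> ClassifierResult:
    """Fit on the full training table, score the external table once.

    Nothing from the test table enters any fitted quantity (including the
    optional standardization, which is learned on the training rows).
    """
    if len(test_table) == 0:
        raise ParameterError("external test table is empty")
    Xtr = _encode_features(train_table, features).to_numpy()
    Xte = _encode_features(test_table, features).to_numpy()
    ytr = train_table[outcome].astype(bool).astype(int).to_numpy()
    yte = test_table[outcome].astype(bool).astype(int).to_numpy()
    if standardize:
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
    prob = knn_predict(Xtr, ytr, Xte, k=min(k, len(Xtr)))
    roc, a, acc = _metrics(yte, prob)
    return ClassifierResult(
        outcome=outcome,
        features=list(features),
        probabilities=pd.Series(prob, index=test_table.index),
        labels=pd.Series(yte, index=test_table.index),
        fold_assignments=None,
        roc_points=roc,
        auc=a,
        accuracy=acc,
    )
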