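"""Classifier registry, cross-validation harness and best-model selection.

Seven classifier families are evaluated over the assembled datasets. Every
hyperparameter is pinned explicitly in :data:`CLASSIFIER_CONFIG` — "library
defaults" drift across versions, so reproducibility wins over guessing a
historical default set. Each model is a pipeline of a robust scaler (fit on
the training rows only, so no scaling statistics leak from held-out rows)
followed by the classifier.

LOOCV is scored as pooled accuracy over the n held-out predictions
(per-fold balanced accuracy is degenerate when every fold holds a single
record); k-fold CV is scored as mean per-fold balanced accuracy with
stratified folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import RobustScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .datasets import DatasetSpec, EncodedDataset, assemble

logger = logging.getLogger(__name__)

#: Family name -> pinned hyperparameters. Order fixes the tie-break rank.
CLASSIFIER_CONFIG: dict[str, dict] = {
    "KNN": {"n_neighbors": 5, "weights": "uniform"},
    "SVM linear": {"kernel": "linear", "C": 1.0},
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    # LR penalty is L2 (the sklearn default; the explicit kwarg is deprecated)
    "LR": {"C": 1.0, "solver": "lbfgs", "max_iter": 1000},
    "DT": {"criterion": "gini", "max_depth": None},
    "RF": {"n_estimators": 100, "criterion": "gini"},
    "XGB": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
}
CLASSIFIER_FAMILIES = list(CLASSIFIER_CONFIG)
#: Families with internal randomness; their seed is recorded per run.
STOCHASTIC_FAMILIES = {"DT", "RF", "XGB"}
DEFAULT_SEED = 42


def make_classifier(family: str, seed: int = DEFAULT_SEED):
    """Instantiate one pinned classifier; ``seed`` applies to stochastic families."""
    if family not in CLASSIFIER_CONFIG:
        raise KeyError(f"unknown classifier family {family!r}; "
                       f"known: {CLASSIFIER_FAMILIES}")
    params = dict(CLASSIFIER_CONFIG[family])
    if family == "KNN":
        return KNeighborsClassifier(**params)
    if family in ("SVM linear", "SVM"):
        return SVC(**params)
    if family == "LR":
        return LogisticRegression(**params)
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    # single-threaded: xgboost histogram building is only bitwise
    # reproducible at a fixed thread count
    return XGBClassifier(random_state=seed, verbosity=0, n_jobs=1, **params)


def make_model(family: str, seed: int = DEFAULT_SEED) -> Pipeline:
    """Robust-scaler + classifier pipeline, the unit every evaluation fits."""
    return Pipeline([("scale", RobustScaler()),
                     ("clf", make_classifier(family, seed))])


@dataclass
class EvalResult:
    """One (dataset, classifier, CV scheme) evaluation."""

    dataset_id: str
    output: str
    blocks: tuple[str, ...]
    family: str
    cv: str
    score: float
    n_features: int
    n_records: int
    predictions: np.ndarray | None = field(default=None, repr=False)


def fit_predict(X_train, y_train, X_test, family: str,
                seed: int = DEFAULT_SEED) -> np.ndarray:
    """Fit the scaler+classifier pipeline on training rows, predict test rows.

    A single-class training set cannot fit most classifiers; the contract is
    to predict that lone class for every test row, with a logged warning.
    """
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size == 1:
        logger.warning("single-class training set; predicting class %s", classes[0])
        return np.full(np.asarray(X_test).shape[0], classes[0])
    model = make_model(family, seed)
    model.fit(np.asarray(X_train, dtype=float), y_train)
    return model.predict(np.asarray(X_test, dtype=float))


def loocv_accuracy(dataset: EncodedDataset, family: str,
                   seed: int = DEFAULT_SEED) -> EvalResult:
    """Leave-one-out CV: train on n−1 records, predict the held-out one.

    Score is the pooled fraction of correct held-out predictions.
    """
    X = np.asarray(dataset.X, dtype=float)
    y = np.asarray(dataset.y)
    n = len(y)
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 records, got {n}")
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        preds[i] = fit_predict(X[mask], y[mask], X[i:i + 1], family, seed)[0]
    return EvalResult(
        dataset_id=dataset.spec.dataset_id, output=dataset.spec.output,
        blocks=dataset.spec.blocks, family=family, cv="LOOCV",
        score=float(np.mean(preds == y)),
        n_features=X.shape[1], n_records=n, predictions=preds)


def balanced_accuracy(y_true, y_pred) -> float:
    """(sensitivity + specificity)/2 with the degenerate-fold convention.

    A class absent from ``y_true`` has an undefined recall; it is treated as
    0 (and logged), which penalises rather than silently drops degenerate
    folds — sklearn's score instead averages only the classes present.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    recalls = []
    for cls in (0, 1):
        mask = y_true == cls
        if not mask.any():
            logger.warning("balanced_accuracy: class %d absent from fold", cls)
            recalls.append(0.0)
        else:
            recalls.append(float(np.mean(y_pred[mask] == cls)))
    return float(np.mean(recalls))


def kfold_score(dataset: EncodedDataset, family: str, k: int,
                shuffle_seed: int = DEFAULT_SEED,
                seed: int = DEFAULT_SEED) -> EvalResult:
    """Stratified k-fold CV scored as mean per-fold balanced accuracy."""
    X = np.asarray(dataset.X, dtype=float)
    y = np.asarray(dataset.y)
    if k > len(y):
        raise ValueError(f"k={k} exceeds n={len(y)}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=shuffle_seed)
    scores = [
        balanced_accuracy(y[test], fit_predict(X[train], y[train], X[test],
                                               family, seed))
        for train, test in splitter.split(X, y)
    ]
    return EvalResult(
        dataset_id=dataset.spec.dataset_id, output=dataset.spec.output,
        blocks=dataset.spec.blocks, family=family, cv=f"{k}-fold",
        score=float(np.mean(scores)),
        n_features=X.shape[1], n_records=len(y))


def evaluate(dataset: EncodedDataset, family: str, cv: str = "LOOCV",
             seed: int = DEFAULT_SEED) -> EvalResult:
    """Dispatch to LOOCV or k-fold CV by scheme name ('LOOCV' or e.g. '5-fold')."""
    if cv.upper() == "LOOCV":
        return loocv_accuracy(dataset, family, seed)
    k = int(cv.split("-")[0])
    return kfold_score(dataset, family, k, seed=seed)


RESULT_COLUMNS = ["dataset_id", "output", "blocks", "classifier", "cv",
                  "score", "n_features", "n_records"]


def results_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Tidy results table, one row per evaluated model."""
    return pd.DataFrame([
        {"dataset_id": r.dataset_id, "output": r.output,
         "blocks": "+".join(r.blocks), "classifier": r.family, "cv": r.cv,
         "score": r.score, "n_features": r.n_features,
         "n_records": r.n_records}
        for r in results
    ], columns=RESULT_COLUMNS)


def grid_evaluate(df: pd.DataFrame, specs: list[DatasetSpec],
                  families: list[str] | None = None, cv: str = "LOOCV",
                  seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Evaluate the full datasets x classifiers grid; per-cell failures are
    recorded (score NaN) rather than aborting the grid."""
    families = list(families or CLASSIFIER_FAMILIES)
    results: list[EvalResult] = []
    for spec in specs:
        try:
            dataset = assemble(df, spec)
        except Exception:
            logger.exception("assembly failed for %s", spec.dataset_id)
            for family in families:
                results.append(EvalResult(spec.dataset_id, spec.output,
                                          spec.blocks, family, cv, np.nan,
                                          spec.n_columns, 0))
            continue
        for family in families:
            try:
                results.append(evaluate(dataset, family, cv, seed))
            except Exception:
                logger.exception("evaluation failed for %s / %s",
                                 spec.dataset_id, family)
                results.append(EvalResult(spec.dataset_id, spec.output,
                                          spec.blocks, family, cv, np.nan,
                                          spec.n_columns, len(dataset.y)))
    return results_frame(results)


def select_best(results: pd.DataFrame, output: str) -> pd.Series:
    """Best model for one output: argmax score, ties broken by fewer input
    columns then by fixed classifier-family order."""
    sub = results[(results["output"] == output) & results["score"].notna()]
    if sub.empty:
        raise ValueError(f"no results for output {output!r}")
    sub = sub.assign(_rank=sub["classifier"].map(CLASSIFIER_FAMILIES.index))
    sub = sub.sort_values(["score", "n_features", "_rank"],
                          ascending=[False, True, True], kind="mergesort")
    return sub.drop(columns="_rank").iloc[0]


def best_per_output(results: pd.DataFrame) -> pd.DataFrame:
    """One best-model row per output present in the results."""
    outputs = list(dict.fromkeys(results["output"]))
    return pd.DataFrame([select_best(results, o) for o in outputs]) \
        .reset_index(drop=True)
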