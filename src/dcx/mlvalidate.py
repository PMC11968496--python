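"""Classifier-panel validation of cluster genes.

Quantifies how well the expression of a cluster's genes separates disease from
healthy samples: a stratified 80/20 split, per-feature standardization fitted
on the training partition only, and a panel of standard classifiers reporting
accuracy, F1 and recall with the disease class as positive.  A per-gene mode
trains each model on a single gene's expression to rank genes as candidate
markers.

The panel registry covers k-NN, SVM (RBF), decision tree, random forest, MLP,
three gradient-boosting implementations (sklearn's classic and histogram
boosters, plus XGBoost) and LightGBM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import accuracy_score, f1_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ParameterError

__all__ = [
    "MODEL_REGISTRY",
    "ClassificationReport",
    "split_samples",
    "evaluate_panel",
    "per_gene_panel",
]


def _xgboost(seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(random_state=seed, n_estimators=100, verbosity=0, eval_metric="logloss")


def _lightgbm(seed: int):
    from lightgbm import LGBMClassifier

    return LGBMClassifier(random_state=seed, n_estimators=100, verbose=-1)


MODEL_REGISTRY: dict[str, Callable[[int], object]] = {
    "k_neighbors": lambda seed: KNeighborsClassifier(),
    "svm": lambda seed: SVC(random_state=seed),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed, n_estimators=200),
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
    "hist_gradient_boosting": lambda seed: HistGradientBoostingClassifier(random_state=seed),
    "mlp": lambda seed: MLPClassifier(random_state=seed, max_iter=800),
    "xgboost": _xgboost,
    "lightgbm": _lightgbm,
}

FAST_MODELS = ("k_neighbors", "svm", "decision_tree", "random_forest")


@dataclass(frozen=True)
class ClassificationReport:
    model_name: str
    accuracy: float
    f1: float
    recall: float
    n_train: int
    n_test: int
    seed: int


def split_samples(labels: Sequence[str], train_fraction: float = 0.8, seed: int = 0):
    """Deterministic stratified split; returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("both classes must be present")
    if counts.min() < 2:
        raise ParameterError("each class needs at least 2 samples")
    idx = np.arange(len(labels))
    train, test = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed
    )
    return np.sort(train), np.sort(test)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray, StandardScaler]:
    """Fit the scaler on the training partition only (no test leakage)."""
    scaler = StandardScaler().fit(train)
    return scaler.transform(train), scaler.transform(test), scaler


def _resolve(models: Sequence[str] | None) -> list[str]:
    names = list(MODEL_REGISTRY) if models is None else list(models)
    unknown = [m for m in names if m not in MODEL_REGISTRY]
    if unknown:
        raise ParameterError(
            f"unknown models {unknown}; supported: {sorted(MODEL_REGISTRY)}"
        )
    return names


def evaluate_panel(
    features: pd.DataFrame,
    labels: Sequence[str],
    models: Sequence[str] | None = None,
    seed: int = 0,
    train_fraction: float = 0.8,
    positive: str = "disease",
) -> list[ClassificationReport]:
    """Train each panel model on the cluster genes and score the held-out split.

    ``features`` is genes x samples (the expression-matrix orientation);
    ``labels`` gives one condition per sample.
    """
    names = _resolve(models)
    X = features.to_numpy(dtype=float).T  # samples x genes
    y = (np.asarray(labels) == positive).astype(int)
    if len(y) != X.shape[0]:
        raise ParameterError("label count does not match sample count")
    train, test = split_samples(np.asarray(labels), train_fraction, seed)
    X_train, X_test, _ = _standardize(X[train], X[test])
    y_train, y_test = y[train], y[test]
    reports = []
    for name in names:
        model = MODEL_REGISTRY[name](seed)
        model.fit(X_train, y_train)
        pred = np.asarray(model.predict(X_test)).astype(int)
        reports.append(
            ClassificationReport(
                model_name=name,
                accuracy=float(accuracy_score(y_test, pred)),
                f1=float(f1_score(y_test, pred, zero_division=0)),
                recall=float(recall_score(y_test, pred, zero_division=0)),
                n_train=len(train),
                n_test=len(test),
                seed=seed,
            )
        )
    return reports


def per_gene_panel(
    features: pd.DataFrame,
    labels: Sequence[str],
    models: Sequence[str] | None = None,
    seed: int = 0,
    train_fraction: float = 0.8,
    positive: str = "disease",
) -> pd.DataFrame:
    """Single-gene classifiers: one accuracy per (gene, model)."""
    names = _resolve(models)
    rows = []
    for gene in features.index:
        single = features.loc[[gene]]
        for rep in evaluate_panel(single, labels, names, seed, train_fraction, positive):
            rows.append((gene, rep.model_name, rep.accuracy))
    return pd.DataFrame(rows, columns=["gene", "model_name", "accuracy"])


def reports_to_frame(reports: list[ClassificationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
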