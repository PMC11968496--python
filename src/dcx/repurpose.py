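"""Drug-signature filtering and drug-induced fold-change regression.

A drug counts as a repurposing candidate when at least one of its per-gene
signature rows against the cluster genes is significant (p < 0.05 and
q < 0.05) with a fold change outside the (0.67, 1.5) dead zone — the same
linear-scale thresholds used for DEGs.  Candidate sets from different tissue
clusters are intersected to find shared candidates.

The regression stage predicts a drug's per-gene fold change from the gene's
disease fold change plus a one-hot gene encoding, with five model families
under k-fold cross-validation; the reported cv_error is the out-of-fold mean
absolute error.  Small hyperparameter grids are searched inside each training
fold only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .errors import ParameterError, ValidationError

__all__ = [
    "filter_drug_candidates",
    "common_candidates",
    "build_design",
    "predict_fc_panel",
    "REGRESSOR_GRIDS",
]

SIGNATURE_COLUMNS = ["drug", "gene", "drug_fc", "p_value", "q_value", "specificity", "source_id"]

# model family -> (factory, hyperparameter grid searched inside training folds)
REGRESSOR_GRIDS = {
    "linear": (lambda seed: LinearRegression(), {}),
    "svr": (lambda seed: SVR(), {"C": [0.1, 1.0, 10.0]}),
    "random_forest": (
        lambda seed: RandomForestRegressor(random_state=seed, n_estimators=100),
        {"max_depth": [None, 5]},
    ),
    "gradient_boosting": (
        lambda seed: GradientBoostingRegressor(random_state=seed),
        {"max_depth": [2, 3]},
    ),
    "neural_net": (
        lambda seed: MLPRegressor(random_state=seed, max_iter=1500, hidden_layer_sizes=(32,)),
        {},
    ),
}


def _validate_signatures(signatures: pd.DataFrame) -> None:
    fc = signatures["drug_fc"].astype(float)
    bad = signatures.index[fc <= 0]
    if len(bad):
        row = bad[0]
        raise ValidationError(
            f"non-positive drug_fc in row {row}: drug={signatures.loc[row, 'drug']}, "
            f"gene={signatures.loc[row, 'gene']}"
        )


def filter_drug_candidates(
    signatures: pd.DataFrame,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
    cluster_genes: set[str] | None = None,
    min_genes: int = 1,
) -> set[str]:
    """Drugs with >= min_genes signature rows passing p, q and fold-change gates."""
    if not fc_down < 1 < fc_up:
        raise ParameterError(f"need fc_down < 1 < fc_up, got {fc_down}, {fc_up}")
    _validate_signatures(signatures)
    df = signatures
    if cluster_genes is not None:
        df = df[df["gene"].isin(cluster_genes)]
    fc = df["drug_fc"].astype(float)
    passing = df[
        (df["p_value"].astype(float) < alpha)
        & (df["q_value"].astype(float) < alpha)
        & ((fc > fc_up) | (fc < fc_down))
    ]
    counts = passing.groupby("drug").size()
    return set(counts.index[counts >= min_genes].astype(str))


def common_candidates(set_a: set[str], set_b: set[str]) -> set[str]:
    """Drugs shared between two tissue clusters' candidate sets."""
    return set(set_a) & set(set_b)


def build_design(
    signatures: pd.DataFrame, cluster_gene_fcs: dict[str, float]
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix [standardized gene disease-FC | one-hot gene] and drug-FC target.

    Rows are sorted by (drug, gene) for determinism; the index is a
    (drug, gene) MultiIndex so predictions stay attributable.
    """
    unknown = set(signatures["gene"]) - set(cluster_gene_fcs)
    if unknown:
        raise ValidationError(f"signature genes missing from cluster FCs: {sorted(unknown)[:5]}")
    df = signatures.sort_values(["drug", "gene"], kind="stable").reset_index(drop=True)
    gene_fc = df["gene"].map(cluster_gene_fcs).astype(float)
    sd = gene_fc.std(ddof=0)
    z = (gene_fc - gene_fc.mean()) / sd if sd > 0 else gene_fc * 0.0
    onehot = pd.get_dummies(df["gene"], prefix="gene").astype(float)
    X = pd.concat([z.rename("gene_fc_z"), onehot], axis=1)
    X.index = pd.MultiIndex.from_frame(df[["drug", "gene"]])
    y = df["drug_fc"].astype(float)
    y.index = X.index
    return X, y


def predict_fc_panel(
    features: pd.DataFrame,
    target: pd.Series,
    models: Sequence[str] = ("linear", "svr", "random_forest", "gradient_boosting", "neural_net"),
    k_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold fold-change predictions and MAE per model.

    Returns one row per (drug, gene, model) with columns drug, gene,
    model_name, predicted_fc, cv_error (the model's out-of-fold mean absolute
    error, repeated on its rows).
    """
    unknown = [m for m in models if m not in REGRESSOR_GRIDS]
    if unknown:
        raise ParameterError(f"unknown regressors {unknown}; supported: {sorted(REGRESSOR_GRIDS)}")
    n = len(features)
    if n < k_folds:
        raise ParameterError(f"{n} rows is fewer than k_folds={k_folds}")
    X = features.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    frames = []
    for name in models:
        factory, grid = REGRESSOR_GRIDS[name]
        pred = np.empty(n)
        for train, test in folds:
            if grid:
                search = GridSearchCV(factory(seed), grid, cv=3, scoring="neg_mean_absolute_error")
                search.fit(X[train], y[train])
                model = search.best_estimator_
            else:
                model = factory(seed).fit(X[train], y[train])
            pred[test] = model.predict(X[test])
        mae = float(np.abs(pred - y).mean())
        frame = pd.DataFrame(
            {
                "drug": features.index.get_level_values("drug"),
                "gene": features.index.get_level_values("gene"),
                "model_name": name,
                "predicted_fc": pred,
                "cv_error": mae,
            }
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
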