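"""Replicate Random-Forest ensemble.

Each replicate training set is fitted with a classification forest
(bootstrap sample per tree, floor(sqrt(p)) candidate variables per
split). Per-unit probability of occurrence is the class-1 vote fraction
of fully grown trees, averaged across replicates. Out-of-bag (OOB)
error and OOB permutation importance (mean decrease in accuracy) are
computed from each tree's bootstrap indices, matching the convention of
the classical randomForest implementation.

The forest itself is scikit-learn's RandomForestClassifier; the OOB
statistics are computed here because the library does not expose
OOB-permutation importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from streamsdm._seeds import derive_seed
from streamsdm.features import FeatureTable
from streamsdm.labels import TrainingSet


@dataclass
class ModelConfig:
    """Forest settings. 10,001 trees is the documented field default
    (twice the OOB-stabilization point); tests and desk-scale runs use
    fewer."""

    n_trees: int = 10001
    mtry_rule: str = "floor_sqrt"
    n_replicates: int = 10
    oob_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_replicates < 1:
            raise ValueError("n_trees and n_replicates must be >= 1")
        if self.mtry_rule != "floor_sqrt":
            raise ValueError("only the floor_sqrt mtry rule is supported")


@dataclass
class ReplicateModel:
    """One fitted replicate: the forest plus its OOB statistics."""

    replicate_id: int
    forest: RandomForestClassifier
    columns: list[str]
    unit_ids: list[int]
    oob_error: float
    importance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


@dataclass
class EnsemblePrediction:
    """Averaged per-unit probabilities and between-replicate spread."""

    mean: pd.Series  # per-unit mean probability
    matrix: pd.DataFrame  # per-replicate probability columns rep1..repR
    cv: pd.Series  # per-unit coefficient of variation (sd/mean)


def _oob_masks(forest: RandomForestClassifier, n_rows: int) -> list[np.ndarray]:
    masks = []
    for sample_idx in forest.estimators_samples_:
        m = np.ones(n_rows, dtype=bool)
        m[sample_idx] = False
        masks.append(m)
    return masks


def _tree_predict(tree, X32: np.ndarray) -> np.ndarray:
    """Predicted class labels straight from the fitted tree structure
    (skips per-call estimator validation, which dominates otherwise)."""
    leaf_values = tree.tree_.predict(X32)
    if leaf_values.ndim == 3:  # (n, n_outputs, n_classes) in older layouts
        leaf_values = leaf_values[:, 0, :]
    return tree.classes_.take(leaf_values.argmax(axis=1)).astype(int)


def _oob_error(forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray,
               masks: list[np.ndarray]) -> float:
    """OOB misclassification: each row voted on only by trees that did
    not see it; rows never out-of-bag are excluded."""
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    votes = np.zeros((len(y), 2))
    for tree, m in zip(forest.estimators_, masks):
        if not m.any():
            continue
        pred = _tree_predict(tree, X32[m])
        votes[np.where(m)[0], pred] += 1
    has = votes.sum(axis=1) > 0
    oob_pred = votes[has].argmax(axis=1)
    return float(np.mean(oob_pred != y[has]))


def _oob_permutation_importance(forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray,
                                masks: list[np.ndarray], seed: int) -> np.ndarray:
    """Mean decrease in accuracy: per tree, OOB accuracy minus OOB
    accuracy after permuting one variable's OOB values; averaged over
    trees (per-tree independent permutations, randomForest style)."""
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    drops = np.zeros((len(forest.estimators_), p))
    for t, (tree, m) in enumerate(zip(forest.estimators_, masks)):
        idx = np.where(m)[0]
        if idx.size == 0:
            continue
        Xo = X32[idx]
        base = float(np.mean(_tree_predict(tree, Xo) == y[idx]))
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(idx.size), j]
            acc = float(np.mean(_tree_predict(tree, Xp) == y[idx]))
            drops[t, j] = base - acc
    return drops.mean(axis=0)


def fit_replicate(training: TrainingSet, scores: FeatureTable, config: ModelConfig,
                  sub_seed: int, compute_importance: bool = True) -> ReplicateModel:
    """Fit one replicate forest on the balanced training rows.

    ``scores`` must contain every training unit id in its index; trees
    are fully grown, with floor(sqrt(p)) candidate variables per split.
    """
    uids = training.rows["unit_id"].tolist()
    missing = set(uids) - set(scores.index)
    if missing:
        raise ValueError(f"training units missing from feature table: {sorted(missing)[:10]}")
    y = training.rows["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = scores.loc[uids].to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        bootstrap=True,
        n_jobs=1,
        random_state=int(sub_seed),
    )
    forest.fit(X, y)
    masks = _oob_masks(forest, len(y))
    oob = _oob_error(forest, X, y, masks) if config.oob_enabled else float("nan")
    imp = pd.Series(dtype=float)
    if compute_importance and config.oob_enabled:
        vals = _oob_permutation_importance(forest, X, y, masks, derive_seed(sub_seed, "permutation"))
        imp = pd.Series(vals, index=list(scores.columns))
    return ReplicateModel(training.replicate_id, forest, list(scores.columns), uids, oob, imp)


def fit_ensemble(training_sets: list[TrainingSet], scores: FeatureTable, config: ModelConfig,
                 compute_importance: bool = True) -> list[ReplicateModel]:
    """Fit every replicate with sub-seeds derived from the config seed."""
    return [
        fit_replicate(ts, scores, config, derive_seed(config.seed, "forest", ts.replicate_id),
                      compute_importance=compute_importance)
        for ts in training_sets
    ]


def predict_ensemble(models: list[ReplicateModel], scores: FeatureTable) -> EnsemblePrediction:
    """Average the replicates' vote-fraction probabilities per unit."""
    if not models:
        raise ValueError("need at least one replicate model")
    cols = {}
    for m in models:
        if m.columns != list(scores.columns):
            raise ValueError("feature columns differ from those used in fitting")
        proba = m.forest.predict_proba(scores.to_numpy(dtype=float))
        k1 = int(np.where(m.forest.classes_ == 1)[0][0])
        cols[f"rep{m.replicate_id}"] = proba[:, k1]
    matrix = pd.DataFrame(cols, index=scores.index)
    mean = matrix.mean(axis=1)
    if matrix.shape[1] >= 2:
        sd = matrix.std(axis=1, ddof=1)
        cv = (sd / mean.replace(0, np.nan)).fillna(0.0)
    else:
        cv = pd.Series(0.0, index=matrix.index)
    return EnsemblePrediction(mean=mean, matrix=matrix, cv=cv)


def importance_summary(models: list[ReplicateModel]) -> pd.DataFrame:
    """Mean +/- sd of each variable's OOB mean decrease in accuracy
    across replicates, sorted by descending mean."""
    if not models:
        raise ValueError("need at least one replicate model")
    imp = pd.DataFrame({m.replicate_id: m.importance for m in models})
    out = pd.DataFrame({
        "mean_decrease_accuracy": imp.mean(axis=1),
        "sd": imp.std(axis=1, ddof=1).fillna(0.0) if imp.shape[1] > 1 else 0.0,
    })
    return out.sort_values("mean_decrease_accuracy", ascending=False)


def cv_map(prediction: EnsemblePrediction) -> pd.Series:
    """Per-unit coefficient of variation (sd/mean) across replicates."""
    if prediction.matrix.shape[1] < 2:
        raise ValueError("need at least 2 replicates for a CV map")
    return prediction.cv


def bootstrap_oob_fraction(n_rows: int, n_boot: int, seed: int) -> float:
    """Mean fraction of rows excluded from a bootstrap sample of size n.

    Converges to (1 - 1/n)^n -> 1/e ~ 36.8% — the expected OOB share
    per tree in a bagged ensemble.
    """
    rng = np.random.default_rng(seed)
    frac = np.empty(n_boot)
    for b in range(n_boot):
        drawn = rng.integers(0, n_rows, size=n_rows)
        frac[b] = 1.0 - np.unique(drawn).size / n_rows
    return float(frac.mean())
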