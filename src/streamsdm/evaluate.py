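"""Model evaluation.

Threshold-independent performance is the rank-based AUC; probabilities
are binarized at the minimum training-presence threshold (the lowest
averaged probability at any confirmed presence), from which the True
Skill Statistic (sensitivity + specificity - 1) and the
misclassification rate follow. Significance comes from a label
permutation test: the forest is refitted on randomized labels and the
p-value is the proportion of null OOB errors strictly below the
observed one (ties count against significance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from streamsdm.ensemble import EnsemblePrediction, ModelConfig, ReplicateModel, fit_replicate
from streamsdm.features import FeatureTable
from streamsdm.integrate import BinaryMap
from streamsdm.labels import TrainingSet


@dataclass
class EvaluationReport:
    auc: float
    threshold: float
    tss: float
    misclassification: float
    sensitivity: float
    specificity: float
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN)
    p_value: float | None = None
    p_is_upper_bound: bool = False
    per_replicate_auc: list[float] = field(default_factory=list)
    per_replicate_p: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "threshold": self.threshold,
            "tss": self.tss,
            "misclassification": self.misclassification,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": {"TP": self.confusion[0], "FP": self.confusion[1],
                          "TN": self.confusion[2], "FN": self.confusion[3]},
            "per_replicate_auc": self.per_replicate_auc,
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
            d["p_is_upper_bound"] = self.p_is_upper_bound
            d["per_replicate_p"] = self.per_replicate_p
        return d


def auc(probs, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midranks for ties."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(probs, dtype=float)))


def min_presence_threshold(prediction: EnsemblePrediction, presence_units: set[int]) -> float:
    """Lowest averaged probability among confirmed-presence units."""
    if not presence_units:
        raise ValueError("presence set is empty")
    missing = set(presence_units) - set(prediction.mean.index)
    if missing:
        raise ValueError(f"presence unit(s) without a prediction: {sorted(missing)[:10]}")
    return float(prediction.mean.loc[sorted(presence_units)].min())


def binarize(prediction: EnsemblePrediction, tau: float, model_tag: str = "") -> BinaryMap:
    """Habitat iff mean probability >= tau (the threshold itself is habitat)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    return BinaryMap((prediction.mean >= tau).astype(int), model_tag)


def confusion_metrics(binary: BinaryMap, labels: pd.Series) -> dict:
    """Sensitivity, specificity, TSS and misclassification from the 2x2 table."""
    labels = labels.astype(int)
    if len(labels) == 0:
        raise ValueError("empty label set")
    if labels.nunique() < 2:
        raise ValueError("confusion metrics need both classes present")
    pred = binary.values.reindex(labels.index)
    if pred.isna().any():
        raise ValueError("labels include units absent from the binary map")
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "tss": sens + spec - 1.0,
        "misclassification": (fp + fn) / (tp + fp + tn + fn),
        "confusion": (tp, fp, tn, fn),
    }


@dataclass
class PermutationResult:
    p_value: float  # count/n_perm, or 1/n_perm upper bound when count == 0
    count: int
    n_perm: int
    observed_oob: float
    null_oob: np.ndarray
    is_upper_bound: bool

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        rel = "<" if self.is_upper_bound else "="
        return f"PermutationResult(p {rel} {self.p_value:.4g}, observed OOB {self.observed_oob:.3f})"


def permutation_test(training: TrainingSet, scores: FeatureTable, config: ModelConfig,
                     n_perm: int, seed: int) -> PermutationResult:
    """Label-randomization significance test on the OOB error.

    The forest is refitted ``n_perm`` times with labels permuted and
    features fixed; p = (# null OOB errors strictly < observed)/n_perm.
    A zero count is reported as the upper bound p < 1/n_perm, so p is
    always in (0, 1].
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for useful resolution")
    observed = fit_replicate(training, scores, config, seed, compute_importance=False).oob_error
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = training.rows.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        ts = TrainingSet(training.replicate_id, shuffled)
        sub = int(rng.integers(0, 2**31 - 1))
        null[i] = fit_replicate(ts, scores, config, sub, compute_importance=False).oob_error
    count = int(np.sum(null < observed))
    if count == 0:
        return PermutationResult(1.0 / n_perm, 0, n_perm, observed, null, True)
    return PermutationResult(count / n_perm, count, n_perm, observed, null, False)


def evaluate_model(prediction: EnsemblePrediction, presence_units: set[int],
                   negative_units: set[int],
                   per_replicate_negatives: list[set[int]] | None = None) -> EvaluationReport:
    """Back-prediction evaluation of an averaged ensemble.

    AUC pools presences against the union of negatives (verified
    absences plus all replicates' pseudoabsences); per-replicate AUCs
    against each replicate's own negatives are also reported. The
    threshold-dependent metrics use the minimum-presence threshold.
    """
    pres = sorted(presence_units)
    neg = sorted(set(negative_units) - set(presence_units))
    labels = pd.Series(
        [1] * len(pres) + [0] * len(neg), index=pres + neg, dtype=int)
    probs = prediction.mean.reindex(labels.index)
    pooled_auc = auc(probs.to_numpy(), labels.to_numpy())
    rep_aucs = []
    if per_replicate_negatives:
        for rep_neg in per_replicate_negatives:
            rn = sorted(set(rep_neg) - set(pres))
            lab = pd.Series([1] * len(pres) + [0] * len(rn), index=pres + rn, dtype=int)
            rep_aucs.append(auc(prediction.mean.reindex(lab.index).to_numpy(), lab.to_numpy()))
    tau = min_presence_threshold(prediction, presence_units)
    binary = binarize(prediction, tau)
    frag = confusion_metrics(binary, labels)
    return EvaluationReport(
        auc=pooled_auc,
        threshold=tau,
        tss=frag["tss"],
        misclassification=frag["misclassification"],
        sensitivity=frag["sensitivity"],
        specificity=frag["specificity"],
        confusion=frag["confusion"],
        per_replicate_auc=rep_aucs,
    )
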