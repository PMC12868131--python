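"""Metrics, cross-validation and comparison harnesses.

Confusion-matrix metrics:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    SP  = TN / (TN + FP)
    SN  = TP / (TP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is defined as 0 when any denominator factor vanishes (the "random
prediction" point of its [-1, 1] scale); SP or SN with an empty class is
reported as absent (None), not as 0.  AUC is the Mann-Whitney
probability that a random positive outranks a random negative, ties
counted one half.

The harnesses run stratified k-fold cross-validation for any
fit/predict_proba estimator, a nine-classifier comparison (standard
scikit-learn implementations, fixed seeds), and the four-variant
ablation suite of the stage-two network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .data_io import CVPlan
from .deep_model import ModelVariant, NetConfig, SequenceClassifier


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    ACC: float
    SP: float | None
    SN: float | None
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict:
        return {"ACC": self.ACC, "SP": self.SP, "SN": self.SN,
                "MCC": self.MCC, "AUC": self.AUC}


def _check_binary(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values).ravel()
    if not set(np.unique(arr)) <= {0, 1}:
        raise ValueError(f"{name} must be binary 0/1")
    return arr.astype(int)


def confusion_counts(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    y = _check_binary(np.asarray(labels), "labels")
    p = _check_binary(np.asarray(predictions), "predictions")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.size} labels vs {p.size} predictions")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FP=int(np.sum((y == 0) & (p == 1))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def compute_metrics(c: ConfusionCounts, auc: float | None = None) -> MetricSet:
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = (c.TP + c.TN) / c.total
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = 0.0 if denom == 0 else (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
    return MetricSet(ACC=acc, SP=sp, SN=sn, MCC=float(mcc), AUC=auc)


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    y = _check_binary(np.asarray(labels), "labels")
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise ValueError("labels and scores length mismatch")
    if len(set(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


def roc_points(labels: Sequence[int], scores: Sequence[float]) -> pd.DataFrame:
    """ROC operating points (fpr, tpr, threshold) for curve export."""
    y = _check_binary(np.asarray(labels), "labels")
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def evaluate_predictions(labels, predictions, scores=None) -> MetricSet:
    auc = roc_auc(labels, scores) if scores is not None else None
    return compute_metrics(confusion_counts(labels, predictions), auc=auc)


# ---------------------------------------------------------------------------
# cross-validation

def _validate_plan(plan: CVPlan, index: pd.Index) -> None:
    assigned = set(plan.fold_assignments)
    rows = set(index)
    if assigned != rows:
        raise ValueError("CV plan does not cover exactly the feature rows")
    folds = set(plan.fold_assignments.values())
    if folds != set(range(plan.n_folds)):
        raise ValueError("CV plan fold indices are not 0..n_folds-1")


def cross_validate(
    features: pd.DataFrame,
    labels: pd.Series | dict,
    plan: CVPlan,
    model_factory: Callable[[int], object],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-fold metrics for any fit/predict(_proba) estimator.

    ``model_factory(fold)`` must return a fresh estimator with sklearn's
    ``fit(X, y)`` and either ``predict_proba`` or ``decision_function``.
    Returns one row per fold plus ``mean`` and ``sd`` rows.
    """
    _validate_plan(plan, features.index)
    y = pd.Series(labels).reindex(features.index)
    rows = []
    for fold in range(plan.n_folds):
        tr, va = plan.train_ids(fold), plan.fold_ids(fold)
        y_tr = y.loc[tr].to_numpy(dtype=int)
        y_va = y.loc[va].to_numpy(dtype=int)
        if len(set(y_va)) < 2 or len(set(y_tr)) < 2:
            raise ValueError(f"fold {fold} has a single class")
        est = model_factory(fold)
        est.fit(features.loc[tr].to_numpy(), y_tr)
        X_va = features.loc[va].to_numpy()
        scores = _scores_of(est, X_va)
        preds = (scores >= _threshold_of(est)).astype(int)
        ms = evaluate_predictions(y_va, preds, scores)
        rows.append({"fold": fold, **ms.as_dict()})
    table = pd.DataFrame(rows).set_index("fold")
    table.loc["mean"] = table.mean(numeric_only=True)
    table.loc["sd"] = table.drop(index=["mean"]).std(numeric_only=True)
    return table


def _scores_of(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        return proba[:, 1] if proba.ndim == 2 else np.asarray(proba).ravel()
    return np.asarray(est.decision_function(X)).ravel()


def _threshold_of(est) -> float:
    return 0.5 if hasattr(est, "predict_proba") else 0.0


# ---------------------------------------------------------------------------
# comparison harnesses

CLASSIFIER_NAMES = ("KNN", "DT", "LR", "NB", "RF", "AdaBoost", "Bagging", "SGD", "MLP")


def _baseline_classifier(name: str, seed: int):
    return {
        "KNN": lambda: KNeighborsClassifier(),
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "LR": lambda: LogisticRegression(max_iter=1000, random_state=seed),
        "NB": lambda: GaussianNB(),
        "RF": lambda: RandomForestClassifier(random_state=seed),
        "AdaBoost": lambda: AdaBoostClassifier(random_state=seed),
        "Bagging": lambda: BaggingClassifier(random_state=seed),
        "SGD": lambda: SGDClassifier(loss="log_loss", random_state=seed),
        "MLP": lambda: MLPClassifier(max_iter=300, random_state=seed),
    }[name]()


def compare_classifiers(
    features: pd.DataFrame,
    labels: pd.Series | dict,
    plan: CVPlan,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean CV metrics for the nine standard classifiers.

    A classifier whose fit fails contributes a row of NaNs (with the
    error recorded in the ``error`` column) instead of aborting the table.
    """
    rows = []
    for name in CLASSIFIER_NAMES:
        try:
            table = cross_validate(
                features, labels, plan,
                model_factory=lambda fold, n=name: _baseline_classifier(n, seed),
            )
            mean = table.loc["mean"]
            rows.append({"classifier": name, "ACC": mean["ACC"], "SP": mean["SP"],
                         "SN": mean["SN"], "MCC": mean["MCC"], "AUC": mean["AUC"],
                         "error": ""})
        except Exception as exc:  # per-classifier failures must not abort
            rows.append({"classifier": name, "ACC": np.nan, "SP": np.nan,
                         "SN": np.nan, "MCC": np.nan, "AUC": np.nan,
                         "error": str(exc)})
    return pd.DataFrame(rows).set_index("classifier")


class _DeepEstimator:
    """sklearn-style adapter around SequenceClassifier for the harnesses.

    Splits off a fraction of the training fold as the early-stopping
    validation set (stratified, seeded).
    """

    def __init__(self, variant, config: NetConfig, val_fraction: float = 0.1):
        self.variant, self.config, self.val_fraction = variant, config, val_fraction
        self.model: SequenceClassifier | None = None

    def fit(self, X, y):
        rng = np.random.default_rng(self.config.seed)
        y = np.asarray(y)
        val_idx = []
        for cls in (0, 1):
            members = np.flatnonzero(y == cls)
            rng.shuffle(members)
            n_val = max(1, int(round(self.val_fraction * len(members))))
            val_idx.extend(members[:n_val])
        val_mask = np.zeros(len(y), dtype=bool)
        val_mask[val_idx] = True
        self.model = SequenceClassifier(self.variant, self.config)
        self.model.fit(X[~val_mask], y[~val_mask], X[val_mask], y[val_mask])
        return self

    def predict_proba(self, X):
        p = self.model.predict_proba(X)
        return np.column_stack([1 - p, p])


def ablation_suite(
    features: pd.DataFrame,
    labels: pd.Series | dict,
    plan: CVPlan,
    config: NetConfig | None = None,
) -> pd.DataFrame:
    """Mean CV metrics for FULL and the V1/V2/V3 ablations on shared folds."""
    config = config or NetConfig(input_dim=features.shape[1])
    rows = []
    split_hash = hash(tuple(sorted(plan.fold_assignments.items())))
    for variant in ModelVariant:
        table = cross_validate(
            features, labels, plan,
            model_factory=lambda fold, v=variant: _DeepEstimator(v, config),
        )
        mean = table.loc["mean"]
        rows.append({
            "variant": variant.value, "ACC": mean["ACC"], "SP": mean["SP"],
            "SN": mean["SN"], "MCC": mean["MCC"], "AUC": mean["AUC"],
            "split_hash": split_hash,
        })
    return pd.DataFrame(rows).set_index("variant")


def write_metric_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t")
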