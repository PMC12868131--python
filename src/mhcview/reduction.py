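"""Stage-one dimensionality reduction.

Fused embeddings are standardized (center + unit scale) and projected
onto a PCA basis fitted on training rows only.  The component count k
is chosen by a cross-validated search: for each candidate k an MLP
evaluator is trained on the leading k components of each fold's
training part and scored on the fold's validation part; the k with the
highest mean validation accuracy wins (ties broken toward the smaller
k).  At full scale the search runs k = 1..400; the shipped default for
the fused 5,120-dim space is k = 224, the optimum of that search on
the reference dataset.

Fold-wise refits keep the scaler and basis free of validation-row
leakage; the final model is refit once on all train/val rows at the
selected k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .data_io import CVPlan

#: search-selected component count for the 5,120-dim fused space
DEFAULT_COMPONENTS = 224


@dataclass
class ReductionModel:
    """Fitted standardization + PCA basis truncated at k components."""

    input_dim: int
    k: int
    feature_means: np.ndarray
    feature_scales: np.ndarray
    components: np.ndarray  # (k, input_dim), rows orthonormal
    explained_variance: np.ndarray  # (k,), non-increasing

    def transform(self, features: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        return apply_reduction(self, features)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savez(
            prefix.with_suffix(".npz"),
            feature_means=self.feature_means,
            feature_scales=self.feature_scales,
            components=self.components,
            explained_variance=self.explained_variance,
        )
        prefix.with_suffix(".json").write_text(
            json.dumps({"input_dim": self.input_dim, "k": self.k}, indent=1)
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "ReductionModel":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        arrays = np.load(prefix.with_suffix(".npz"))
        return cls(
            meta["input_dim"], meta["k"],
            arrays["feature_means"], arrays["feature_scales"],
            arrays["components"], arrays["explained_variance"],
        )


@dataclass
class DimensionSearchResult:
    k_grid: list[int]
    scores: dict[int, float]  # mean CV accuracy per k
    per_fold_scores: dict[int, list[float]]
    best_k: int
    evaluator_config: dict

    def to_tsv(self, path: str | Path) -> None:
        n_folds = len(next(iter(self.per_fold_scores.values())))
        header = "k\tmean_score\t" + "\t".join(f"fold{i}" for i in range(n_folds))
        lines = [header]
        for k in self.k_grid:
            folds = "\t".join(f"{s:.6f}" for s in self.per_fold_scores[k])
            lines.append(f"{k}\t{self.scores[k]:.6f}\t{folds}")
        Path(path).write_text("\n".join(lines) + "\n")


def _as_matrix(features: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def fit_reduction(train_features: pd.DataFrame | np.ndarray, k: int) -> ReductionModel:
    """Fit scaler + PCA on training rows only and keep k components."""
    X = _as_matrix(train_features)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 training rows")
    if not 1 <= k <= min(d, n - 1):
        raise ValueError(
            f"k={k} outside valid range 1..{min(d, n - 1)} "
            f"(input_dim={d}, n_train={n})"
        )
    scaler = StandardScaler().fit(X)
    scale = np.where(scaler.scale_ == 0.0, 1.0, scaler.scale_)  # constant columns
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    pca.fit((X - scaler.mean_) / scale)
    return ReductionModel(
        input_dim=d,
        k=k,
        feature_means=scaler.mean_,
        feature_scales=scale,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
    )


def apply_reduction(
    model: ReductionModel, features: pd.DataFrame | np.ndarray
) -> pd.DataFrame | np.ndarray:
    """Project rows with the stored training statistics (no refitting)."""
    X = _as_matrix(features)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match model input_dim {model.input_dim}"
        )
    Z = ((X - model.feature_means) / model.feature_scales) @ model.components.T
    if isinstance(features, pd.DataFrame):
        return pd.DataFrame(
            Z, index=features.index, columns=[f"pc{i:03d}" for i in range(model.k)]
        )
    return Z


def _default_evaluator(config: dict, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(config.get("hidden", 128),),
        max_iter=config.get("max_iter", 200),
        early_stopping=config.get("early_stopping", True),
        n_iter_no_change=config.get("patience", 10),
        random_state=seed,
    )


def search_dimension(
    train_val_features: pd.DataFrame,
    labels: pd.Series | dict,
    cv: CVPlan,
    k_grid: Sequence[int] | None = None,
    evaluator_config: dict | None = None,
    seed: int = 0,
) -> DimensionSearchResult:
    """Cross-validated component-count search with an MLP evaluator.

    For each fold the scaler and PCA basis are fitted on the fold's
    training rows at max(k_grid) components; each candidate k then uses
    the leading k components (valid because PCA bases are nested).
    """
    if k_grid is None:
        k_grid = range(1, 401)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid or k_grid[0] < 1:
        raise ValueError("k_grid must contain positive integers")
    evaluator_config = dict(evaluator_config or {})
    y = pd.Series(labels).reindex(train_val_features.index)
    if y.isna().any():
        raise ValueError("labels missing for some feature rows")
    per_fold: dict[int, list[float]] = {k: [] for k in k_grid}
    for fold in range(cv.n_folds):
        val_ids = cv.fold_ids(fold)
        train_ids = cv.train_ids(fold)
        X_tr = train_val_features.loc[train_ids]
        X_va = train_val_features.loc[val_ids]
        y_tr = y.loc[train_ids].to_numpy(dtype=int)
        y_va = y.loc[val_ids].to_numpy(dtype=int)
        if len(set(y_tr)) < 2 or len(set(y_va)) < 2:
            raise ValueError(f"fold {fold} is single-class; cannot evaluate")
        k_max = k_grid[-1]
        limit = min(X_tr.shape[1], X_tr.shape[0] - 1)
        if k_max > limit:
            raise ValueError(f"k={k_max} exceeds fold limit {limit}")
        model = fit_reduction(X_tr, k_max)
        Z_tr = apply_reduction(model, X_tr).to_numpy()
        Z_va = apply_reduction(model, X_va).to_numpy()
        for k in k_grid:
            clf = _default_evaluator(evaluator_config, seed)
            clf.fit(Z_tr[:, :k], y_tr)
            per_fold[k].append(float(clf.score(Z_va[:, :k], y_va)))
    scores = {k: float(np.mean(v)) for k, v in per_fold.items()}
    best = max(scores.values())
    best_k = min(k for k, s in scores.items() if s == best)  # ties → smallest k
    return DimensionSearchResult(
        k_grid=list(k_grid),
        scores=scores,
        per_fold_scores=per_fold,
        best_k=best_k,
        evaluator_config=evaluator_config,
    )
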