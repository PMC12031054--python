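"""Regression metrics, train/validation splitting, and cross-validation.

RMSE = sqrt(mean squared residual); R² = 1 − SS_res/SS_tot (may be
negative for a model worse than the mean predictor).  The 80/20 split
and the 5-fold partition are seeded shuffles; all models inside one
cross-validation share the identical fold assignment, and the feature
selection + PCA preprocessing is refitted on the training folds only so
no validation information leaks into the transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .errors import ConfigError
from .selection import correlation_report, fit_pca, select_features, transform_pca

__all__ = ["rmse", "r_squared", "split_80_20", "kfold_indices", "cross_validate", "CVReport"]


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error of predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("cannot compute RMSE of empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 2:
        raise ValueError("R² needs at least 2 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² is undefined for constant observations")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def split_80_20(n: int, seed: int = 20240625) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint-exhaustive shuffle split; |val| = round(0.2·n)."""
    if n < 5:
        raise ValueError(f"need at least 5 samples for an 80/20 split, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    n_val = int(round(0.2 * n))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def kfold_indices(n: int, k: int = 5, seed: int = 20240625) -> np.ndarray:
    """Fold label (0..k-1) per sample; folds differ in size by at most 1."""
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    perm = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return labels


class Estimator(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Estimator": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class CVReport:
    """Per-fold and aggregated metrics for a set of models."""

    folds: np.ndarray                      # fold label per sample
    seed: int
    per_fold: pd.DataFrame                 # model, fold, train/val R² & RMSE
    summary: pd.DataFrame                  # model × mean/sd of the four metrics

    def to_markdown(self) -> str:
        cols = ["train_r2_mean", "train_r2_sd", "train_rmse_mean", "train_rmse_sd",
                "val_r2_mean", "val_r2_sd", "val_rmse_mean", "val_rmse_sd"]
        return self.summary[cols].round(4).to_markdown()


def cross_validate(
    models: dict[str, Callable[[], Estimator]],
    table: pd.DataFrame,
    k: int = 5,
    seed: int = 20240625,
    selection_mode: str = "canonical",
    selection_threshold: float = 0.7,
    n_components: int = 5,
    fold_safe: bool = True,
) -> CVReport:
    """k-fold cross-validation of several models on a feature table.

    ``models`` maps a display name to a zero-argument factory producing
    a fresh estimator.  With ``fold_safe`` (default) the correlation
    screening and PCA are refitted inside each training fold; disabling
    it reproduces the historical fit-once-on-everything protocol, which
    leaks validation information into the transform.
    """
    y = table["spad"].to_numpy(dtype=float)
    n = len(table)
    folds = kfold_indices(n, k=k, seed=seed)
    for f in range(k):
        if np.ptp(y[folds == f]) == 0:
            raise ConfigError(f"fold {f} has constant SPAD values; metrics are undefined")

    if not fold_safe:
        rep = correlation_report(table, threshold=selection_threshold)
        feats = select_features(rep, mode=selection_mode, threshold=selection_threshold)
        pca_all = fit_pca(table[feats], k_fixed=n_components)
        scores_all = transform_pca(pca_all, table[feats])

    rows = []
    for f in range(k):
        tr, va = folds != f, folds == f
        if fold_safe:
            rep = correlation_report(table.loc[tr], threshold=selection_threshold)
            feats = select_features(rep, mode=selection_mode, threshold=selection_threshold)
            pca = fit_pca(table.loc[tr, feats], k_fixed=n_components)
            Xtr = transform_pca(pca, table.loc[tr, feats])
            Xva = transform_pca(pca, table.loc[va, feats])
        else:
            Xtr, Xva = scores_all[tr], scores_all[va]
        for name, factory in models.items():
            est = factory().fit(Xtr, y[tr])
            ptr, pva = est.predict(Xtr), est.predict(Xva)
            rows.append({
                "model": name, "fold": f,
                "train_r2": r_squared(y[tr], ptr), "train_rmse": rmse(y[tr], ptr),
                "val_r2": r_squared(y[va], pva), "val_rmse": rmse(y[va], pva),
            })
    per_fold = pd.DataFrame(rows)
    agg = per_fold.groupby("model", sort=False).agg(
        train_r2_mean=("train_r2", "mean"), train_r2_sd=("train_r2", "std"),
        train_rmse_mean=("train_rmse", "mean"), train_rmse_sd=("train_rmse", "std"),
        val_r2_mean=("val_r2", "mean"), val_r2_sd=("val_r2", "std"),
        val_rmse_mean=("val_rmse", "mean"), val_rmse_sd=("val_rmse", "std"),
    )
    return CVReport(folds=folds, seed=seed, per_fold=per_fold, summary=agg)
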