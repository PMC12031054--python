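"""Correlation-based feature screening and PCA reduction.

Each color index is Pearson-correlated with the measured SPAD values;
strongly correlated indices (|r| above a threshold, or the published
21-feature list) are retained.  Because the retained indices are highly
collinear, they are reduced with principal component analysis on
standardised features (correlation-matrix PCA): raw channels live on a
0–255 scale while ratio indices live near 1, so covariance PCA would be
dominated by the raw channels.  The leading component scores become the
regression inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .errors import ConfigError, SchemaError
from .color_features import FEATURE_NAMES, CANONICAL_FEATURES

__all__ = [
    "pearson_r",
    "correlation_report",
    "select_features",
    "PCAModel",
    "fit_pca",
    "transform_pca",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient between two vectors.

    Both vectors must have equal length >= 3 and be non-constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"expected equal-length 1-D vectors, got {x.shape} and {y.shape}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def correlation_report(table: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Correlate every feature column with the ``spad`` column.

    Returns a DataFrame indexed by feature with columns ``r``, ``n`` and
    ``selected`` (|r| >= threshold).  Rows with missing feature values
    are dropped per feature before correlating.
    """
    if "spad" not in table.columns:
        raise SchemaError("feature table lacks a 'spad' column")
    feats = [c for c in table.columns if c != "spad"]
    rows = []
    for name in feats:
        sub = table[[name, "spad"]].dropna()
        r = pearson_r(sub[name].to_numpy(), sub["spad"].to_numpy())
        rows.append({"feature": name, "r": r, "n": len(sub), "selected": abs(r) >= threshold})
    return pd.DataFrame(rows).set_index("feature")


def select_features(
    report: pd.DataFrame,
    mode: str = "canonical",
    threshold: float = 0.7,
) -> list[str]:
    """Choose the feature subset fed to PCA.

    ``canonical`` returns the canonical 21-index list in its published
    order (all must be present in the report); ``threshold`` returns
    every feature with |r| >= threshold, ordered by |r| descending
    (ties by report order).
    """
    if mode == "canonical":
        missing = [f for f in CANONICAL_FEATURES if f not in report.index]
        if missing:
            raise ConfigError(f"features missing from the correlation report: {missing}")
        return list(CANONICAL_FEATURES)
    if mode == "threshold":
        absr = report["r"].abs()
        keep = report.index[absr >= threshold]
        order = absr[keep].sort_values(ascending=False, kind="stable")
        return list(order.index)
    raise ConfigError(f"unknown selection mode {mode!r} (use 'canonical' or 'threshold')")


@dataclass
class PCAModel:
    """Standardise-then-project PCA model.

    Stores per-feature means/SDs, the loading matrix (features ×
    components, orthonormal columns) and explained-variance ratios.
    The sign of each loading column is fixed so that its largest-
    magnitude element is positive, making scores reproducible bit for
    bit across runs.
    """

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # p × k
    explained_variance_ratio: np.ndarray
    n_components: int
    training_scores: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": 1,
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components": self.n_components,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=list(d["feature_names"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
            n_components=int(d["n_components"]),
        )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        peak = np.argmax(np.abs(col))
        if col[peak] < 0:
            out[:, j] = -col
    return out


def fit_pca(
    X: pd.DataFrame | np.ndarray,
    variance_target: float = 0.9999,
    k_fixed: int | None = 5,
    feature_names: list[str] | None = None,
) -> PCAModel:
    """Fit standardised PCA, keeping ``k_fixed`` components if given,
    else the smallest k whose cumulative explained-variance ratio
    reaches ``variance_target``.

    Columns with zero variance are rejected by name.  Missing values
    are not allowed.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
    if not 0 < variance_target <= 1:
        raise ConfigError(f"variance_target must be in (0, 1], got {variance_target}")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = [feature_names[i] for i in np.flatnonzero(sds == 0)]
    if dead:
        raise ValueError(f"zero-variance feature column(s): {dead}")
    Z = (X - means) / sds

    full = _SKPCA(n_components=min(Z.shape), svd_solver="full")
    full.fit(Z)
    ratios = full.explained_variance_ratio_
    if k_fixed is not None:
        if not 1 <= k_fixed <= len(ratios):
            raise ConfigError(f"k_fixed must be in [1, {len(ratios)}], got {k_fixed}")
        k = int(k_fixed)
    else:
        k = int(np.searchsorted(np.cumsum(ratios), variance_target - 1e-12) + 1)
        k = min(k, len(ratios))
    loadings = _fix_signs(full.components_[:k].T)
    model = PCAModel(
        feature_names=feature_names,
        means=means,
        sds=sds,
        loadings=loadings,
        explained_variance_ratio=ratios[:k].copy(),
        n_components=k,
    )
    model.training_scores = transform_pca(model, pd.DataFrame(X, columns=feature_names))
    return model


def transform_pca(model: PCAModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Project new rows onto the fitted components (m × k scores)."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        X = X[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
            )
    Z = (X - model.means) / model.sds
    return Z @ model.loadings


def inverse_transform_pca(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map component scores back to the original feature space."""
    Z = np.asarray(scores, dtype=float) @ model.loadings.T
    return Z * model.sds + model.means
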