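"""Kernel regressors: ε-insensitive SVR and relevance vector machine.

SVR minimises ½‖w‖² + C·Σ(ξᵢ+ξᵢ*) subject to every residual lying
within an ε-tube up to the slacks — the solver is libsvm via
scikit-learn, wrapped behind a serialisable model object.

The RVM is a sparse Bayesian linear model over kernel basis functions
(one per training sample, plus a bias): each weight wᵢ carries its own
Gaussian prior precision αᵢ, and type-II maximum likelihood drives most
αᵢ to infinity, pruning their basis functions.  The surviving training
samples are the relevance vectors.  Predictions come with a variance,
σ² + φ(x*)ᵀ Σ φ(x*).  No scikit-learn equivalent exists, so the
fixed-point update scheme (Tipping-style) is implemented here:

    Σ = (σ⁻² ΦᵀΦ + A)⁻¹          A = diag(α)
    μ = σ⁻² Σ Φᵀ y
    γᵢ = 1 − αᵢ Σᵢᵢ
    αᵢ ← γᵢ / μᵢ²
    σ² ← ‖y − Φμ‖² / (n − Σγᵢ)

iterated until the log-α vector stabilises.  Both fitters are fully
deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVR as _SKSVR

from .errors import ConfigError, DegenerateFit, SchemaError

__all__ = [
    "SVRConfig",
    "SVRModel",
    "fit_svr",
    "predict_svr",
    "RVMModel",
    "fit_rvm",
    "predict_rvm",
]

ALPHA_PRUNE_CAP = 1e9


# ---------------------------------------------------------------------------
# support vector regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameters of ε-insensitive SVR.

    C is the slack penalty, ``epsilon`` the tube half-width on the SPAD
    scale.  ``gamma`` is the RBF/poly kernel width; it is inert for a
    linear kernel (stored, warned about, ignored).
    """

    C: float = 10.0
    epsilon: float = 0.1
    kernel: str = "linear"
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigError(f"C must be positive, got {self.C}")
        if self.epsilon < 0:
            raise ConfigError(f"epsilon must be non-negative, got {self.epsilon}")
        if self.kernel not in ("linear", "rbf", "poly"):
            raise ConfigError(f"kernel must be linear/rbf/poly, got {self.kernel!r}")
        if self.gamma <= 0:
            raise ConfigError(f"gamma must be positive, got {self.gamma}")


@dataclass
class SVRModel:
    """Fitted SVR: support vectors, their dual coefficients, and bias."""

    config: SVRConfig
    support_vectors: np.ndarray  # s × k
    dual_coef: np.ndarray        # s, each in [-C, C]
    intercept: float
    n_features: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "schema_version": 1,
            "model": "svr",
            "config": vars(self.config) | {},
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "n_features": self.n_features,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "SVRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            config=SVRConfig(**d["config"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            n_features=int(d["n_features"]),
        )


def _kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: str, gamma: float) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "rbf":
        sq = (A * A).sum(1)[:, None] + (B * B).sum(1)[None, :] - 2 * A @ B.T
        return np.exp(-gamma * np.maximum(sq, 0))
    if kernel == "poly":
        return (gamma * (A @ B.T)) ** 3
    raise ConfigError(f"unknown kernel {kernel!r}")


def fit_svr(X: np.ndarray, y: np.ndarray, cfg: SVRConfig | None = None) -> SVRModel:
    """Solve the ε-insensitive SVR problem on (X, y)."""
    cfg = cfg or SVRConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("SVR input contains non-finite values")
    if len(X) < 2:
        raise ValueError(f"need at least 2 samples, got {len(X)}")
    if cfg.kernel == "linear" and cfg.gamma != 1.0:
        warnings.warn("gamma has no effect with a linear kernel; it is stored but ignored",
                      stacklevel=2)
    # iteration cap: near-interpolating fits (huge C, tiny ε) otherwise
    # let the solver spin ~forever chasing the last 1e-9 of the gap
    sk = _SKSVR(kernel=cfg.kernel, C=cfg.C, epsilon=cfg.epsilon,
                gamma=cfg.gamma, degree=3, coef0=0.0, tol=1e-9, max_iter=1_000_000)
    sk.fit(X, y)
    return SVRModel(
        config=cfg,
        support_vectors=sk.support_vectors_.copy(),
        dual_coef=sk.dual_coef_.ravel().copy(),
        intercept=float(sk.intercept_[0]),
        n_features=X.shape[1],
    )


def predict_svr(model: SVRModel, X: np.ndarray) -> np.ndarray:
    """f(x) = Σᵢ dualᵢ·K(svᵢ, x) + b."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != model.n_features:
        raise SchemaError(f"expected {model.n_features} features, got {X.shape[1]}")
    K = _kernel_matrix(X, model.support_vectors, model.config.kernel, model.config.gamma)
    return K @ model.dual_coef + model.intercept


def svr_primal_objective(model: SVRModel, X: np.ndarray, y: np.ndarray) -> float:
    """Value of ½‖w‖² + C·Σ(ξᵢ+ξᵢ*) at the fitted solution.

    ‖w‖² is computed in the kernel-induced feature space from the dual
    coefficients; slacks are the residual excess over the ε-tube.
    """
    K = _kernel_matrix(model.support_vectors, model.support_vectors,
                       model.config.kernel, model.config.gamma)
    w_sq = float(model.dual_coef @ K @ model.dual_coef)
    resid = np.abs(np.asarray(y, dtype=float) - predict_svr(model, X))
    slack = np.maximum(resid - model.config.epsilon, 0.0).sum()
    return 0.5 * w_sq + model.config.C * slack


# ---------------------------------------------------------------------------
# relevance vector machine
# ---------------------------------------------------------------------------

@dataclass
class RVMModel:
    """Fitted RVM over kernel basis functions.

    ``active`` indexes retained basis functions in the full design
    matrix [bias, K(·, x₁), …, K(·, xₙ)]; relevance vectors are the
    training samples whose column survived pruning.
    """

    kernel: str
    gamma: float
    X_train: np.ndarray
    active: np.ndarray              # indices into the n+1 basis columns
    weight_mean: np.ndarray         # posterior mean over active basis
    weight_cov: np.ndarray
    alpha: np.ndarray               # precisions of active weights
    noise_var: float
    log_marginal_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def relevance_indices(self) -> np.ndarray:
        """Training-sample indices acting as relevance vectors (bias excluded)."""
        return self.active[self.active > 0] - 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "schema_version": 1,
            "model": "rvm",
            "kernel": self.kernel,
            "gamma": self.gamma,
            "X_train": self.X_train.tolist(),
            "active": self.active.tolist(),
            "weight_mean": self.weight_mean.tolist(),
            "weight_cov": self.weight_cov.tolist(),
            "alpha": self.alpha.tolist(),
            "noise_var": self.noise_var,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "RVMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            kernel=d["kernel"], gamma=float(d["gamma"]),
            X_train=np.asarray(d["X_train"], dtype=float),
            active=np.asarray(d["active"], dtype=int),
            weight_mean=np.asarray(d["weight_mean"], dtype=float),
            weight_cov=np.asarray(d["weight_cov"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            noise_var=float(d["noise_var"]),
        )


def _rvm_design(X: np.ndarray, X_train: np.ndarray, kernel: str, gamma: float) -> np.ndarray:
    if kernel == "linear":
        K = X @ X_train.T
    elif kernel == "gaussian":
        sq = (X * X).sum(1)[:, None] + (X_train * X_train).sum(1)[None, :] - 2 * X @ X_train.T
        K = np.exp(-gamma * np.maximum(sq, 0))
    else:
        raise ConfigError(f"RVM kernel must be 'linear' or 'gaussian', got {kernel!r}")
    return np.hstack([np.ones((len(X), 1)), K])


def _log_marginal(Phi: np.ndarray, y: np.ndarray, alpha: np.ndarray, noise_var: float) -> float:
    n = len(y)
    C = noise_var * np.eye(n) + (Phi / alpha) @ Phi.T
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + y @ np.linalg.solve(C, y)))


def fit_rvm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "gaussian",
    gamma: float = 0.01,
    max_iter: int = 3000,
    tol: float = 1e-6,
    fixed_alpha: float | None = None,
    fixed_noise_var: float | None = None,
) -> RVMModel:
    """Type-II maximum-likelihood RVM regression fit.

    Deterministic initialisation (αᵢ = 1, σ² = 0.1·var(y)); basis
    functions whose precision exceeds 1e9 are pruned each sweep.
    Raises :class:`DegenerateFit` if every basis function is pruned.

    ``fixed_alpha``/``fixed_noise_var`` freeze the hyperparameters and
    disable pruning, reducing the fit to a single dense Bayesian
    linear-regression (ridge) posterior solve — useful for validation
    against closed-form results.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    Phi_full = _rvm_design(X, X, kernel, gamma)
    m = Phi_full.shape[1]

    active = np.arange(m)
    alpha = np.ones(m)
    noise_var = max(0.1 * float(np.var(y)), 1e-9)
    trace: list[float] = []
    mu = np.zeros(m)
    Sigma = np.eye(m)

    if fixed_alpha is not None or fixed_noise_var is not None:
        alpha = np.full(m, fixed_alpha if fixed_alpha is not None else 1.0)
        if fixed_noise_var is not None:
            noise_var = float(fixed_noise_var)
        max_iter = 0

    for _ in range(max_iter):
        Phi = Phi_full[:, active]
        A = np.diag(alpha)
        H = Phi.T @ Phi / noise_var + A
        # jitter keeps the posterior solve stable for near-duplicate bases
        Sigma = np.linalg.inv(H + 1e-12 * np.eye(len(active)))
        mu = Sigma @ Phi.T @ y / noise_var
        gamma_i = 1.0 - alpha * np.diag(Sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = gamma_i / mu**2
        alpha_new = np.where(np.isfinite(alpha_new) & (alpha_new > 0), alpha_new, 2 * ALPHA_PRUNE_CAP)
        resid = y - Phi @ mu
        denom = max(n - gamma_i.sum(), 1e-9)
        noise_var = max(float(resid @ resid) / denom, 1e-12)

        keep = alpha_new < ALPHA_PRUNE_CAP
        if not keep.any():
            raise DegenerateFit("all basis functions pruned; the fit diverged")
        delta = np.max(np.abs(np.log(alpha_new[keep]) - np.log(alpha[keep])))
        active = active[keep]
        alpha = alpha_new[keep]
        trace.append(_log_marginal(Phi_full[:, active], y, alpha, noise_var))
        if delta < tol:
            break

    Phi = Phi_full[:, active]
    H = Phi.T @ Phi / noise_var + np.diag(alpha)
    Sigma = np.linalg.inv(H + 1e-12 * np.eye(len(active)))
    mu = Sigma @ Phi.T @ y / noise_var
    return RVMModel(
        kernel=kernel, gamma=gamma, X_train=X.copy(),
        active=active.copy(), weight_mean=mu, weight_cov=Sigma,
        alpha=alpha.copy(), noise_var=noise_var, log_marginal_trace=trace,
    )


def predict_rvm(model: RVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean Φ*μ and variance σ² + φ(x*)ᵀ Σ φ(x*)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        return np.empty(0), np.empty(0)
    if X.shape[1] != model.X_train.shape[1]:
        raise SchemaError(f"expected {model.X_train.shape[1]} features, got {X.shape[1]}")
    Phi = _rvm_design(X, model.X_train, model.kernel, model.gamma)[:, model.active]
    mean = Phi @ model.weight_mean
    var = model.noise_var + np.einsum("ij,jk,ik->i", Phi, model.weight_cov, Phi)
    return mean, np.maximum(var, 1e-300)
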