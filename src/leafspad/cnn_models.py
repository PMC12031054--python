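"""Small 1-D convolutional regression network and CNN-kernel hybrids.

The network treats the principal-component score vector (length 5 by
default) as a single-channel 1-D sequence.  Each convolutional block is
convolution ("same" padding) → batch normalisation → ReLU → max pooling
(window 2, stride 2); the head is flatten → dense(32) → ReLU → dense(1).
The standalone network uses one block of 16 filters; the hybrids use
two blocks (16 then 32 filters) so an intermediate "pool2" layer exists
to tap.  With "same" padding a length-5 input shrinks 5 → 2 → 1 through
the two pooling stages.

Training is full-batch gradient descent with Adam, an initial learning
rate of 0.01 decayed ×0.1 every 100 epochs, L2 weight penalty 0.001,
global gradient-norm clipping at 1.0, and early stopping with patience
10 on a validation loss.  Everything is plain NumPy, single threaded,
and bit-reproducible from the seed.

Hybrids train in two stages: the CNN is fitted on (X, y), then frozen;
its tap-layer activations over the training rows become the inputs of
an SVR or RVM fitted on the same targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, SchemaError, LeafSpadError
from .kernel_regressors import (
    RVMModel, SVRConfig, SVRModel, fit_rvm, fit_svr, predict_rvm, predict_svr,
)

__all__ = [
    "CNNArchitecture",
    "TrainConfig",
    "CNNRegressor",
    "HybridModel",
    "train_cnn",
    "extract_features",
    "fit_hybrid",
]


class TrainingDiverged(LeafSpadError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class CNNArchitecture:
    """Network shape: conv blocks as (kernel_length, n_filters) pairs."""

    input_length: int = 5
    conv_blocks: tuple[tuple[int, int], ...] = ((3, 16),)
    dense_units: int = 32

    def __post_init__(self) -> None:
        if self.input_length < 1:
            raise ConfigError("input_length must be >= 1")
        L = self.input_length
        for k, f in self.conv_blocks:
            if k < 1 or f < 1:
                raise ConfigError(f"invalid conv block ({k}, {f})")
            if k > L:
                raise ConfigError(f"kernel length {k} exceeds feature-map length {L}")
            if L >= 2:
                L //= 2

    @classmethod
    def standalone(cls, input_length: int = 5) -> "CNNArchitecture":
        return cls(input_length=input_length, conv_blocks=((3, 16),))

    @classmethod
    def hybrid(cls, input_length: int = 5) -> "CNNArchitecture":
        return cls(input_length=input_length, conv_blocks=((3, 16), (2, 32)))


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam, staircase learning-rate decay)."""

    max_epochs: int = 1000
    initial_lr: float = 0.01
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 100
    l2_coeff: float = 0.001
    grad_clip_norm: float = 1.0
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.initial_lr, self.lr_decay_factor, self.grad_clip_norm) <= 0:
            raise ConfigError("learning rate, decay factor and clip norm must be positive")
        if self.l2_coeff < 0:
            raise ConfigError("l2_coeff must be non-negative")
        if self.early_stop_patience < 1:
            raise ConfigError("patience must be >= 1")


def _conv_pads(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class CNNRegressor:
    """1-D CNN for scalar regression, with tappable intermediate layers."""

    def __init__(self, arch: CNNArchitecture | None = None, seed: int = 0):
        self.arch = arch or CNNArchitecture()
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        # fixed output affine: predictions = raw·out_scale + out_mean, anchored
        # at the training-target statistics so the net starts at the mean
        # predictor instead of crawling from zero under clipped updates
        self.out_mean: float = 0.0
        self.out_scale: float = 1.0
        self._init_params(np.random.default_rng(seed))
        self.training_log: list[dict] = []

    # -- construction ------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        c_in, L = 1, self.arch.input_length
        for i, (k, f) in enumerate(self.arch.conv_blocks, start=1):
            bound = np.sqrt(6.0 / (c_in * k))
            self.params[f"conv{i}_W"] = rng.uniform(-bound, bound, size=(f, c_in, k))
            self.params[f"conv{i}_b"] = np.zeros(f)
            self.params[f"bn{i}_gamma"] = np.ones(f)
            self.params[f"bn{i}_beta"] = np.zeros(f)
            self.running[f"bn{i}_mean"] = np.zeros(f)
            self.running[f"bn{i}_var"] = np.ones(f)
            c_in = f
            if L >= 2:
                L //= 2
        self.flat_dim = c_in * L
        bound = np.sqrt(6.0 / self.flat_dim)
        self.params["fc1_W"] = rng.uniform(-bound, bound, size=(self.flat_dim, self.arch.dense_units))
        self.params["fc1_b"] = np.zeros(self.arch.dense_units)
        bound = np.sqrt(6.0 / self.arch.dense_units)
        self.params["out_W"] = rng.uniform(-bound, bound, size=(self.arch.dense_units, 1))
        self.params["out_b"] = np.zeros(1)

    def layer_names(self) -> list[str]:
        names = []
        for i in range(1, len(self.arch.conv_blocks) + 1):
            names += [f"conv{i}", f"bn{i}", f"relu{i}", f"pool{i}"]
        return names + ["flatten", "fc1", "relu_fc", "output"]

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.arch.input_length:
            raise SchemaError(f"expected input length {self.arch.input_length}, got {X.shape[1]}")
        acts: dict[str, np.ndarray] = {"input": X}
        cache: dict = {"acts": acts}
        x = X[:, None, :]  # (m, 1, L)
        for i, (k, _f) in enumerate(self.arch.conv_blocks, start=1):
            x, cv = self._conv_fwd(x, i, k)
            acts[f"conv{i}"] = x
            cache[f"conv{i}"] = cv
            x, bc = self._bn_fwd(x, i, train)
            acts[f"bn{i}"] = x
            cache[f"bn{i}"] = bc
            relu_mask = x > 0
            x = x * relu_mask
            acts[f"relu{i}"] = x
            cache[f"relu{i}"] = relu_mask
            if x.shape[2] >= 2:
                x, pc = self._pool_fwd(x)
                cache[f"pool{i}"] = pc
            else:
                cache[f"pool{i}"] = None
            acts[f"pool{i}"] = x
        m = x.shape[0]
        flat = x.reshape(m, -1)
        acts["flatten"] = flat
        h = flat @ self.params["fc1_W"] + self.params["fc1_b"]
        acts["fc1"] = h
        hmask = h > 0
        h = h * hmask
        acts["relu_fc"] = h
        cache["relu_fc"] = hmask
        out = (h @ self.params["out_W"] + self.params["out_b"]).ravel()
        out = out * self.out_scale + self.out_mean
        acts["output"] = out
        cache["pool_shape"] = x.shape
        return out, cache

    def _conv_fwd(self, x: np.ndarray, i: int, k: int) -> tuple[np.ndarray, dict]:
        W, b = self.params[f"conv{i}_W"], self.params[f"conv{i}_b"]
        pl, pr = _conv_pads(k)
        xpad = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        L = x.shape[2]
        patches = np.stack([xpad[:, :, j:j + L] for j in range(k)], axis=-1)  # (m,c,L,k)
        out = np.einsum("ock,mclk->mol", W, patches) + b[None, :, None]
        return out, {"patches": patches, "in_shape": x.shape, "k": k}

    def _conv_bwd(self, dout: np.ndarray, i: int, cv: dict,
                  grads: dict[str, np.ndarray]) -> np.ndarray:
        W = self.params[f"conv{i}_W"]
        k = cv["k"]
        pl, pr = _conv_pads(k)
        m, c, L = cv["in_shape"]
        grads[f"conv{i}_W"] = np.einsum("mol,mclk->ock", dout, cv["patches"])
        grads[f"conv{i}_b"] = dout.sum(axis=(0, 2))
        dxpad = np.zeros((m, c, L + pl + pr))
        for j in range(k):
            dxpad[:, :, j:j + L] += np.einsum("oc,mol->mcl", W[:, :, j], dout)
        return dxpad[:, :, pl:pl + L]

    def _bn_fwd(self, x: np.ndarray, i: int, train: bool) -> tuple[np.ndarray, dict]:
        gamma = self.params[f"bn{i}_gamma"][None, :, None]
        beta = self.params[f"bn{i}_beta"][None, :, None]
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running[f"bn{i}_mean"] = (
                (1 - _BN_MOMENTUM) * self.running[f"bn{i}_mean"] + _BN_MOMENTUM * mean)
            self.running[f"bn{i}_var"] = (
                (1 - _BN_MOMENTUM) * self.running[f"bn{i}_var"] + _BN_MOMENTUM * var)
        else:
            mean = self.running[f"bn{i}_mean"]
            var = self.running[f"bn{i}_var"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        return gamma * xhat + beta, {"xhat": xhat, "inv_std": inv_std}

    def _bn_bwd(self, dout: np.ndarray, i: int, bc: dict,
                grads: dict[str, np.ndarray]) -> np.ndarray:
        xhat, inv_std = bc["xhat"], bc["inv_std"]
        gamma = self.params[f"bn{i}_gamma"][None, :, None]
        N = dout.shape[0] * dout.shape[2]
        grads[f"bn{i}_gamma"] = (dout * xhat).sum(axis=(0, 2))
        grads[f"bn{i}_beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * gamma
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / N) * (N * dxhat - s1 - xhat * s2)

    @staticmethod
    def _pool_fwd(x: np.ndarray) -> tuple[np.ndarray, dict]:
        L2 = x.shape[2] // 2
        pairs = x[:, :, : 2 * L2].reshape(x.shape[0], x.shape[1], L2, 2)
        arg = pairs.argmax(axis=3)
        out = np.take_along_axis(pairs, arg[..., None], axis=3)[..., 0]
        return out, {"arg": arg, "in_len": x.shape[2]}

    @staticmethod
    def _pool_bwd(dout: np.ndarray, pc: dict) -> np.ndarray:
        m, c, L2 = dout.shape
        dpairs = np.zeros((m, c, L2, 2))
        np.put_along_axis(dpairs, pc["arg"][..., None], dout[..., None], axis=3)
        dx = np.zeros((m, c, pc["in_len"]))
        dx[:, :, : 2 * L2] = dpairs.reshape(m, c, 2 * L2)
        return dx

    def _backward(self, cache: dict, dpred: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        acts = cache["acts"]
        h = acts["relu_fc"]
        dpred = (dpred * self.out_scale)[:, None]
        grads["out_W"] = h.T @ dpred
        grads["out_b"] = dpred.sum(axis=0)
        dh = dpred @ self.params["out_W"].T
        dh = dh * cache["relu_fc"]
        grads["fc1_W"] = acts["flatten"].T @ dh
        grads["fc1_b"] = dh.sum(axis=0)
        dflat = dh @ self.params["fc1_W"].T
        dx = dflat.reshape(cache["pool_shape"])
        for i in range(len(self.arch.conv_blocks), 0, -1):
            if cache[f"pool{i}"] is not None:
                dx = self._pool_bwd(dx, cache[f"pool{i}"])
            dx = dx * cache[f"relu{i}"]
            dx = self._bn_bwd(dx, i, cache[f"bn{i}"], grads)
            dx = self._conv_bwd(dx, i, cache[f"conv{i}"], grads)
        return grads

    # -- public API --------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference-mode forward pass."""
        out, _ = self._forward(X, train=False)
        return out

    def activations(self, X: np.ndarray) -> dict[str, np.ndarray]:
        _, cache = self._forward(X, train=False)
        return cache["acts"]

    def loss(self, X: np.ndarray, y: np.ndarray, l2_coeff: float = 0.0) -> float:
        pred = self.predict(X)
        mse = float(np.mean((pred - np.asarray(y, dtype=float)) ** 2))
        return mse + l2_coeff * self._weight_sq_norm()

    def _weight_sq_norm(self) -> float:
        return float(sum(
            (self.params[k] ** 2).sum() for k in self.params
            if k.endswith("_W")))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        cfg: TrainConfig | None = None,
        val: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> "CNNRegressor":
        """Full-batch Adam training with the staircase learning-rate decay.

        ``val`` enables early stopping (patience on validation loss);
        the best-validation weights are restored on exit.  The per-epoch
        log records epoch, lr, train/val loss, and the post-clip global
        gradient norm.
        """
        cfg = cfg or TrainConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.out_mean = float(y.mean())
        self.out_scale = float(y.std()) or 1.0
        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        t = 0
        best_val = np.inf
        best_epoch = 0
        best_params: dict[str, np.ndarray] | None = None
        best_running: dict[str, np.ndarray] | None = None
        self.training_log = []

        for epoch in range(1, cfg.max_epochs + 1):
            lr = cfg.initial_lr * cfg.lr_decay_factor ** ((epoch - 1) // cfg.lr_decay_every)
            pred, cache = self._forward(X, train=True)
            resid = pred - y
            mse = float(np.mean(resid**2))
            loss = mse + cfg.l2_coeff * self._weight_sq_norm()
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            grads = self._backward(cache, 2.0 * resid / len(y))
            for k in self.params:
                if k.endswith("_W"):
                    grads[k] = grads[k] + 2.0 * cfg.l2_coeff * self.params[k]
            gnorm = float(np.sqrt(sum((g**2).sum() for g in grads.values())))
            if gnorm > cfg.grad_clip_norm:
                scale = cfg.grad_clip_norm / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            clipped_norm = min(gnorm, cfg.grad_clip_norm)
            t += 1
            for k in self.params:
                adam_m[k] = 0.9 * adam_m[k] + 0.1 * grads[k]
                adam_v[k] = 0.999 * adam_v[k] + 0.001 * grads[k] ** 2
                mhat = adam_m[k] / (1 - 0.9**t)
                vhat = adam_v[k] / (1 - 0.999**t)
                self.params[k] = self.params[k] - lr * mhat / (np.sqrt(vhat) + 1e-8)

            row = {"epoch": epoch, "lr": lr, "train_loss": loss,
                   "grad_norm": clipped_norm, "val_loss": np.nan}
            if val is not None:
                vloss = self.loss(val[0], val[1])
                row["val_loss"] = vloss
                if vloss < best_val:
                    best_val, best_epoch = vloss, epoch
                    best_params = {k: v.copy() for k, v in self.params.items()}
                    best_running = {k: v.copy() for k, v in self.running.items()}
                self.training_log.append(row)
                if epoch - best_epoch >= cfg.early_stop_patience:
                    break
            else:
                self.training_log.append(row)

        if best_params is not None:
            self.params = best_params
            self.running = best_running
        return self


def train_cnn(
    X: np.ndarray,
    y: np.ndarray,
    arch: CNNArchitecture | None = None,
    cfg: TrainConfig | None = None,
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> CNNRegressor:
    """Construct a seeded network and fit it; returns the trained model."""
    cfg = cfg or TrainConfig()
    net = CNNRegressor(arch or CNNArchitecture(input_length=np.atleast_2d(X).shape[1]),
                       seed=cfg.seed)
    return net.fit(X, y, cfg=cfg, val=val)


def extract_features(net: CNNRegressor, tap: str, X: np.ndarray) -> np.ndarray:
    """Flattened inference-mode activations at the named tap layer."""
    valid = net.layer_names()
    if tap not in valid:
        raise ConfigError(f"unknown tap layer {tap!r}; valid layers: {valid}")
    act = net.activations(X)[tap]
    return act.reshape(act.shape[0], -1)


@dataclass
class HybridModel:
    """Frozen CNN feature extractor + kernel regressor head."""

    cnn: CNNRegressor
    tap: str
    downstream: str                      # "svr" | "rvm"
    svr: SVRModel | None = None
    rvm: RVMModel | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        feats = extract_features(self.cnn, self.tap, X)
        if self.downstream == "svr":
            return predict_svr(self.svr, feats)
        return predict_rvm(self.rvm, feats)[0]


def fit_hybrid(
    X: np.ndarray,
    y: np.ndarray,
    arch: CNNArchitecture | None = None,
    cfg: TrainConfig | None = None,
    downstream: str = "svr",
    downstream_cfg: dict | SVRConfig | None = None,
    tap: str | None = None,
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> HybridModel:
    """Stage 1: train the CNN.  Stage 2: freeze it and fit the kernel
    regressor on tap-layer features.

    The default tap is "pool2" when the architecture has two blocks,
    else the last pooling layer.
    """
    if downstream not in ("svr", "rvm"):
        raise ConfigError(f"downstream must be 'svr' or 'rvm', got {downstream!r}")
    arch = arch or CNNArchitecture.hybrid(input_length=np.atleast_2d(X).shape[1])
    net = train_cnn(X, y, arch=arch, cfg=cfg, val=val)
    if tap is None:
        tap = f"pool{len(arch.conv_blocks)}"
    feats = extract_features(net, tap, X)
    if downstream == "svr":
        scfg = downstream_cfg if isinstance(downstream_cfg, SVRConfig) else SVRConfig(**(downstream_cfg or {}))
        return HybridModel(cnn=net, tap=tap, downstream="svr", svr=fit_svr(feats, y, scfg))
    rcfg = dict(downstream_cfg or {})
    rcfg.setdefault("kernel", "gaussian")
    rcfg.setdefault("gamma", 0.05)
    return HybridModel(cnn=net, tap=tap, downstream="rvm", rvm=fit_rvm(feats, y, **rcfg))
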