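"""End-to-end orchestration: images → segmentation → features → PCA → models.

`run_pipeline` executes every stage on an image directory plus a
``filename,spad`` manifest and writes all artifacts (feature CSV,
correlation report, PCA model, per-model holdout and cross-validation
reports, serialized models, resolved config, provenance) into the
output directory.  `predict_single` applies a saved bundle to one new
photograph.  Every stage is deterministic given the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, LeafSpadError
from .imaging import (
    SegmentationConfig, load_image, mean_channels, median_filter_roi, segment_leaf,
)
from .color_features import feature_table
from .selection import PCAModel, correlation_report, fit_pca, select_features, transform_pca
from .kernel_regressors import (
    RVMModel, SVRConfig, SVRModel, fit_rvm, fit_svr, predict_rvm, predict_svr,
)
from .cnn_models import (
    CNNArchitecture, CNNRegressor, HybridModel, TrainConfig, extract_features, fit_hybrid,
    train_cnn,
)
from .evaluation import cross_validate, r_squared, rmse, split_80_20

__all__ = [
    "PipelineConfig", "run_pipeline", "predict_single", "make_estimator",
    "extract_feature_table", "save_model", "load_model", "MODEL_NAMES",
]

MODEL_NAMES = ("svr", "rvm", "cnn", "cnn_svr", "cnn_rvm")


# ---------------------------------------------------------------------------
# estimator wrappers with a uniform fit/predict surface
# ---------------------------------------------------------------------------

class SVREstimator:
    def __init__(self, **params: Any):
        self.cfg = SVRConfig(**params)
        self.model: SVRModel | None = None

    def fit(self, X, y):
        self.model = fit_svr(X, y, self.cfg)
        return self

    def predict(self, X):
        return predict_svr(self.model, X)


class RVMEstimator:
    def __init__(self, kernel: str = "gaussian", gamma: float = 0.01, **kw: Any):
        self.kernel, self.gamma, self.kw = kernel, gamma, kw
        self.model: RVMModel | None = None

    def fit(self, X, y):
        self.model = fit_rvm(X, y, kernel=self.kernel, gamma=self.gamma, **self.kw)
        return self

    def predict(self, X):
        return predict_rvm(self.model, X)[0]


def _val_split(X: np.ndarray, y: np.ndarray, seed: int):
    tr, va = split_80_20(len(y), seed=seed)
    return X[tr], y[tr], (X[va], y[va])


class CNNEstimator:
    """Standalone CNN; carves an internal 80/20 validation subset for
    early stopping so `fit(X, y)` matches the common estimator surface."""

    def __init__(self, arch: CNNArchitecture | None = None, train: TrainConfig | None = None):
        self.arch, self.traincfg = arch, train or TrainConfig()
        self.model: CNNRegressor | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        arch = self.arch or CNNArchitecture.standalone(input_length=X.shape[1])
        Xtr, ytr, val = _val_split(X, y, self.traincfg.seed)
        self.model = train_cnn(Xtr, ytr, arch=arch, cfg=self.traincfg, val=val)
        return self

    def predict(self, X):
        return self.model.predict(X)


class HybridEstimator:
    def __init__(self, downstream: str, arch: CNNArchitecture | None = None,
                 train: TrainConfig | None = None,
                 downstream_cfg: dict | None = None, tap: str | None = None):
        self.downstream = downstream
        self.arch, self.traincfg = arch, train or TrainConfig()
        self.downstream_cfg, self.tap = downstream_cfg, tap
        self.model: HybridModel | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        arch = self.arch or CNNArchitecture.hybrid(input_length=X.shape[1])
        Xtr, ytr, val = _val_split(X, y, self.traincfg.seed)
        self.model = fit_hybrid(Xtr, ytr, arch=arch, cfg=self.traincfg,
                                downstream=self.downstream,
                                downstream_cfg=self.downstream_cfg,
                                tap=self.tap, val=val)
        return self

    def predict(self, X):
        return self.model.predict(X)


def make_estimator(name: str, params: dict | None = None, seed: int = 0):
    """Factory for the five model kinds by canonical name."""
    params = dict(params or {})
    if name == "svr":
        return SVREstimator(**params)
    if name == "rvm":
        params.setdefault("kernel", "gaussian")
        params.setdefault("gamma", 0.01)
        return RVMEstimator(**params)
    train_kw = params.pop("train", {})
    train = TrainConfig(**{"seed": seed, **train_kw})
    if name == "cnn":
        return CNNEstimator(train=train)
    if name in ("cnn_svr", "cnn_rvm"):
        kind = name.split("_")[1]
        default_dn = {} if kind == "svr" else {"kernel": "gaussian", "gamma": 0.05}
        return HybridEstimator(kind, train=train,
                               downstream_cfg=params.pop("downstream", default_dn),
                               tap=params.pop("tap", None))
    raise ConfigError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def _cnn_payload(net: CNNRegressor) -> dict:
    return {
        "arch": {"input_length": net.arch.input_length,
                 "conv_blocks": [list(b) for b in net.arch.conv_blocks],
                 "dense_units": net.arch.dense_units},
        "params": {k: v.tolist() for k, v in net.params.items()},
        "running": {k: v.tolist() for k, v in net.running.items()},
        "out_mean": net.out_mean,
        "out_scale": net.out_scale,
    }


def _cnn_from_payload(d: dict) -> CNNRegressor:
    arch = CNNArchitecture(input_length=d["arch"]["input_length"],
                           conv_blocks=tuple(tuple(b) for b in d["arch"]["conv_blocks"]),
                           dense_units=d["arch"]["dense_units"])
    net = CNNRegressor(arch, seed=0)
    net.params = {k: np.asarray(v, dtype=float) for k, v in d["params"].items()}
    net.running = {k: np.asarray(v, dtype=float) for k, v in d["running"].items()}
    net.out_mean = float(d.get("out_mean", 0.0))
    net.out_scale = float(d.get("out_scale", 1.0))
    return net


def save_model(model: Any, path: str | Path) -> None:
    """Serialize any of the five fitted model kinds to JSON."""
    path = Path(path)
    if isinstance(model, (SVREstimator, RVMEstimator, CNNEstimator, HybridEstimator)):
        model = model.model
    if isinstance(model, SVRModel):
        model.to_json(path)
    elif isinstance(model, RVMModel):
        model.to_json(path)
    elif isinstance(model, CNNRegressor):
        path.write_text(json.dumps({"schema_version": 1, "model": "cnn"} | _cnn_payload(model)))
    elif isinstance(model, HybridModel):
        payload = {"schema_version": 1, "model": f"cnn_{model.downstream}",
                   "tap": model.tap, "cnn": _cnn_payload(model.cnn)}
        if model.downstream == "svr":
            payload["svr"] = json.loads(_dump_json(model.svr))
        else:
            payload["rvm"] = json.loads(_dump_json(model.rvm))
        path.write_text(json.dumps(payload))
    else:
        raise ConfigError(f"cannot serialize model of type {type(model).__name__}")


def _dump_json(m) -> str:
    import tempfile
    with tempfile.NamedTemporaryFile("r", suffix=".json", delete=False) as fh:
        tmp = Path(fh.name)
    m.to_json(tmp)
    txt = tmp.read_text()
    tmp.unlink()
    return txt


def load_model(path: str | Path):
    """Inverse of :func:`save_model`; returns a fitted model object."""
    d = json.loads(Path(path).read_text())
    kind = d["model"]
    if kind == "svr":
        return SVRModel.from_json(path)
    if kind == "rvm":
        return RVMModel.from_json(path)
    if kind == "cnn":
        return _cnn_from_payload(d)
    if kind in ("cnn_svr", "cnn_rvm"):
        cnn = _cnn_from_payload(d["cnn"])
        if kind == "cnn_svr":
            sub = d["svr"]
            svr = SVRModel(config=SVRConfig(**sub["config"]),
                           support_vectors=np.asarray(sub["support_vectors"], dtype=float),
                           dual_coef=np.asarray(sub["dual_coef"], dtype=float),
                           intercept=float(sub["intercept"]),
                           n_features=int(sub["n_features"]))
            return HybridModel(cnn=cnn, tap=d["tap"], downstream="svr", svr=svr)
        sub = d["rvm"]
        rvm = RVMModel(kernel=sub["kernel"], gamma=float(sub["gamma"]),
                       X_train=np.asarray(sub["X_train"], dtype=float),
                       active=np.asarray(sub["active"], dtype=int),
                       weight_mean=np.asarray(sub["weight_mean"], dtype=float),
                       weight_cov=np.asarray(sub["weight_cov"], dtype=float),
                       alpha=np.asarray(sub["alpha"], dtype=float),
                       noise_var=float(sub["noise_var"]))
        return HybridModel(cnn=cnn, tap=d["tap"], downstream="rvm", rvm=rvm)
    raise ConfigError(f"unknown serialized model kind {kind!r}")


def predict_model(model: Any, X: np.ndarray) -> np.ndarray:
    if isinstance(model, SVRModel):
        return predict_svr(model, X)
    if isinstance(model, RVMModel):
        return predict_rvm(model, X)[0]
    return model.predict(X)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

_SECTION_KEYS = {
    "segmentation": {"s_min", "v_max", "hue_range", "median_kernel"},
    "selection": {"mode", "threshold"},
    "evaluation": {"seed", "folds", "pooled_preprocessing"},
}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    images_dir: str = "."
    manifest: str = "manifest.csv"
    out_dir: str = "out"
    segmentation: dict = field(default_factory=dict)
    selection: dict = field(default_factory=lambda: {"mode": "canonical", "threshold": 0.7})
    pca_components: int = 5
    models: tuple[str, ...] = MODEL_NAMES
    model_params: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=lambda: {"seed": 20240625, "folds": 5,
                                                      "pooled_preprocessing": False})

    def __post_init__(self) -> None:
        for section, allowed in _SECTION_KEYS.items():
            extra = set(getattr(self, section)) - allowed
            if extra:
                raise ConfigError(f"unknown key(s) in '{section}': {sorted(extra)}")
        bad = [m for m in self.models if m not in MODEL_NAMES]
        if bad:
            raise ConfigError(f"unknown model name(s) {bad}; expected subset of {MODEL_NAMES}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config key(s): {sorted(extra)}")
        if "models" in d:
            d = {**d, "models": tuple(d["models"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def segmentation_config(self) -> SegmentationConfig:
        seg = dict(self.segmentation)
        seg.pop("median_kernel", None)
        if seg.get("hue_range") is not None:
            seg["hue_range"] = tuple(seg["hue_range"])
        return SegmentationConfig(**seg)

    def to_resolved_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def extract_feature_table(
    images_dir: str | Path,
    manifest: pd.DataFrame,
    seg_cfg: SegmentationConfig | None = None,
    median_kernel: int = 5,
) -> pd.DataFrame:
    """Segment every manifest image and build the n×28 feature table."""
    images_dir = Path(images_dir)
    if not {"filename", "spad"} <= set(manifest.columns):
        raise ConfigError("manifest must have 'filename' and 'spad' columns")
    colors = []
    for fname in manifest["filename"]:
        path = images_dir / fname
        if not path.exists():
            raise LeafSpadError(f"manifest references missing image: {fname}")
        img = load_image(path)
        mask = segment_leaf(img, seg_cfg)
        filtered = median_filter_roi(img, mask, kernel=median_kernel)
        colors.append(mean_channels(filtered, mask))
    return feature_table(colors, manifest["spad"].tolist(),
                         index=manifest["filename"].tolist())


def _holdout_report(models: dict, scores: np.ndarray, y: np.ndarray,
                    seed: int) -> tuple[pd.DataFrame, dict]:
    tr, va = split_80_20(len(y), seed=seed)
    rows, fitted = [], {}
    for name, factory in models.items():
        est = factory().fit(scores[tr], y[tr])
        fitted[name] = est
        ptr, pva = est.predict(scores[tr]), est.predict(scores[va])
        rows.append({"model": name,
                     "train_r2": r_squared(y[tr], ptr), "train_rmse": rmse(y[tr], ptr),
                     "val_r2": r_squared(y[va], pva), "val_rmse": rmse(y[va], pva)})
    return pd.DataFrame(rows).set_index("model"), fitted


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write artifacts under ``cfg.out_dir``.

    Returns a dict with the in-memory results (feature table,
    correlation report, PCA model, holdout report, CV report).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mpath = Path(cfg.manifest)
    if not mpath.is_absolute() and not mpath.exists():
        mpath = Path(cfg.images_dir) / mpath
    manifest = pd.read_csv(mpath)

    seg_cfg = cfg.segmentation_config()
    kernel = int(cfg.segmentation.get("median_kernel", 5))
    table = extract_feature_table(cfg.images_dir, manifest, seg_cfg, median_kernel=kernel)
    table.to_csv(out / "features.csv")

    rep = correlation_report(table, threshold=float(cfg.selection.get("threshold", 0.7)))
    rep.to_csv(out / "correlation.csv")
    feats = select_features(rep, mode=cfg.selection.get("mode", "canonical"),
                            threshold=float(cfg.selection.get("threshold", 0.7)))
    pca = fit_pca(table[feats], k_fixed=cfg.pca_components)
    pca.to_json(out / "pca.json")
    scores = transform_pca(pca, table[feats])
    y = table["spad"].to_numpy(dtype=float)

    seed = int(cfg.evaluation.get("seed", 20240625))
    models = {name: (lambda n=name: make_estimator(n, cfg.model_params.get(n), seed=seed))
              for name in cfg.models}
    holdout, fitted = _holdout_report(models, scores, y, seed=seed)
    holdout.to_csv(out / "holdout_report.csv")

    cv = None
    folds = int(cfg.evaluation.get("folds", 5))
    if folds >= 2:
        cv = cross_validate(models, table, k=folds, seed=seed,
                            selection_mode=cfg.selection.get("mode", "canonical"),
                            selection_threshold=float(cfg.selection.get("threshold", 0.7)),
                            n_components=cfg.pca_components,
                            fold_safe=not cfg.evaluation.get("pooled_preprocessing", False))
        cv.summary.to_csv(out / "cv_report.csv")
        (out / "cv_report.md").write_text(cv.to_markdown() + "\n")
        pd.Series(cv.folds).to_csv(out / "fold_assignment.csv", header=["fold"])

    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    for name, est in fitted.items():
        save_model(est, mdir / f"{name}.json")

    resolved = cfg.to_resolved_dict()
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(resolved, sort_keys=True).encode()).hexdigest()[:16]
    (out / "provenance.json").write_text(json.dumps({
        "leafspad_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config_sha256": cfg_hash,
        "n_samples": len(table),
    }, indent=1))
    return {"features": table, "correlation": rep, "selected": feats, "pca": pca,
            "holdout": holdout, "cv": cv, "models": fitted}


def predict_single(bundle_dir: str | Path, image_path: str | Path,
                   model_name: str = "cnn_svr") -> float:
    """Predict SPAD for one photograph using a saved pipeline bundle.

    The bundle is the output directory of :func:`run_pipeline`
    (resolved config + pca.json + models/*.json).
    """
    bundle = Path(bundle_dir)
    cfg = PipelineConfig.from_dict(
        yaml.safe_load((bundle / "config.resolved.yaml").read_text()))
    pca = PCAModel.from_json(bundle / "pca.json")
    model = load_model(bundle / "models" / f"{model_name}.json")

    img = load_image(image_path)
    try:
        mask = segment_leaf(img, cfg.segmentation_config())
    except LeafSpadError as exc:
        raise type(exc)(f"{exc} — is the photo a single leaf on a bright background?") from exc
    filtered = median_filter_roi(img, mask, kernel=int(cfg.segmentation.get("median_kernel", 5)))
    color = mean_channels(filtered, mask)
    from .color_features import compute_features
    feats = compute_features(color)
    score = transform_pca(pca, feats.to_frame().T)
    return float(predict_model(model, score)[0])
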