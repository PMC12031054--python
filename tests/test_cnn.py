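import numpy as np
import pytest

from leafspad.cnn_models import (
    CNNArchitecture, CNNRegressor, TrainConfig, TrainingDiverged, extract_features,
    fit_hybrid, train_cnn,
)
from leafspad.errors import ConfigError, SchemaError
from leafspad.kernel_regressors import SVRConfig


def _linear_data(n=50, seed=0, noise=0.1, offset=40.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 5))
    w = np.array([2.0, -1.0, 0.5, 1.0, -0.5])
    return X, X @ w + offset + rng.normal(0, noise, n)


class TestForward:
    def test_hand_computed_edge_detector(self):
        """One conv filter [1,0,−1] with 'same' padding on [1,2,3,4,5]:
        conv → [−2,−2,−2,−2,4], ReLU → [0,0,0,0,4], pool2 → [0,0];
        a hand-set summing head then yields 0."""
        arch = CNNArchitecture(input_length=5, conv_blocks=((3, 1),), dense_units=2)
        net = CNNRegressor(arch, seed=0)
        net.params["conv1_W"] = np.array([[[1.0, 0.0, -1.0]]])
        net.params["conv1_b"] = np.zeros(1)
        # batch-norm with running stats (0, 1) and γ=1, β=0 is the identity
        net.params["fc1_W"] = np.eye(2)
        net.params["fc1_b"] = np.zeros(2)
        net.params["out_W"] = np.ones((2, 1))
        net.params["out_b"] = np.zeros(1)
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        acts = net.activations(x)
        np.testing.assert_allclose(acts["conv1"][0, 0], [-2, -2, -2, -2, 4], atol=1e-6)
        np.testing.assert_allclose(acts["bn1"][0, 0],
                                   np.array([-2, -2, -2, -2, 4]) / np.sqrt(1 + 1e-5),
                                   atol=1e-9)
        np.testing.assert_allclose(acts["pool1"][0, 0], [0, 0], atol=1e-6)
        assert net.predict(x)[0] == pytest.approx(0.0, abs=1e-6)

    def test_zero_weights_zero_output(self):
        net = CNNRegressor(CNNArchitecture(), seed=0)
        for k in net.params:
            if not k.startswith("bn"):
                net.params[k] = np.zeros_like(net.params[k])
        X = np.random.default_rng(1).normal(size=(7, 5))
        np.testing.assert_allclose(net.predict(X), 0.0, atol=1e-12)

    def test_batching_consistency(self):
        net = CNNRegressor(CNNArchitecture.hybrid(), seed=3)
        X = np.random.default_rng(2).normal(size=(9, 5))
        batch = net.predict(X)
        singles = np.concatenate([net.predict(X[i:i + 1]) for i in range(9)])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_length_mismatch(self):
        net = CNNRegressor(CNNArchitecture(input_length=5), seed=0)
        with pytest.raises(SchemaError):
            net.predict(np.zeros((2, 7)))

    def test_invalid_architecture(self):
        with pytest.raises(ConfigError):
            CNNArchitecture(input_length=2, conv_blocks=((3, 4),))


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """Analytic backprop against central finite differences on a tiny
        two-block network (training-mode batch norm included)."""
        arch = CNNArchitecture(input_length=5, conv_blocks=((3, 2), (2, 3)), dense_units=4)
        net = CNNRegressor(arch, seed=7)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        y = rng.normal(size=6)

        def loss_at(params):
            saved = net.params
            run_saved = {k: v.copy() for k, v in net.running.items()}
            net.params = params
            pred, _ = net._forward(X, train=True)
            net.params = saved
            net.running = run_saved
            return float(np.mean((pred - y) ** 2))

        pred, cache = net._forward(X, train=True)
        run_after = {k: v.copy() for k, v in net.running.items()}
        grads = net._backward(cache, 2.0 * (pred - y) / len(y))
        net.running = run_after

        eps = 1e-6
        for name in ["conv1_W", "bn2_gamma", "fc1_W", "out_b", "conv2_b", "bn1_beta"]:
            p = net.params[name]
            flat_idx = [0, p.size // 2, p.size - 1]
            for idx in dict.fromkeys(flat_idx):
                pp = {k: v.copy() for k, v in net.params.items()}
                pp[name].flat[idx] += eps
                up = loss_at(pp)
                pm = {k: v.copy() for k, v in net.params.items()}
                pm[name].flat[idx] -= eps
                down = loss_at(pm)
                numeric = (up - down) / (2 * eps)
                assert grads[name].flat[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), name


class TestTraining:
    def test_capacity_on_linear_map(self):
        X, y = _linear_data(n=50, seed=0, noise=0.1)
        net = train_cnn(X[:40], y[:40], arch=CNNArchitecture.standalone(),
                        cfg=TrainConfig(seed=1), val=(X[40:], y[40:]))
        pred = net.predict(X[:40])
        assert np.sqrt(np.mean((pred - y[:40]) ** 2)) <= 0.5

    def test_early_stop_within_patience_of_best(self):
        X, y = _linear_data(n=40, seed=1)
        # validation targets shifted far off: val loss cannot keep improving
        val = (X[:10], y[:10] + 100.0)
        cfg = TrainConfig(seed=2, early_stop_patience=10, max_epochs=500)
        net = train_cnn(X, y, cfg=cfg, val=val)
        losses = [r["val_loss"] for r in net.training_log]
        best_epoch = int(np.argmin(losses)) + 1
        assert len(net.training_log) <= best_epoch + cfg.early_stop_patience

    def test_learning_rate_staircase(self):
        X, y = _linear_data(n=30, seed=2)
        cfg = TrainConfig(seed=3, max_epochs=210)
        net = train_cnn(X, y, cfg=cfg)  # no val → runs all 210 epochs
        lrs = {r["epoch"]: r["lr"] for r in net.training_log}
        assert lrs[1] == lrs[100] == pytest.approx(0.01)
        assert lrs[101] == lrs[200] == pytest.approx(0.001)
        assert lrs[201] == lrs[210] == pytest.approx(0.0001)

    def test_gradient_clipping_recorded(self):
        X, y = _linear_data(n=30, seed=3)
        net = train_cnn(X, y, cfg=TrainConfig(seed=4, max_epochs=150))
        norms = np.array([r["grad_norm"] for r in net.training_log])
        assert (norms <= 1.0 + 1e-9).all()

    def test_l2_shrinks_weights(self):
        X, y = _linear_data(n=40, seed=4)

        def fit(l2):
            net = train_cnn(X, y, cfg=TrainConfig(seed=5, max_epochs=200, l2_coeff=l2))
            return np.sqrt(net._weight_sq_norm())

        assert fit(10.0) < fit(0.0)

    def test_determinism(self):
        X, y = _linear_data(n=40, seed=5)
        cfg = TrainConfig(seed=6, max_epochs=80)
        n1 = train_cnn(X, y, cfg=cfg, val=(X[:8], y[:8]))
        n2 = train_cnn(X, y, cfg=cfg, val=(X[:8], y[:8]))
        assert n1.training_log == n2.training_log
        for k in n1.params:
            np.testing.assert_array_equal(n1.params[k], n2.params[k])

    def test_divergence_detected(self):
        X, y = _linear_data(n=20, seed=6)
        with pytest.raises(TrainingDiverged, match="epoch"):
            train_cnn(X, y * 1e160, cfg=TrainConfig(seed=7, max_epochs=50,
                                                    grad_clip_norm=1e30, initial_lr=1e20))


class TestFeatureExtraction:
    def test_output_tap_equals_predictions(self):
        X, y = _linear_data(n=30, seed=7)
        net = train_cnn(X, y, cfg=TrainConfig(seed=8, max_epochs=30))
        feats = extract_features(net, "output", X)
        np.testing.assert_allclose(feats.ravel(), net.predict(X), atol=1e-12)

    def test_identical_rows_identical_features(self):
        net = CNNRegressor(CNNArchitecture.hybrid(), seed=9)
        row = np.random.default_rng(3).normal(size=(1, 5))
        X = np.vstack([row, row, row])
        feats = extract_features(net, "pool2", X)
        assert feats.shape == (3, 32)
        np.testing.assert_array_equal(feats[0], feats[1])
        np.testing.assert_array_equal(feats[0], feats[2])

    def test_unknown_tap_lists_valid_names(self):
        net = CNNRegressor(CNNArchitecture.hybrid(), seed=0)
        with pytest.raises(ConfigError, match="pool2"):
            extract_features(net, "pool7", np.zeros((1, 5)))


class TestHybrid:
    def test_refit_on_features_matches_cnn(self):
        """A linear-kernel SVR with C→∞, ε→0 fitted on the last hidden
        activations can replicate the CNN's own linear output layer, so
        hybrid training error cannot be meaningfully worse."""
        X, y = _linear_data(n=60, seed=8, noise=0.0)
        cfg = TrainConfig(seed=9)
        h = fit_hybrid(X[:48], y[:48], cfg=cfg, downstream="svr",
                       downstream_cfg=SVRConfig(C=1e4, epsilon=1e-3, kernel="linear"),
                       tap="relu_fc", val=(X[48:], y[48:]))
        cnn_rmse = np.sqrt(np.mean((h.cnn.predict(X[:48]) - y[:48]) ** 2))
        hyb_rmse = np.sqrt(np.mean((h.predict(X[:48]) - y[:48]) ** 2))
        assert hyb_rmse <= cnn_rmse + 0.1

    def test_output_tap_degenerate_composition(self):
        """Tapping the output layer and composing with an identity SVR
        head (f(x) = x, built by hand) reproduces the CNN exactly."""
        from leafspad.cnn_models import HybridModel
        from leafspad.kernel_regressors import SVRModel

        X, y = _linear_data(n=60, seed=9, noise=0.01)
        cfg = TrainConfig(seed=10)
        net = train_cnn(X[:48], y[:48], cfg=cfg, val=(X[48:], y[48:]))
        identity_svr = SVRModel(config=SVRConfig(kernel="linear"),
                                support_vectors=np.array([[1.0]]),
                                dual_coef=np.array([1.0]),
                                intercept=0.0, n_features=1)
        h = HybridModel(cnn=net, tap="output", downstream="svr", svr=identity_svr)
        np.testing.assert_allclose(h.predict(X), net.predict(X), atol=1e-12)

    def test_cnn_rvm_sparse(self):
        X, y = _linear_data(n=60, seed=10, noise=0.1)
        cfg = TrainConfig(seed=11)
        h = fit_hybrid(X[:48], y[:48], cfg=cfg, downstream="rvm",
                       downstream_cfg={"kernel": "gaussian", "gamma": 0.05},
                       val=(X[48:], y[48:]))
        assert h.tap == "pool2"
        assert len(h.rvm.active) < 48

    def test_invalid_downstream(self):
        X, y = _linear_data(n=30, seed=11)
        with pytest.raises(ConfigError):
            fit_hybrid(X, y, downstream="forest")
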