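import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from optsep.network import (
    LayerActivations,
    MarginMaxNetClassifier,
    NetworkArchitecture,
    NetworkParams,
    TrainConfig,
    TrainingDivergedError,
    _loss_and_grads,
    _should_stop,
    compute_loss,
    evaluate,
    forward,
    init_network,
    is_degenerate,
    train_model,
)


def _linear_params(w):
    """Zero-hidden-depth net whose signed score is exactly w . x."""
    w = np.asarray(w, dtype=float)
    W = np.zeros((w.size, 2))
    W[:, 1] = w
    return NetworkParams([W], [np.zeros(2)])


class TestArchitectureAndInit:
    def test_shapes(self):
        params = init_network(NetworkArchitecture((4, 2, 2)), seed=0)
        assert params.weights[0].shape == (4, 2)
        assert params.weights[1].shape == (2, 2)

    def test_seed_determinism(self):
        a = init_network(NetworkArchitecture((5, 3, 2)), seed=1)
        b = init_network(NetworkArchitecture((5, 3, 2)), seed=1)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_non_binary_head_rejected(self):
        with pytest.raises(ValueError, match="2 neurons"):
            NetworkArchitecture((4, 8, 3))

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            NetworkArchitecture((4, 0, 2))


class TestForward:
    def test_zero_network_is_symmetric(self):
        params = NetworkParams(
            [np.zeros((3, 4)), np.zeros((4, 2))], [np.zeros(4), np.zeros(2)]
        )
        acts = forward(params, np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(acts.hidden[0], 0.0)
        assert np.allclose(acts.proba, 0.5)

    def test_hand_computed_single_layer(self):
        W1 = np.array([[1.0, -1.0], [0.5, 2.0]])
        params = NetworkParams([W1, np.eye(2)], [np.zeros(2), np.zeros(2)])
        acts = forward(params, np.array([[2.0, 1.0]]))
        # pre-activation (2.5, 0.0) -> ReLU (2.5, 0.0)
        assert np.allclose(acts.hidden[0], [[2.5, 0.0]])

    def test_softmax_normalized(self):
        rng = np.random.default_rng(0)
        params = init_network(NetworkArchitecture((6, 4, 2)), seed=3)
        acts = forward(params, rng.normal(size=(10, 6)))
        assert np.allclose(acts.proba.sum(axis=1), 1.0)

    def test_dimension_mismatch(self):
        params = init_network(NetworkArchitecture((4, 3, 2)), seed=0)
        with pytest.raises(ValueError, match="features"):
            forward(params, np.ones((2, 5)))


class TestOptsepLoss:
    @pytest.mark.parametrize(
        "x,expected",
        [((2.0, 0.0), 0.5), ((0.5, 0.0), 1.0), ((-1.0, 0.0), 2.5)],
    )
    def test_linear_hinge_cases(self, x, expected):
        # w=(1,0), alpha=0, t=+1: loss = 0.5||w||^2 + max(0, 1 - w.x)
        params = _linear_params([1.0, 0.0])
        acts = forward(params, np.array([x]))
        cfg = TrainConfig(loss_kind="optsep", alpha=0.0)
        assert compute_loss(params, acts, np.array([1]), cfg) == pytest.approx(expected)

    @given(
        st.integers(0, 10_000),
        st.integers(1, 5),
        st.integers(1, 12),
    )
    def test_zero_depth_equals_svm_hinge(self, seed, d, n):
        """With no hidden layers and alpha=0, the loss is exactly the
        soft-margin SVM objective 0.5||w||^2 + sum_i max(0, 1 - t_i w.x_i)."""
        rng = np.random.default_rng(seed)
        w = rng.normal(size=d)
        X = rng.normal(size=(n, d))
        y = rng.integers(0, 2, size=n)
        params = _linear_params(w)
        acts = forward(params, X)
        cfg = TrainConfig(loss_kind="optsep", alpha=0.0)
        t = 2.0 * y - 1.0
        oracle = 0.5 * np.dot(w, w) + np.sum(np.maximum(0.0, 1.0 - t * (X @ w)))
        assert compute_loss(params, acts, y, cfg) == pytest.approx(oracle)

    def test_hinge_monotone_in_margin(self):
        params = _linear_params([1.0])
        cfg = TrainConfig(loss_kind="optsep", alpha=0.0)
        losses = [
            compute_loss(params, forward(params, np.array([[x]])), np.array([1]), cfg)
            for x in (0.2, 0.4, 0.8, 1.6)
        ]
        assert losses == sorted(losses, reverse=True)

    def test_mismatched_sample_count(self):
        params = _linear_params([1.0, 0.0])
        acts = forward(params, np.ones((3, 2)))
        with pytest.raises(ValueError, match="label count"):
            compute_loss(params, acts, np.array([1, 0]), TrainConfig())


class TestGradients:
    @pytest.mark.parametrize("loss_kind", ["softmax", "optsep"])
    def test_backprop_matches_finite_differences(self, loss_kind):
        rng = np.random.default_rng(42)
        arch = NetworkArchitecture((3, 4, 3, 2))
        params = init_network(arch, seed=9)
        X = rng.normal(size=(7, 3))
        y = rng.integers(0, 2, size=7)
        cfg = TrainConfig(loss_kind=loss_kind, alpha=0.02)
        loss, gw, gb = _loss_and_grads(params, X, y, cfg)
        eps = 1e-6
        for l in range(len(params.weights)):
            for idx in [(0, 0), (1, 1)]:
                params.weights[l][idx] += eps
                up = compute_loss(params, forward(params, X), y, cfg)
                params.weights[l][idx] -= 2 * eps
                dn = compute_loss(params, forward(params, X), y, cfg)
                params.weights[l][idx] += eps
                assert gw[l][idx] == pytest.approx((up - dn) / (2 * eps), abs=1e-4)


class TestTraining:
    def test_separable_clouds_reach_perfect_accuracy(self, blobs):
        X, y = blobs
        arch = NetworkArchitecture((2, 4, 2))
        cfg = TrainConfig(loss_kind="optsep", learning_rate=0.05, seed=1,
                          optimizer="gd")
        model = train_model(X, y, arch, cfg)
        assert evaluate(model, X, y) == 1.0
        assert model.loss_history[-1] < model.loss_history[0]

    def test_max_epochs_one(self, blobs):
        X, y = blobs
        cfg = TrainConfig(max_epochs=1, es_window=1, seed=0)
        model = train_model(X, y, NetworkArchitecture((2, 3, 2)), cfg)
        assert model.stopped_epoch == 1

    def test_early_stop_fires_after_window(self):
        cfg = TrainConfig(es_window=5, es_thresh=1e-3, es_mode="abs")
        history = [10.0, 9.0, 8.0]
        assert not _should_stop(history, cfg)
        flat = [1.0] * 6
        assert _should_stop(flat, cfg)  # unchanged over the last 5 epochs
        assert not _should_stop([1.0] * 5, cfg)

    def test_early_stop_relative_mode(self):
        cfg = TrainConfig(es_window=5, es_thresh=0.01, es_mode="rel")
        decaying = [100.0 / (i + 1) for i in range(10)]
        assert not _should_stop(decaying, cfg)
        assert _should_stop([50.0] * 4 + [50.2] * 6, cfg)

    def test_single_class_training_rejected(self, blobs):
        X, y = blobs
        cfg = TrainConfig()
        with pytest.raises(ValueError, match="both classes"):
            train_model(X, np.zeros_like(y), NetworkArchitecture((2, 3, 2)), cfg)


class TestEvaluateAndDegeneracy:
    def test_perfect_and_flipped(self, blobs):
        X, y = blobs
        arch = NetworkArchitecture((2, 4, 2))
        cfg = TrainConfig(loss_kind="softmax", learning_rate=0.05, seed=1,
                          optimizer="gd")
        model = train_model(X, y, arch, cfg)
        assert evaluate(model, X, y) == 1.0
        assert evaluate(model, X, 1 - y) == 0.0

    def test_zero_network_is_degenerate_and_ties_to_class0(self):
        params = NetworkParams(
            [np.zeros((2, 3)), np.zeros((3, 2))], [np.zeros(3), np.zeros(2)]
        )
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert is_degenerate(params, X)
        acts = forward(params, X)
        assert np.all(np.argmax(acts.proba, axis=1) == 0)

    def test_live_network_not_degenerate(self, blobs):
        X, y = blobs
        model = train_model(
            X, y, NetworkArchitecture((2, 4, 2)),
            TrainConfig(learning_rate=0.05, seed=1, optimizer="gd"),
        )
        assert not is_degenerate(model, X)


class TestEstimator:
    def test_fit_predict_roundtrip(self, blobs):
        X, y = blobs
        clf = MarginMaxNetClassifier(
            hidden_layer_sizes=(4,), loss="optsep", learning_rate=0.05,
            optimizer="gd", random_state=0,
        ).fit(X, y)
        assert clf.score(X, y) == 1.0
        assert clf.predict_proba(X).shape == (40, 2)
        assert clf.n_iter_ == len(clf.loss_curve_)

    def test_decision_function_sign_matches_prediction(self, blobs):
        X, y = blobs
        clf = MarginMaxNetClassifier(
            hidden_layer_sizes=(4,), learning_rate=0.05, optimizer="gd",
            random_state=0,
        ).fit(X, y)
        score = clf.decision_function(X)
        assert np.array_equal(clf.predict(X), (score > 0).astype(int))

    def test_clone_and_get_params(self):
        clf = MarginMaxNetClassifier(loss="softmax", alpha=0.5)
        cloned = clone(clf)
        assert cloned.get_params()["alpha"] == 0.5
        assert cloned.get_params()["loss"] == "softmax"

    def test_non_binary_target_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([0, 1, 2, 0, 1, 2])
        with pytest.raises(ValueError, match="2 classes"):
            MarginMaxNetClassifier().fit(X, y)

    def test_nonstandard_class_labels_preserved(self, blobs):
        X, y = blobs
        labels = np.where(y == 0, "natural", "disturbed")
        clf = MarginMaxNetClassifier(
            hidden_layer_sizes=(4,), learning_rate=0.05, optimizer="gd",
            random_state=0,
        ).fit(X, labels)
        assert set(clf.predict(X)) <= {"natural", "disturbed"}
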