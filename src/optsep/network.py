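"""Binary feedforward classifiers with softmax or margin-maximizing objectives.

Two loss functions share one architecture (ReLU hidden layers, a 2-logit
softmax head):

* ``softmax`` — mean cross-entropy, the conventional classifier objective.
* ``optsep``  — a hinge objective inspired by the soft-margin SVM:

      (1/2) ||W_L||^2  +  sum_i max{0, 1 - t_i * s_i}  +  alpha * sum_l ||W_l||^2

  with t_i = 2 y_i - 1 in {-1, +1} the true label and
  s_i = logit_1(i) - logit_0(i) the signed pre-softmax score. The
  final-layer weight-norm term keeps the separating margins finite while the
  hinge pushes the two classes apart, so the learned hidden layers become
  optimally-separating latent spaces. With zero hidden depth and alpha = 0
  this reduces exactly to the linear SVM hinge loss.

Networks here are small (tens of neurons, at most a few hundred samples), so
training is plain full-batch Adam with hand-derived gradients on numpy
arrays; there is no batch-size hyperparameter. The l2 regularizer covers the
weights of every layer; biases are not regularized. The output activation
before the softmax is the identity — a ReLU there would forbid negative
logits and cripple the signed score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import softmax as _softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "NetworkArchitecture",
    "NetworkParams",
    "LayerActivations",
    "TrainConfig",
    "TrainedModel",
    "TrainingDivergedError",
    "MarginMaxNetClassifier",
    "init_network",
    "forward",
    "compute_loss",
    "train_model",
    "evaluate",
]

LOSS_KINDS = ("softmax", "optsep")
ES_MODES = ("abs", "rel")
OPTIMIZERS = ("adam", "gd")
N_CLASSES = 2


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class NetworkArchitecture:
    """Layer widths [d, k1, ..., k_{L-1}, 2] of a binary classifier net.

    Hidden layers use ReLU; the 2-logit head uses identity then softmax.
    Zero hidden layers (a linear softmax model) is allowed — it is the
    degenerate case in which the optsep loss coincides with the linear SVM.
    """

    layer_sizes: tuple[int, ...]

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 2:
            raise ValueError("need at least input and output layers")
        if any(s <= 0 for s in sizes):
            raise ValueError(f"layer sizes must be positive: {sizes}")
        if sizes[-1] != N_CLASSES:
            raise ValueError(f"output layer must have {N_CLASSES} neurons (binary)")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return self.layer_sizes[1:-1]

    @property
    def n_layers(self) -> int:
        """Number of weight layers (hidden + output)."""
        return len(self.layer_sizes) - 1


@dataclass
class NetworkParams:
    """Per-layer weights (fan_in x fan_out) and biases (fan_out,)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self):
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must pair per layer")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or b.ndim != 1 or w.shape[1] != b.shape[0]:
                raise ValueError(f"layer {l}: inconsistent shapes {w.shape}/{b.shape}")
            if l and self.weights[l - 1].shape[1] != w.shape[0]:
                raise ValueError(f"layer {l}: fan-in mismatch")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {l}: non-finite parameters")

    @property
    def architecture(self) -> NetworkArchitecture:
        sizes = (self.weights[0].shape[0],) + tuple(w.shape[1] for w in self.weights)
        return NetworkArchitecture(sizes)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            [w.copy() for w in self.weights], [b.copy() for b in self.biases]
        )


@dataclass
class LayerActivations:
    """Activated values z[l] per hidden layer, plus logits and probabilities."""

    hidden: list[np.ndarray]
    logits: np.ndarray
    proba: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.logits.shape[0]

    def score(self) -> np.ndarray:
        """Signed separation score s = logit_1 - logit_0 per sample."""
        return self.logits[:, 1] - self.logits[:, 0]


@dataclass(frozen=True)
class TrainConfig:
    loss_kind: str = "optsep"
    max_epochs: int = 1000
    alpha: float = 0.01
    es_window: int = 5
    es_thresh: float = 1e-3
    es_mode: str = "abs"
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    momentum: float = 0.9
    clip_norm: float | None = 2.0

    def __post_init__(self):
        if self.loss_kind not in LOSS_KINDS:
            raise ValueError(f"loss_kind must be one of {LOSS_KINDS}")
        if self.es_mode not in ES_MODES:
            raise ValueError(f"es_mode must be one of {ES_MODES}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.clip_norm is not None and self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive or None")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.es_window < 1:
            raise ValueError("es_window must be >= 1")
        if self.max_epochs < self.es_window:
            raise ValueError("max_epochs must be >= es_window")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainedModel:
    params: NetworkParams
    loss_history: list[float]
    config: TrainConfig
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None

    @property
    def stopped_epoch(self) -> int:
        return len(self.loss_history)


def init_network(arch: NetworkArchitecture, seed: int) -> NetworkParams:
    """Seed-deterministic initialization: Glorot-uniform weights; hidden
    biases at 0.1 so ReLU units start active (zero-bias nets on all-positive
    inputs are prone to dead units); zero output biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    sizes = arch.layer_sizes
    n_layers = len(sizes) - 1
    for l, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.full(fan_out, 0.1 if l < n_layers - 1 else 0.0))
    return NetworkParams(weights, biases)


def is_degenerate(model_or_params, X) -> bool:
    """True when the fitted net is structurally dead on the given inputs:
    some hidden layer outputs zero for every sample, or the decision score is
    constant. Such a net predicts one class everywhere — an optimization
    failure (a ReLU layer died), not a fit. The check uses no labels."""
    params = getattr(model_or_params, "params", model_or_params)
    acts = forward(params, np.asarray(X, dtype=float))
    for z in acts.hidden:
        if float(np.max(z)) == 0.0:
            return True
    score = acts.score()
    return float(np.ptp(score)) < 1e-12


def forward(params: NetworkParams, X: np.ndarray) -> LayerActivations:
    """Propagate X through ReLU hidden layers to logits and softmax probs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects "
            f"{params.weights[0].shape[0]}"
        )
    z = X
    hidden = []
    n_layers = len(params.weights)
    for l in range(n_layers - 1):
        z = np.maximum(z @ params.weights[l] + params.biases[l], 0.0)
        hidden.append(z)
    logits = z @ params.weights[-1] + params.biases[-1]
    proba = _softmax(logits, axis=1)
    return LayerActivations(hidden, logits, proba)


def _labels_as_array(y) -> np.ndarray:
    arr = y.labels if hasattr(y, "labels") else np.asarray(y)
    arr = np.asarray(arr, dtype=int)
    if set(np.unique(arr)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return arr


def compute_loss(
    params: NetworkParams, acts: LayerActivations, y, config: TrainConfig
) -> float:
    """Objective value for the given activations and labels (see module doc)."""
    t_y = _labels_as_array(y)
    if len(t_y) != acts.n_samples:
        raise ValueError("label count does not match activation batch")
    reg = config.alpha * sum(float(np.sum(w * w)) for w in params.weights)
    if config.loss_kind == "softmax":
        p = np.clip(acts.proba[np.arange(len(t_y)), t_y], 1e-12, None)
        return float(np.mean(-np.log(p)) + reg)
    t = 2.0 * t_y - 1.0
    hinge = np.maximum(0.0, 1.0 - t * acts.score())
    w_last = params.weights[-1]
    return float(0.5 * np.sum(w_last * w_last) + np.sum(hinge) + reg)


def _loss_and_grads(params: NetworkParams, X: np.ndarray, y: np.ndarray,
                    config: TrainConfig):
    """Full-batch loss with hand-derived gradients (backprop through ReLU)."""
    n = X.shape[0]
    zs = [X]
    pres = []
    z = X
    n_layers = len(params.weights)
    for l in range(n_layers - 1):
        pre = z @ params.weights[l] + params.biases[l]
        z = np.maximum(pre, 0.0)
        pres.append(pre)
        zs.append(z)
    logits = z @ params.weights[-1] + params.biases[-1]
    proba = _softmax(logits, axis=1)

    reg = config.alpha * sum(float(np.sum(w * w)) for w in params.weights)
    if config.loss_kind == "softmax":
        p = np.clip(proba[np.arange(n), y], 1e-12, None)
        loss = float(np.mean(-np.log(p)) + reg)
        onehot = np.zeros_like(proba)
        onehot[np.arange(n), y] = 1.0
        dlogits = (proba - onehot) / n
        extra_last = 0.0
    else:
        t = 2.0 * y.astype(float) - 1.0
        s = logits[:, 1] - logits[:, 0]
        hinge = np.maximum(0.0, 1.0 - t * s)
        w_last = params.weights[-1]
        loss = float(0.5 * np.sum(w_last * w_last) + np.sum(hinge) + reg)
        ds = np.where(hinge > 0.0, -t, 0.0)
        dlogits = np.stack([-ds, ds], axis=1)
        extra_last = params.weights[-1]  # d/dW of (1/2)||W_L||^2

    grads_w = [None] * n_layers
    grads_b = [None] * n_layers
    delta = dlogits
    grads_w[-1] = zs[-1].T @ delta + extra_last + 2.0 * config.alpha * params.weights[-1]
    grads_b[-1] = delta.sum(axis=0)
    for l in range(n_layers - 2, -1, -1):
        delta = (delta @ params.weights[l + 1].T) * (pres[l] > 0.0)
        grads_w[l] = zs[l].T @ delta + 2.0 * config.alpha * params.weights[l]
        grads_b[l] = delta.sum(axis=0)
    return loss, grads_w, grads_b


def _should_stop(history: list[float], config: TrainConfig) -> bool:
    w = config.es_window
    if config.es_mode == "abs":
        # loss unchanged (within es_thresh) over the last w epochs
        if len(history) < w + 1:
            return False
        window = history[-(w + 1):]
        return max(window) - min(window) <= config.es_thresh
    # relative: mean loss over the last w epochs within es_thresh (fractional)
    # of the mean over the w epochs before that
    if len(history) < 2 * w:
        return False
    recent = float(np.mean(history[-w:]))
    prev = float(np.mean(history[-2 * w:-w]))
    return abs(recent - prev) <= config.es_thresh * max(abs(prev), 1e-12)


def _train(
    X: np.ndarray, y: np.ndarray, arch: NetworkArchitecture, config: TrainConfig
) -> tuple[NetworkParams, list[float]]:
    """Full-batch training loop.

    ``optimizer="adam"`` is the usual adaptive default. ``optimizer="gd"``
    is momentum gradient descent with global gradient-norm clipping; unlike
    Adam it preserves the relative magnitudes of gradient components, which
    matters when the fitted first-layer weights are later ranked by
    magnitude (weight tracing) — Adam's per-coordinate normalization makes
    weakly- and strongly-driven weights grow at the same rate.
    """
    params = init_network(arch, config.seed)
    m_w = [np.zeros_like(w) for w in params.weights]
    v_w = [np.zeros_like(w) for w in params.weights]
    m_b = [np.zeros_like(b) for b in params.biases]
    v_b = [np.zeros_like(b) for b in params.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    history: list[float] = []
    for epoch in range(1, config.max_epochs + 1):
        loss, gw, gb = _loss_and_grads(params, X, y, config)
        if not np.isfinite(loss):
            raise TrainingDivergedError(epoch)
        history.append(loss)
        if _should_stop(history, config):
            break
        if config.optimizer == "adam":
            c1 = 1.0 - beta1**epoch
            c2 = 1.0 - beta2**epoch
            for l in range(len(params.weights)):
                m_w[l] = beta1 * m_w[l] + (1 - beta1) * gw[l]
                v_w[l] = beta2 * v_w[l] + (1 - beta2) * gw[l] ** 2
                params.weights[l] -= lr * (m_w[l] / c1) / (np.sqrt(v_w[l] / c2) + eps)
                m_b[l] = beta1 * m_b[l] + (1 - beta1) * gb[l]
                v_b[l] = beta2 * v_b[l] + (1 - beta2) * gb[l] ** 2
                params.biases[l] -= lr * (m_b[l] / c1) / (np.sqrt(v_b[l] / c2) + eps)
        else:  # clipped momentum gradient descent (m_w/m_b reused as velocity)
            scale = 1.0
            if config.clip_norm is not None:
                gnorm = np.sqrt(
                    sum(float(np.sum(g * g)) for g in gw)
                    + sum(float(np.sum(g * g)) for g in gb)
                )
                scale = min(1.0, config.clip_norm / max(gnorm, 1e-12))
            for l in range(len(params.weights)):
                m_w[l] = config.momentum * m_w[l] - lr * scale * gw[l]
                m_b[l] = config.momentum * m_b[l] - lr * scale * gb[l]
                params.weights[l] += m_w[l]
                params.biases[l] += m_b[l]
    return params, history


class MarginMaxNetClassifier(ClassifierMixin, BaseEstimator):
    """Binary MLP classifier with a softmax or margin-maximizing objective.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int, default (16, 8, 4)
        Widths of the ReLU hidden layers. May be empty for a linear model.
    loss : {"optsep", "softmax"}
        ``"optsep"`` trains the hinge objective that maximizes inter-class
        separation in every latent layer; ``"softmax"`` is plain
        cross-entropy.
    alpha : float, default 0.01
        l2 weight-decay coefficient, applied to every layer's weights.
    learning_rate : float, default 1e-3
        Adam step size (full-batch).
    max_epochs : int, default 1000
    es_window, es_thresh, es_mode
        Early stopping: in ``"abs"`` mode training stops once the loss has
        changed by no more than ``es_thresh`` over the last ``es_window``
        epochs; in ``"rel"`` mode once the mean loss over the last
        ``es_window`` epochs is within ``es_thresh`` (fraction) of the mean
        over the preceding window.
    random_state : int or None
        Seed for weight initialization. Training is full-batch, so the seed
        alone makes a fit reproducible.

    Attributes
    ----------
    classes_ : ndarray of the two class labels (sorted).
    params_ : NetworkParams, the fitted weights and biases.
    loss_curve_ : list of per-epoch loss values.
    n_iter_ : number of epochs actually run.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (16, 8, 4),
        loss: str = "optsep",
        alpha: float = 0.01,
        learning_rate: float = 1e-3,
        max_epochs: int = 1000,
        es_window: int = 5,
        es_thresh: float = 1e-3,
        es_mode: str = "abs",
        optimizer: str = "adam",
        momentum: float = 0.9,
        clip_norm: float | None = 2.0,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.loss = loss
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.es_window = es_window
        self.es_thresh = es_thresh
        self.es_mode = es_mode
        self.optimizer = optimizer
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        seed = self.random_state if self.random_state is not None else 0
        return TrainConfig(
            loss_kind=self.loss,
            max_epochs=self.max_epochs,
            alpha=self.alpha,
            es_window=self.es_window,
            es_thresh=self.es_thresh,
            es_mode=self.es_mode,
            learning_rate=self.learning_rate,
            seed=int(seed),
            optimizer=self.optimizer,
            momentum=self.momentum,
            clip_norm=self.clip_norm,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"binary classifier: need exactly 2 classes, got {len(self.classes_)}"
            )
        y01 = np.searchsorted(self.classes_, y)
        arch = NetworkArchitecture(
            (X.shape[1], *tuple(self.hidden_layer_sizes), N_CLASSES)
        )
        config = self._config()
        self.params_, self.loss_curve_ = _train(X, y01, arch, config)
        self.n_iter_ = len(self.loss_curve_)
        self.architecture_ = arch
        self.n_features_in_ = X.shape[1]
        return self

    def _forward(self, X) -> LayerActivations:
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float)
        return forward(self.params_, X)

    def decision_function(self, X) -> np.ndarray:
        return self._forward(X).score()

    def predict_proba(self, X) -> np.ndarray:
        return self._forward(X).proba

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax takes the first maximum: ties break to the lower class index
        return self.classes_[np.argmax(proba, axis=1)]

    def hidden_activations(self, X) -> list[np.ndarray]:
        """Activated values z[l] of every hidden layer for the given samples."""
        return self._forward(X).hidden


# ---------------------------------------------------------------------------
# procedural wrappers over the estimator, for pipeline-style use

def train_model(table, labels, arch: NetworkArchitecture, config: TrainConfig,
                train_indices: np.ndarray | None = None,
                test_indices: np.ndarray | None = None) -> TrainedModel:
    """Train on a (CountTable, LabelVector) pair (or plain arrays).

    If ``train_indices`` is given, only those rows are fitted; the index sets
    are recorded on the result.
    """
    X = table.counts if hasattr(table, "counts") else np.asarray(table, float)
    y = _labels_as_array(labels)
    if X.shape[1] != arch.n_inputs:
        raise ValueError("table width does not match architecture input size")
    if train_indices is not None:
        X_fit, y_fit = X[train_indices], y[train_indices]
    else:
        X_fit, y_fit = X, y
    if len(np.unique(y_fit)) != 2:
        raise ValueError("training set must contain both classes")
    params, history = _train(X_fit, y_fit, arch, config)
    return TrainedModel(params, history, config, train_indices, test_indices)


def evaluate(model: TrainedModel, X, y) -> float:
    """Fraction of samples whose softmax argmax matches the true label."""
    acts = forward(model.params, np.asarray(X, dtype=float))
    pred = np.argmax(acts.proba, axis=1)
    return float(np.mean(pred == _labels_as_array(y)))
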