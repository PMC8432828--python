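"""Separating margins, direction of separation, and weight tracing.

The extraction procedure works on the latent coordinates z[l] of a trained
network, by default the first hidden layer (it sits right after the inputs,
so its neurons are activated affine combinations of the raw variables, and
the margin-maximizing loss makes it an optimally-separated space):

1. find the closest pair of opposite-class samples z(+), z(-) — the pair
   spanning the separating margin (Euclidean distance);
2. the direction of separation is m = z(+) - z(-);
3. rank latent neurons by |m_j| and keep the top_n;
4. for each kept neuron, rank its first-layer input weights (by magnitude,
   or by raw value when the sign of the correlation matters) and keep the
   top_w input variables.

The selected input variables are the ones with the most leverage on the
direction that best separates the classes. This is pure weight/geometry
tracing: no gradient saliency, no surrogate models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .network import TrainedModel, NetworkParams, forward, _labels_as_array

__all__ = [
    "SeparationDirection",
    "ExtractionConfig",
    "FeatureSelection",
    "MarginReport",
    "closest_opposing_pair",
    "separation_direction",
    "layer_margins",
    "top_neurons",
    "trace_input_weights",
    "extract_features",
]

RANK_MODES = ("absolute", "signed")


@dataclass
class SeparationDirection:
    """The margin-spanning pair in one latent layer and their difference."""

    layer: int
    z_plus: np.ndarray
    z_minus: np.ndarray

    def __post_init__(self):
        self.z_plus = np.asarray(self.z_plus, dtype=float).ravel()
        self.z_minus = np.asarray(self.z_minus, dtype=float).ravel()
        if self.z_plus.shape != self.z_minus.shape:
            raise ValueError("z(+) and z(-) must have equal length")

    @property
    def m_vec(self) -> np.ndarray:
        # fixed sign convention z(+) - z(-); either subtraction spans the same
        # margin, and absolute-value ranking makes the choice immaterial
        return self.z_plus - self.z_minus

    @property
    def margin(self) -> float:
        return float(np.linalg.norm(self.m_vec))


@dataclass(frozen=True)
class ExtractionConfig:
    top_n: int = 2
    top_w: int = 2
    layer: int = 1
    rank_mode: str = "absolute"

    def __post_init__(self):
        if self.top_n < 1 or self.top_w < 1:
            raise ValueError("top_n and top_w must be >= 1")
        if self.layer < 1:
            raise ValueError("layer indexes hidden layers from 1")
        if self.rank_mode not in RANK_MODES:
            raise ValueError(f"rank_mode must be one of {RANK_MODES}")


@dataclass
class FeatureSelection:
    """Traced (neuron, input feature, weight) slots for one experiment."""

    seed: int | None
    slots: list[tuple[int, str, float]]
    features: list[str] = field(init=False)

    def __post_init__(self):
        seen: dict[str, None] = {}
        for _, fid, _ in self.slots:
            seen.setdefault(fid, None)
        self.features = list(seen)


@dataclass
class MarginReport:
    """Per hidden layer: separating margin and the spanning sample pair."""

    margins: list[float]
    pairs: list[tuple[int, int]]

    def __post_init__(self):
        if len(self.margins) != len(self.pairs):
            raise ValueError("one pair per margin required")
        if any(m < 0 for m in self.margins):
            raise ValueError("margins must be >= 0")

    def __len__(self) -> int:
        return len(self.margins)


def closest_opposing_pair(
    Z_pos: np.ndarray, Z_neg: np.ndarray
) -> tuple[int, int, float]:
    """Indices (into Z_pos, Z_neg) and distance of the closest cross-class pair.

    Ties resolve to the lexicographically smallest (i, j).
    """
    Z_pos = np.atleast_2d(np.asarray(Z_pos, dtype=float))
    Z_neg = np.atleast_2d(np.asarray(Z_neg, dtype=float))
    if Z_pos.shape[0] == 0 or Z_neg.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    if Z_pos.shape[1] != Z_neg.shape[1]:
        raise ValueError("coordinate dimensions differ between classes")
    dist = cdist(Z_pos, Z_neg)
    i, j = np.unravel_index(np.argmin(dist), dist.shape)  # first min: lex smallest
    return int(i), int(j), float(dist[i, j])


def separation_direction(z_plus, z_minus, layer: int = 1) -> SeparationDirection:
    """Direction of separation m = z(+) - z(-) with its Euclidean margin."""
    return SeparationDirection(layer=layer, z_plus=z_plus, z_minus=z_minus)


def top_neurons(direction: SeparationDirection | np.ndarray, top_n: int) -> np.ndarray:
    """Indices of the top_n entries of m by absolute value, ties to lower index."""
    m = direction.m_vec if isinstance(direction, SeparationDirection) else np.asarray(direction, float)
    if not 1 <= top_n <= m.size:
        raise ValueError(f"top_n must lie in [1, {m.size}], got {top_n}")
    return np.argsort(-np.abs(m), kind="stable")[:top_n]


def trace_input_weights(
    params: NetworkParams,
    neuron: int,
    top_w: int,
    mode: str = "absolute",
    feature_ids: list[str] | None = None,
) -> list[tuple[str, float]]:
    """Top first-layer input weights feeding ``neuron``.

    ``mode="absolute"`` ranks by |w| (feature relevance regardless of sign);
    ``mode="signed"`` ranks by the raw value, distinguishing positively from
    negatively correlated inputs. Ties resolve to the lower feature index.
    """
    if mode not in RANK_MODES:
        raise ValueError(f"mode must be one of {RANK_MODES}")
    w1 = params.weights[0]
    d = w1.shape[0]
    if not 0 <= neuron < w1.shape[1]:
        raise ValueError(f"neuron {neuron} out of range for first hidden layer")
    if not 1 <= top_w <= d:
        raise ValueError(f"top_w must lie in [1, {d}], got {top_w}")
    if feature_ids is None:
        feature_ids = [str(j) for j in range(d)]
    elif len(feature_ids) != d:
        raise ValueError("feature_ids length must equal input dimension")
    col = w1[:, neuron]
    key = np.abs(col) if mode == "absolute" else col
    order = np.argsort(-key, kind="stable")[:top_w]
    return [(feature_ids[j], float(col[j])) for j in order]


def _split_latent(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive/negative-class latent blocks, rows canonically ordered.

    Rows within each class are sorted lexicographically by coordinates so the
    closest-pair tie rule does not depend on the order samples arrived in.
    """
    pos = Z[y == 1]
    neg = Z[y == 0]
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("both classes must be present")
    pos = pos[np.lexsort(pos.T[::-1])]
    neg = neg[np.lexsort(neg.T[::-1])]
    return pos, neg


def layer_margins(model: TrainedModel, X, y) -> MarginReport:
    """Separating margin in every hidden layer, for the given samples."""
    y = _labels_as_array(y)
    acts = forward(model.params, np.asarray(X, dtype=float))
    margins, pairs = [], []
    for Z in acts.hidden:
        pos, neg = _split_latent(Z, y)
        i, j, dist = closest_opposing_pair(pos, neg)
        margins.append(dist)
        pairs.append((i, j))
    return MarginReport(margins, pairs)


def extract_features(
    model: TrainedModel,
    X,
    y,
    config: ExtractionConfig = ExtractionConfig(),
    feature_ids: list[str] | None = None,
    seed: int | None = None,
) -> FeatureSelection:
    """Full extraction: margin pair -> direction -> top neurons -> top weights."""
    y = _labels_as_array(y)
    acts = forward(model.params, np.asarray(X, dtype=float))
    if config.layer > len(acts.hidden):
        raise ValueError(
            f"layer {config.layer} exceeds {len(acts.hidden)} hidden layers"
        )
    Z = acts.hidden[config.layer - 1]
    pos, neg = _split_latent(Z, y)
    i, j, dist = closest_opposing_pair(pos, neg)
    direction = separation_direction(pos[i], neg[j], layer=config.layer)
    if dist == 0.0:
        warnings.warn(
            "coincident opposing samples: zero margin, neuron ranking falls "
            "back to the tie rule",
            RuntimeWarning,
            stacklevel=2,
        )
    neurons = top_neurons(direction, config.top_n)
    slots: list[tuple[int, str, float]] = []
    if config.layer == 1:
        for neuron in neurons:
            traced = trace_input_weights(
                model.params, int(neuron), config.top_w, config.rank_mode, feature_ids
            )
            slots.extend((int(neuron), fid, w) for fid, w in traced)
    else:
        # Deeper layers are supported for study, but their incoming weights
        # combine previous-layer neurons, not raw inputs: traced ids name
        # those latent units instead of species.
        w_in = model.params.weights[config.layer - 1]
        unit_ids = [f"z{config.layer - 1}_{j}" for j in range(w_in.shape[0])]
        for neuron in neurons:
            col = w_in[:, int(neuron)]
            key = np.abs(col) if config.rank_mode == "absolute" else col
            if not config.top_w <= w_in.shape[0]:
                raise ValueError("top_w exceeds fan-in of the chosen layer")
            order = np.argsort(-key, kind="stable")[: config.top_w]
            slots.extend(
                (int(neuron), unit_ids[j], float(col[j])) for j in order
            )
    return FeatureSelection(seed=seed, slots=slots)
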