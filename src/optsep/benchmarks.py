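"""Reference experiment protocols: the binary Iris benchmark.

The Fisher Iris table (150 samples, 4 measurements in cm, 3 species) ships
with scikit-learn; restricted to its first two species (setosa vs
versicolor, 100 samples) it is a linearly separable binary problem whose
relevant features are known from domain knowledge to be petal length and
petal width. That makes it the canonical check for this package: both loss
functions should classify it perfectly, the margin-maximizing loss should
inflate the latent separating margins far beyond the softmax baseline, and
the traced features should be the two petal measurements.

Protocol: per-split centered range scaling of the four measurements (fit on
the training rows), 80:20 stratified splits, ReLU hidden layers (16, 8, 4),
up to 1000 epochs per experiment, early stopping once the loss has moved by
no more than 1e-3 over the last 5 epochs, repeated over many random
initializations. The optimizer is clipped momentum full-batch gradient
descent (step 0.05): plain gradient descent preserves the relative gradient
magnitudes that the later weight-magnitude tracing depends on, which Adam's
per-coordinate normalization would erase.
"""

from __future__ import annotations

import numpy as np

from .aggregate import ExperimentBatch, run_experiments
from .data_io import CountTable, LabelVector
from .network import NetworkArchitecture, TrainConfig
from .separation import ExtractionConfig

__all__ = [
    "IRIS_FEATURES",
    "CenterRangeScaler",
    "load_binary_iris",
    "iris_train_config",
    "run_iris_benchmark",
    "community_train_config",
    "run_community_benchmark",
]

IRIS_FEATURES = ["sepal_length", "sepal_width", "petal_length", "petal_width"]
IRIS_HIDDEN = (16, 8, 4)


class CenterRangeScaler:
    """Center each feature by its training mean and divide by its range.

    Unlike variance autoscaling this keeps the features' relative spreads,
    it only removes the arbitrary offset and unit. Centering matters for the
    weight-tracing step: with all-positive raw inputs, ReLU units that
    specialize on one class grow first-layer weights along that class's raw
    mean (where large-valued features dominate regardless of relevance);
    after centering the class means are +/- half the class difference, so
    weight growth tracks discriminative signal only.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        span = X.max(axis=0) - X.min(axis=0)
        span[span == 0.0] = 1.0
        self.range_ = span
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.range_


def load_binary_iris() -> tuple[CountTable, LabelVector]:
    """First two Iris classes (setosa=0, versicolor=1) as a table/label pair."""
    from sklearn.datasets import load_iris

    data = load_iris()
    keep = data.target < 2
    X = data.data[keep]
    y = data.target[keep]
    sample_ids = [f"iris{i + 1:03d}" for i in range(X.shape[0])]
    table = CountTable(sample_ids, IRIS_FEATURES, X)
    labels = LabelVector(sample_ids, y, {"setosa": 0, "versicolor": 1})
    return table, labels


def iris_train_config(loss: str, seed: int = 0) -> TrainConfig:
    return TrainConfig(
        loss_kind=loss,
        max_epochs=1000,
        alpha=0.01,
        es_window=5,
        es_thresh=1e-3,
        es_mode="abs",
        learning_rate=0.05,
        seed=seed,
        optimizer="gd",
        momentum=0.9,
        clip_norm=2.0,
    )


def run_iris_benchmark(
    n_experiments: int = 100,
    master_seed: int = 0,
    losses: tuple[str, ...] = ("softmax", "optsep"),
    top_n: int = 2,
    top_w: int = 2,
) -> dict[str, ExperimentBatch]:
    """Run the Iris protocol for each loss; returns batches keyed by loss."""
    table, labels = load_binary_iris()
    arch = NetworkArchitecture((4, *IRIS_HIDDEN, 2))
    extract = ExtractionConfig(top_n=top_n, top_w=top_w)
    batches = {}
    for loss in losses:
        batches[loss] = run_experiments(
            table,
            labels,
            arch,
            iris_train_config(loss),
            extract,
            n_experiments=n_experiments,
            master_seed=master_seed,
            test_fraction=0.2,
            split_scaler=CenterRangeScaler,
        )
    return batches


COMMUNITY_HIDDEN = (32, 8, 4)


def community_train_config(loss: str = "optsep", seed: int = 0) -> TrainConfig:
    """Training protocol for log-transformed abundance tables (50 species in,
    hidden layers 32-8-4, the same clipped momentum GD as the Iris
    protocol). No feature scaling: log10(x+1) counts are used as-is so that
    abundant and rare species stay distinguishable."""
    return TrainConfig(
        loss_kind=loss,
        max_epochs=1000,
        alpha=0.01,
        es_window=5,
        es_thresh=1e-3,
        es_mode="abs",
        learning_rate=0.05,
        seed=seed,
        optimizer="gd",
        momentum=0.9,
        clip_norm=2.0,
    )


def run_community_benchmark(
    table: CountTable,
    labels: LabelVector,
    n_experiments: int = 50,
    master_seed: int = 0,
    loss: str = "optsep",
    hidden: tuple[int, ...] = COMMUNITY_HIDDEN,
    top_n: int = 3,
    top_w: int = 3,
) -> ExperimentBatch:
    """Indicator-extraction ensemble on a (preprocessed) abundance table.

    Extraction keeps the top 3 latent directions and 3 input weights each
    (9 slots per run): enough candidate slots to represent a realistic
    indicator set in every run, while the ensemble frequency still filters
    chance selections.
    """
    arch = NetworkArchitecture((table.n_species, *hidden, 2))
    return run_experiments(
        table,
        labels,
        arch,
        community_train_config(loss),
        ExtractionConfig(top_n=top_n, top_w=top_w),
        n_experiments=n_experiments,
        master_seed=master_seed,
        test_fraction=0.2,
    )
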