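"""Multi-experiment harness: repeated seeded runs, frequency ranking, summaries.

A single training run is sensitive to its random initialization — poor inits
converge to bad local minima and trace spurious features. The remedy is an
ensemble: train many models from scratch, each on a fresh stratified split,
extract features from each, and rank input variables by how often they are
selected. Two denominators are offered for the frequency percentages:

* ``per_experiment`` — share of runs whose (distinct) selection contains the
  feature; values can sum past 100 because a run selects several features.
* ``per_slot`` — share of all (neuron, weight) selection slots naming the
  feature; values sum to 100 up to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone

from .data_io import CountTable, LabelVector, check_paired
from .network import (
    NetworkArchitecture,
    TrainConfig,
    TrainedModel,
    evaluate,
    is_degenerate,
    train_model,
)
from .preprocess import stratified_split
from .separation import ExtractionConfig, FeatureSelection, MarginReport, extract_features, layer_margins

__all__ = [
    "ExperimentRun",
    "ExperimentBatch",
    "FeatureFrequencyTable",
    "run_experiments",
    "frequency_ranking",
    "summarize",
    "evaluate_feature_subset",
]

FREQ_MODES = ("per_experiment", "per_slot")
_MAX_REDRAWS = 20


@dataclass
class ExperimentRun:
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    train_accuracy: float
    test_accuracy: float
    margins: MarginReport
    selection: FeatureSelection
    redrawn_from: list[int] = field(default_factory=list)


@dataclass
class ExperimentBatch:
    runs: list[ExperimentRun]
    architecture: NetworkArchitecture
    train_config: TrainConfig
    extract_config: ExtractionConfig
    master_seed: int
    test_fraction: float

    def __post_init__(self):
        if not self.runs:
            raise ValueError("a batch needs at least one run")

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def test_accuracies(self) -> np.ndarray:
        return np.array([r.test_accuracy for r in self.runs])

    @property
    def train_accuracies(self) -> np.ndarray:
        return np.array([r.train_accuracy for r in self.runs])


@dataclass
class FeatureFrequencyTable:
    """feature id -> selection frequency (percent), sorted for reporting."""

    frequencies: dict[str, float]
    mode: str

    def __post_init__(self):
        if self.mode not in FREQ_MODES:
            raise ValueError(f"mode must be one of {FREQ_MODES}")

    def items(self) -> list[tuple[str, float]]:
        return sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))

    def __getitem__(self, fid: str) -> float:
        return self.frequencies[fid]

    def top(self, n: int) -> list[str]:
        return [fid for fid, _ in self.items()[:n]]


def _run_seed(master_seed: int, index: int, attempt: int = 0) -> int:
    ss = np.random.SeedSequence((int(master_seed), int(index), int(attempt)))
    return int(ss.generate_state(1, np.uint32)[0] % 2**31)


def run_experiments(
    table: CountTable,
    labels: LabelVector,
    arch: NetworkArchitecture,
    train_config: TrainConfig,
    extract_config: ExtractionConfig = ExtractionConfig(),
    n_experiments: int = 100,
    master_seed: int = 0,
    test_fraction: float = 0.2,
    split_scaler: Callable[[], object] | None = None,
) -> ExperimentBatch:
    """Train/evaluate/extract ``n_experiments`` independently seeded models.

    Every run draws its own stratified split and weight initialization from a
    seed derived deterministically from ``(master_seed, run_index)``, so
    batches are reproducible and run i is the same whether 10 or 10000 runs
    are requested. A run that degenerates — a single-class split, or a net
    whose hidden layer died during training (constant output) — is re-drawn
    with the next derived seed; every discarded seed is recorded on the run.

    ``split_scaler``, if given, is a zero-argument factory returning a fresh
    fit/transform scaler per run; it is fitted on the training rows only and
    applied to all rows (continuous-measurement benchmarks scale their
    features; count tables are used as-is after the log transform).
    """
    check_paired(table, labels)
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    runs: list[ExperimentRun] = []
    y = labels.labels
    X = table.counts
    for i in range(n_experiments):
        redrawn: list[int] = []
        for attempt in range(_MAX_REDRAWS + 1):
            seed = _run_seed(master_seed, i, attempt)
            train_idx, test_idx = stratified_split(labels, test_fraction, seed)
            if len(set(y[train_idx])) < 2 or len(set(y[test_idx])) < 2:
                redrawn.append(seed)
                continue
            config = replace(train_config, seed=seed)
            if split_scaler is not None:
                scaler = split_scaler()
                scaler.fit(X[train_idx])
                X_use = scaler.transform(X)
            else:
                X_use = X
            model = train_model(X_use, labels, arch, config, train_idx, test_idx)
            # a net whose hidden layer died outputs one class everywhere;
            # like a single-class split, the run is re-drawn with the next
            # derived seed (recorded), rather than polluting the ensemble
            # with an optimization failure
            if is_degenerate(model, X_use[train_idx]):
                redrawn.append(seed)
                continue
            break
        else:
            raise RuntimeError(
                f"run {i}: no usable split/initialization in "
                f"{_MAX_REDRAWS + 1} attempts"
            )
        train_acc = evaluate(model, X_use[train_idx], y[train_idx])
        test_acc = evaluate(model, X_use[test_idx], y[test_idx])
        # margins and extraction are computed on the training samples only:
        # every fitted quantity is kept blind to the held-out set
        margins = layer_margins(model, X_use[train_idx], y[train_idx])
        selection = extract_features(
            model,
            X_use[train_idx],
            y[train_idx],
            extract_config,
            feature_ids=table.species_ids,
            seed=seed,
        )
        runs.append(
            ExperimentRun(
                seed, train_idx, test_idx, train_acc, test_acc, margins,
                selection, redrawn,
            )
        )
    return ExperimentBatch(
        runs, arch, train_config, extract_config, master_seed, test_fraction
    )


def frequency_ranking(
    batch: ExperimentBatch, mode: str = "per_slot"
) -> FeatureFrequencyTable:
    """Selection frequency of every feature over the batch (see module doc)."""
    if mode not in FREQ_MODES:
        raise ValueError(f"mode must be one of {FREQ_MODES}")
    if len(batch.runs) == 0:
        raise ValueError("empty batch")
    freqs: dict[str, float] = {}
    if mode == "per_experiment":
        for run in batch.runs:
            for fid in run.selection.features:
                freqs[fid] = freqs.get(fid, 0.0) + 1.0
        denom = len(batch.runs)
    else:
        total = 0
        for run in batch.runs:
            for _, fid, _ in run.selection.slots:
                freqs[fid] = freqs.get(fid, 0.0) + 1.0
                total += 1
        denom = total
    return FeatureFrequencyTable(
        {fid: 100.0 * c / denom for fid, c in freqs.items()}, mode
    )


def summarize(batch: ExperimentBatch) -> dict:
    """Accuracy avg/max/min/std and per-layer margin avg/max/min over runs.

    The std is the population standard deviation of the test accuracies.
    """
    if len(batch.runs) == 0:
        raise ValueError("empty batch")
    test = batch.test_accuracies
    train = batch.train_accuracies
    margins = np.array([r.margins.margins for r in batch.runs])  # runs x layers
    return {
        "n_experiments": len(batch.runs),
        "train_accuracy": {
            "avg": float(train.mean()),
            "max": float(train.max()),
            "min": float(train.min()),
            "std": float(train.std()),
        },
        "test_accuracy": {
            "avg": float(test.mean()),
            "max": float(test.max()),
            "min": float(test.min()),
            "std": float(test.std()),
        },
        "margins_per_layer": [
            {
                "layer": l + 1,
                "avg": float(margins[:, l].mean()),
                "max": float(margins[:, l].max()),
                "min": float(margins[:, l].min()),
            }
            for l in range(margins.shape[1])
        ],
    }


def evaluate_feature_subset(
    table: CountTable,
    labels: LabelVector,
    feature_ids: Sequence[str],
    classifier,
    n_runs: int = 100,
    test_fraction: float = 0.2,
    master_seed: int = 0,
) -> dict:
    """Repeated-split test accuracy of any fit/predict classifier on a subset.

    Restricts the table to ``feature_ids`` (e.g. the extracted indicators),
    then over ``n_runs`` stratified splits fits a fresh classifier and scores
    the held-out samples. Returns avg and population std of the accuracies.
    """
    check_paired(table, labels)
    if len(feature_ids) == 0:
        raise ValueError("feature subset must be non-empty")
    sub = table.select_species(list(feature_ids))
    X, y = sub.counts, labels.labels
    accs = []
    for i in range(n_runs):
        seed = _run_seed(master_seed, i)
        train_idx, test_idx = stratified_split(labels, test_fraction, seed)
        try:
            clf = clone(classifier)
        except TypeError:
            clf = classifier  # plain fit/predict contract, refit in place
        if hasattr(clf, "random_state"):
            try:
                clf.set_params(random_state=seed)
            except (AttributeError, ValueError):
                pass
        clf.fit(X[train_idx], y[train_idx])
        pred = np.asarray(clf.predict(X[test_idx]))
        accs.append(float(np.mean(pred == y[test_idx])))
    accs = np.array(accs)
    return {"avg": float(accs.mean()), "std": float(accs.std()), "n_runs": n_runs}
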