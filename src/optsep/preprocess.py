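"""Count-table preprocessing: abundance filtering, log transform, splitting.

The pipeline mirrors standard practice for sparse OTU/ASV tables feeding a
dense classifier: keep the top-k species by total abundance across all
samples, then apply log10(x+1) so that rare-but-high-abundance species remain
visible next to the many sparse ones. Mean/variance autoscaling is
deliberately NOT offered: it would equalize species that differ by orders of
magnitude in abundance, destroying exactly the contrast the downstream
extractor relies on. Rarefaction and compositional (CLR) transforms are out
of scope.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data_io import CountTable, LabelVector, check_paired

__all__ = [
    "TopAbundanceSelector",
    "Log10Transformer",
    "select_top_species",
    "log_transform",
    "stratified_split",
]


class TopAbundanceSelector(TransformerMixin, BaseEstimator):
    """Keep the ``k`` columns with the largest total abundance.

    Ties are broken toward the lower original column index, and kept columns
    preserve their original order, so the transform is deterministic and
    idempotent.
    """

    def __init__(self, k: int = 50):
        self.k = k

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if not (isinstance(self.k, (int, np.integer)) and self.k > 0):
            raise ValueError(f"k must be a positive integer, got {self.k!r}")
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds {X.shape[1]} available species")
        sums = X.sum(axis=0)
        # stable argsort on -sums: ties fall to the lower index
        top = np.argsort(-sums, kind="stable")[: self.k]
        self.support_ = np.sort(top)
        self.column_sums_ = sums
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return X[:, self.support_]


class Log10Transformer(TransformerMixin, BaseEstimator):
    """Elementwise x -> log10(x + 1); zeros map to zero, monotone in x."""

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("negative entries cannot be log-transformed")
        return np.log10(X + 1.0)


def select_top_species(table: CountTable, k: int) -> tuple[CountTable, list[str]]:
    """Restrict ``table`` to the k species with the largest column sums.

    Selection is computed on all samples, before any train/test split; this
    leaks marginal abundance information across the split and is a documented
    caveat of the procedure.
    """
    sel = TopAbundanceSelector(k=k).fit(table.counts)
    kept = [table.species_ids[j] for j in sel.support_]
    return table.select_species(kept), kept


def log_transform(table: CountTable) -> CountTable:
    """Return a copy of ``table`` with every entry x replaced by log10(x+1)."""
    if np.any(table.counts < 0):
        raise ValueError("negative entries cannot be log-transformed")
    return CountTable(
        table.sample_ids, table.species_ids, np.log10(table.counts + 1.0)
    )


def stratified_split(
    labels: LabelVector | np.ndarray,
    test_fraction: float,
    seed: int,
    table: CountTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-preserving random train/test split.

    Per class c the test count is round-half-up(n_c * test_fraction), floored
    at 1 and capped at n_c - 1 so both sides see both classes. Returns sorted
    (train_indices, test_indices); the same seed always yields the same split.
    """
    if isinstance(labels, LabelVector):
        if table is not None:
            check_paired(table, labels)
        y = labels.labels
    else:
        y = np.asarray(labels, dtype=int)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test: list[np.ndarray] = []
    train: list[np.ndarray] = []
    for c in (0, 1):
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has {len(idx)} samples; need at least 2")
        n_test = int(np.floor(len(idx) * test_fraction + 0.5))
        n_test = min(max(n_test, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))
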