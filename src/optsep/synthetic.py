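"""Synthetic two-habitat microbial communities with planted indicator species.

The generator emulates the statistical shape of a 16S-derived abundance table
from a disturbed-vs-natural habitat comparison: a small sample count with an
unbalanced class split, heavy zero inflation, overdispersed counts with a
rare high-abundance tail, and a handful of truly class-differential
("indicator") species against an exchangeable background.

Counts follow a zero-inflated negative binomial: with probability ``pi`` a
structural zero, otherwise NB(mean mu, dispersion r). Background species use
identical parameters in both habitats. An indicator species enriched in one
habitat has, in that habitat, its NB mean multiplied by ``10**effect`` and
its structural-zero probability divided by ``10**(effect / 2)`` — indicator
taxa in real surveys are both more abundant and more prevalent where they
indicate, and with ~80% structural zeros a mean-only shift would be nearly
invisible. At ``effect = 0`` an indicator column is distributed exactly like
background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import CountTable, LabelVector

__all__ = ["SyntheticSpec", "generate_community"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-indicator community generator.

    Defaults mirror the study conditions the package is designed around:
    70 samples split 41 (natural) / 29 (disturbed), 50 species after
    abundance filtering, 5 planted indicators with a one-decade abundance
    shift, and a sparse overdispersed background.
    """

    n_class0: int = 41
    n_class1: int = 29
    d: int = 50
    n_indicators: int = 5
    effect: float = 1.0           # log10 fold shift of the enriched-class mean
    zero_inflation: float = 0.8   # background structural-zero probability
    background_mean: float = 5.0  # NB mean of a background species
    dispersion: float = 0.5       # NB size parameter r (small = overdispersed)
    tail_fraction: float = 0.1    # share of background species in the
                                  # rare-high-abundance tail
    tail_scale: float = 50.0      # mean multiplier for tail species
    seed: int = 0

    def __post_init__(self):
        if self.n_class0 < 1 or self.n_class1 < 1:
            raise ValueError("both classes need at least one sample")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not 0 <= self.n_indicators <= self.d:
            raise ValueError("n_indicators must lie in [0, d]")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.background_mean <= 0 or self.dispersion <= 0:
            raise ValueError("background_mean and dispersion must be > 0")
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise ValueError("tail_fraction must lie in [0, 1]")
        if self.tail_scale < 1.0:
            raise ValueError("tail_scale must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_class0 + self.n_class1


def _zinb(rng: np.random.Generator, pi: float, mu: float, r: float, size) -> np.ndarray:
    """Zero-inflated negative binomial draws (nonnegative integers)."""
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p, size=size)
    structural = rng.random(size) < pi
    counts[structural] = 0
    return counts


def generate_community(
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[CountTable, LabelVector, list[str]]:
    """Generate (CountTable, LabelVector, planted indicator ids).

    Class 0 samples come first, then class 1; indicator species are planted
    at random columns, the first ceil(n/2) enriched in class 0 (natural) and
    the rest in class 1 (disturbed). Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.d
    labels = np.concatenate(
        [np.zeros(spec.n_class0, dtype=int), np.ones(spec.n_class1, dtype=int)]
    )
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    species_ids = [f"sp{j + 1:04d}" for j in range(d)]

    indicator_cols = np.sort(rng.choice(d, size=spec.n_indicators, replace=False))
    n_enriched0 = math.ceil(spec.n_indicators / 2)
    enriched_class = {
        int(col): (0 if k < n_enriched0 else 1)
        for k, col in enumerate(indicator_cols)
    }

    # rare high-abundance background tail (indicator columns excluded)
    background = [j for j in range(d) if j not in enriched_class]
    n_tail = int(round(spec.tail_fraction * len(background)))
    tail_cols = set(
        rng.choice(background, size=n_tail, replace=False).tolist() if n_tail else []
    )

    counts = np.zeros((n, d), dtype=int)
    fold = 10.0 ** spec.effect
    pi_enriched = min(1.0, spec.zero_inflation / (10.0 ** (spec.effect / 2.0)))
    for j in range(d):
        if j in enriched_class:
            cls = enriched_class[j]
            rows_e = labels == cls
            rows_d = ~rows_e
            counts[rows_e, j] = _zinb(
                rng, pi_enriched, spec.background_mean * fold, spec.dispersion,
                int(rows_e.sum()),
            )
            counts[rows_d, j] = _zinb(
                rng, spec.zero_inflation, spec.background_mean, spec.dispersion,
                int(rows_d.sum()),
            )
        else:
            mu = spec.background_mean * (spec.tail_scale if j in tail_cols else 1.0)
            counts[:, j] = _zinb(rng, spec.zero_inflation, mu, spec.dispersion, n)

    table = CountTable(sample_ids, species_ids, counts)
    label_vec = LabelVector(sample_ids, labels, {"natural": 0, "disturbed": 1})
    planted = [species_ids[int(j)] for j in indicator_cols]
    return table, label_vec, planted
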