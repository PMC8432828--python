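"""Reading and writing abundance tables, label files and result tables.

The on-disk formats are plain TSV/CSV: a count table is a numeric matrix with
sample identifiers on one axis and species (OTU/ASV) identifiers on the other;
a label file has two columns, sample id and habitat label. BIOM/HDF5 and
sequence-level formats are deliberately out of scope — the tool starts from a
finished count table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "LabelVector",
    "read_count_table",
    "read_labels",
    "read_frequency_table",
    "write_tables",
]


@dataclass
class CountTable:
    """A samples x species abundance matrix with identifiers.

    ``counts`` holds nonnegative reals: raw tables are integer counts, but the
    matrix becomes real-valued after the log10(x+1) transform, so no integer
    dtype is enforced.
    """

    sample_ids: list[str]
    species_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.species_ids = [str(s) for s in self.species_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d matrix")
        n, d = self.counts.shape
        if n != len(self.sample_ids) or d != len(self.species_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.species_ids)} species"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.species_ids)) != d:
            raise ValueError("duplicate species identifiers")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite entries")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative entries")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.species_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_species(self, species: Sequence[str]) -> "CountTable":
        """Restrict to the given species ids, in the given order."""
        index = {s: j for j, s in enumerate(self.species_ids)}
        missing = [s for s in species if s not in index]
        if missing:
            raise KeyError(f"unknown species ids: {missing}")
        cols = [index[s] for s in species]
        return CountTable(self.sample_ids, list(species), self.counts[:, cols])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.species_ids == other.species_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class LabelVector:
    """Binary habitat membership per sample (0 = natural, 1 = disturbed)."""

    sample_ids: list[str]
    labels: np.ndarray
    mapping: dict[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must be one value per sample id")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be in {{0,1}}, got extra values {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def align_to(self, table: CountTable) -> "LabelVector":
        """Reorder to the sample order of ``table``; error on mismatch."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in table.sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples without labels: {missing}")
        order = [index[s] for s in table.sample_ids]
        return LabelVector(table.sample_ids, self.labels[order], self.mapping)


def check_paired(table: CountTable, labels: LabelVector) -> None:
    """Validate a table/label pair: same samples, same order, both classes."""
    if table.sample_ids != labels.sample_ids:
        raise ValueError("count table and labels have different sample ids/order")
    c0, c1 = labels.class_counts()
    if c0 == 0 or c1 == 0:
        raise ValueError("both classes must be present (binary-only tool)")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(
    path: str | Path, orientation: str = "samples_as_rows"
) -> CountTable:
    """Read a TSV/CSV count matrix with an id header row and an id column.

    ``orientation`` declares the on-disk layout; the returned table always has
    samples as rows. OTU tables in the wild come both ways.
    """
    path = Path(path)
    if orientation not in ("samples_as_rows", "species_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):
        raise ValueError(f"{path}: duplicate identifiers in header")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty count table")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    if orientation == "species_as_rows":
        df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate identifiers")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundance value")
    return CountTable.from_dataframe(df)


def read_labels(
    path: str | Path, mapping: Mapping[str, int] | None = None
) -> LabelVector:
    """Read a two-column (sample id, label) file.

    Labels may be 0/1 already, or any two string values; with two strings and
    no explicit ``mapping``, the lexicographically smaller value maps to 0.
    The mapping used is recorded on the result.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns, got {df.shape[1]}")
    if df.empty:
        raise ValueError(f"{path}: no label rows")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1].astype(str).str.strip()
    distinct = sorted(raw.unique())
    if len(distinct) > 2:
        raise ValueError(
            f"{path}: {len(distinct)} distinct labels {distinct}; "
            "this is a binary-only tool"
        )
    if mapping is None:
        if set(distinct) <= {"0", "1"}:
            mapping = {"0": 0, "1": 1}
        else:
            mapping = {v: i for i, v in enumerate(distinct)}
    unknown = set(distinct) - set(mapping)
    if unknown:
        raise ValueError(f"{path}: labels {sorted(unknown)} not in mapping {mapping}")
    labels = raw.map(mapping).to_numpy(dtype=int)
    return LabelVector(sample_ids, labels, dict(mapping))


def write_tables(
    frequency, summary: Mapping, out_dir: str | Path
) -> dict[str, Path]:
    """Write the frequency ranking (TSV) and the experiment summary (JSON).

    The frequency table is sorted by descending frequency, ties broken by
    lexicographic feature id, and printed with one decimal place; full
    precision stays in memory. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    items = list(frequency.items()) if hasattr(frequency, "items") else list(frequency)
    if not items:
        raise ValueError("empty frequency table")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    freq_path = out_dir / "feature_frequency.tsv"
    with open(freq_path, "w") as fh:
        fh.write("feature_id\tfrequency_percent\n")
        for fid, pct in items:
            fh.write(f"{fid}\t{pct:.1f}\n")
    summary_path = out_dir / "experiment_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(_jsonify(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"frequency": freq_path, "summary": summary_path}


def read_frequency_table(path: str | Path) -> list[tuple[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    return list(zip(df["feature_id"], df["frequency_percent"].astype(float)))


def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
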