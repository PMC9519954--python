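"""Shared data containers for count matrices, DEG tables, gene panels and state vectors.

Conventions
-----------
* Count matrices are genes x samples (genes as rows), integer valued.
* A "DEG table" is a :class:`pandas.DataFrame` indexed by gene ID with columns
  ``logFC`` (M, log2 fold-change target vs reference), ``logCPM`` (A, average
  log2 abundance on the counts-per-million scale), ``PValue`` and ``FDR``.
* Gene symbols are matched after whitespace trimming and case folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEG_COLUMNS = ("logFC", "logCPM", "PValue", "FDR")


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped and case-folded."""
    return str(symbol).strip().casefold()


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with a condition label per sample.

    Parameters
    ----------
    counts
        DataFrame with unique gene IDs as index and unique sample IDs as
        columns; entries must be non-negative integers.
    conditions
        Series mapping every sample ID to a condition label.
    """

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dupes[:5])}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            gene = self.counts.index[np.where(values < 0)[0][0]]
            raise ValueError(f"negative count for gene {gene!r}")
        if not np.allclose(values, np.round(values)):
            gene = self.counts.index[
                np.where(~np.isclose(values, np.round(values)))[0][0]
            ]
            raise ValueError(f"non-integer count for gene {gene!r}")
        self.conditions = pd.Series(self.conditions)
        missing = self.counts.columns.difference(self.conditions.index)
        if len(missing):
            raise ValueError(f"samples without condition label: {list(missing)}")
        self.conditions = self.conditions.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.conditions.loc[list(samples)])

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.conditions)


def validate_deg_table(table: pd.DataFrame, require: Sequence[str] = ("logFC",)) -> pd.DataFrame:
    """Check that ``table`` looks like a DEG table with the required columns."""
    if table.empty:
        raise ValueError("empty DEG table")
    for col in require:
        if col not in table.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    if table.index.has_duplicates:
        raise ValueError("duplicate gene IDs in DEG table")
    return table


@dataclass
class GenePanel:
    """A named, curated gene set with per-gene vote counts.

    ``votes`` records, for every panel gene, in how many of the ``n_sources``
    input lists it appeared; for a curated panel every count lies in
    ``[min_votes, n_sources]``.
    """

    name: str
    genes: tuple
    votes: Mapping[str, int] = field(default_factory=dict)
    n_sources: int = 1
    min_votes: int = 1

    def __post_init__(self) -> None:
        genes = tuple(normalize_symbol(g) for g in self.genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"panel {self.name!r} has duplicate gene symbols")
        self.genes = genes
        self.votes = {normalize_symbol(g): int(v) for g, v in dict(self.votes).items()}
        for g in self.genes:
            v = self.votes.get(g, 1)
            if not (1 <= v <= self.n_sources):
                raise ValueError(
                    f"vote count {v} for gene {g!r} outside [1, {self.n_sources}]"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in set(self.genes)

    def as_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass
class StateChangeVector:
    """Per-gene log2 fold-changes for one transition (reference -> target).

    The vector is the object compared by the cosine/PCA geometry: each entry
    is the M value of one gene for the contrast ``reference -> target``.
    """

    values: pd.Series
    reference: str = "reference"
    target: str = "target"
    source: str = "bulk"

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs in state-change vector")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("non-finite log2 fold-change values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()
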