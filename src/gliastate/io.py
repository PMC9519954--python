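"""Readers and writers for count matrices, condition tables and DEG tables.

Counts travel either as TSV (genes as rows, header row of sample IDs) or as
MatrixMarket MTX with sidecar gene/sample name files (``<stem>.genes.txt``
and ``<stem>.samples.txt``).  Condition labels live in a two-column TSV
(sample, condition).  DEG tables are CSV with the fixed column order
``gene, logFC, logCPM, PValue, FDR``.  All numeric output uses '.' decimals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import DEG_COLUMNS, CountMatrix


def read_conditions(path) -> pd.Series:
    """Two-column TSV (sample, condition) -> Series indexed by sample."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"], dtype=str)
    if frame["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    return pd.Series(frame["condition"].to_numpy(), index=frame["sample"].to_numpy())


def write_conditions(conditions: pd.Series, path) -> None:
    with open(path, "w") as handle:
        for sample, condition in conditions.items():
            handle.write(f"{sample}\t{condition}\n")


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.samples.txt")


def read_counts(path, fmt: str | None = None, conditions=None) -> CountMatrix:
    """Read a count matrix from TSV or MTX (+ sidecar name files).

    ``fmt`` defaults to the file extension.  ``conditions`` may be a path to
    a conditions TSV or a Series; if omitted, every sample is labelled
    ``"unknown"`` (sufficient for normalization-only use).

    Raises
    ------
    ValueError
        On non-integer or negative entries (reported with the gene ID), or an
        MTX dimension mismatch with its sidecar files.
    """
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "mtx":
        genes_path, samples_path = _sidecars(path)
        for p in (genes_path, samples_path):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar name file {p}")
        genes = [line.strip() for line in open(genes_path) if line.strip()]
        samples = [line.strip() for line in open(samples_path) if line.strip()]
        matrix = spio.mmread(path)
        matrix = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
        if matrix.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MTX dimensions {matrix.shape} do not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        frame = pd.DataFrame(matrix, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    if conditions is None:
        cond = pd.Series("unknown", index=frame.columns)
    elif isinstance(conditions, (str, Path)):
        cond = read_conditions(conditions)
    else:
        cond = pd.Series(conditions)
    cm = CountMatrix(frame, cond)
    cm.counts = cm.counts.astype(np.int64)
    return cm


def write_counts(matrix: CountMatrix, path, fmt: str | None = None) -> None:
    """Write a count matrix as TSV or MTX with sidecar name files."""
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        matrix.counts.to_csv(path, sep="\t", index_label="gene")
    elif fmt == "mtx":
        genes_path, samples_path = _sidecars(path)
        spio.mmwrite(path, sparse.coo_matrix(matrix.counts.to_numpy()))
        genes_path.write_text("".join(f"{g}\n" for g in matrix.genes))
        samples_path.write_text("".join(f"{s}\n" for s in matrix.samples))
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_deg_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="gene")
    missing = [c for c in DEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: DEG table missing columns {missing}")
    return table


def write_deg_table(table: pd.DataFrame, path) -> None:
    out = table[list(DEG_COLUMNS)].copy()
    out.index.name = "gene"
    out.to_csv(path)


def read_gene_lengths(path) -> pd.Series:
    """Two-column TSV (gene, length in bases)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "length"])
    lengths = pd.Series(frame["length"].to_numpy(dtype=float), index=frame["gene"].to_numpy())
    if (lengths <= 0).any():
        raise ValueError(f"{path}: gene lengths must be positive")
    return lengths
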