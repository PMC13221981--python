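"""Typed containers and plain-text I/O for expression matrices and sample metadata.

The central container is :class:`ExpressionMatrix`, a genes-by-samples numeric
matrix with string identifiers on both axes.  The ``kind`` tag tracks where a
matrix sits in the processing pipeline (raw counts, normalized counts,
log-counts, or a low-dimensional embedding whose rows are components rather
than genes); downstream operations validate the tag instead of guessing.

Supported on-disk formats are deliberately plain text: TSV/CSV with gene ids
in the first column and sample ids in the header row, and MatrixMarket
coordinate files with one-column sidecar files (``<file>.rows`` /
``<file>.cols``) for gene and sample names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotations",
    "DistanceMatrix",
    "read_counts",
    "write_counts",
    "read_annotations",
    "align",
]

VALID_KINDS = ("counts", "normalized", "logcounts", "embedding")


def _as_str_array(ids: Sequence[str], name: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    arr = np.array([str(x) for x in arr], dtype=object)
    if len(set(arr)) != len(arr):
        dupes = pd.Series(arr).value_counts()
        dupes = list(dupes[dupes > 1].index[:5])
        raise ValueError(f"duplicate {name}: {dupes}")
    return arr


@dataclass
class ExpressionMatrix:
    """Genes-by-samples numeric matrix with identifiers.

    Parameters
    ----------
    values
        2-D array, rows are genes (or components when ``kind='embedding'``),
        columns are samples.
    gene_ids, sample_ids
        Unique string identifiers for rows and columns.
    kind
        One of ``counts``, ``normalized``, ``logcounts``, ``embedding``.
        ``counts`` requires non-negative integer entries.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    kind: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.sample_ids = _as_str_array(self.sample_ids, "sample_ids")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[1]} columns"
            )
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or infinite entries")
        if self.kind == "counts":
            if np.any(self.values < 0):
                raise ValueError("counts must be non-negative")
            if np.any(self.values != np.floor(self.values)):
                raise ValueError("counts must be integers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.gene_ids.copy(), self.sample_ids.copy(), self.kind
        )

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "ExpressionMatrix":
        """New matrix sharing identifiers, with replaced values (and optionally kind)."""
        return ExpressionMatrix(
            np.asarray(values), self.gene_ids.copy(), self.sample_ids.copy(),
            self.kind if kind is None else kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotations:
    """Per-sample batch and biological-group labels, order-aligned to a matrix."""

    sample_ids: np.ndarray
    batch: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_array(self.sample_ids, "sample_ids")
        self.batch = np.array([str(x) for x in np.asarray(self.batch)], dtype=object)
        self.group = np.array([str(x) for x in np.asarray(self.group)], dtype=object)
        n = len(self.sample_ids)
        if len(self.batch) != n or len(self.group) != n:
            raise ValueError("batch/group labels must match sample_ids in length")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def batch_levels(self) -> list[str]:
        return sorted(set(self.batch))

    @property
    def group_levels(self) -> list[str]:
        return sorted(set(self.group))

    def copy(self) -> "SampleAnnotations":
        return SampleAnnotations(
            self.sample_ids.copy(), self.batch.copy(), self.group.copy()
        )

    def subset(self, idx: np.ndarray) -> "SampleAnnotations":
        return SampleAnnotations(
            self.sample_ids[idx], self.batch[idx], self.group[idx]
        )

    def validate_for_benchmark(self) -> None:
        """Benchmarking needs at least two batches and two biological groups."""
        if len(self.batch_levels) < 2:
            raise ValueError("need >=2 distinct batch labels, got "
                             f"{self.batch_levels}")
        if len(self.group_levels) < 2:
            raise ValueError("need >=2 distinct group labels, got "
                             f"{self.group_levels}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample-distance matrix with zero diagonal."""

    values: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _as_str_array(self.sample_ids, "sample_ids")
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square and match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        # enforce exactness so symmetry survives round-trips
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix == "csv":
        return "csv"
    if suffix == "mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_counts(path: str | Path, format: str | None = None,
                transpose: bool = False) -> ExpressionMatrix:
    """Read a count matrix from TSV/CSV or MatrixMarket.

    TSV/CSV: first column gene ids, header row sample ids.  MTX: standard
    coordinate format, with ``<file>.rows`` and ``<file>.cols`` sidecar files
    holding one gene/sample name per line.

    Set ``transpose=True`` when the file stores samples in rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, format)
    if fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        if df.shape[1] == 0:
            raise ValueError(f"{path}: no sample columns found")
        values = df.to_numpy()
        gene_ids, sample_ids = df.index.astype(str), df.columns.astype(str)
    elif fmt == "mtx":
        rows_file = path.with_name(path.name + ".rows")
        cols_file = path.with_name(path.name + ".cols")
        for f in (rows_file, cols_file):
            if not f.exists():
                raise FileNotFoundError(
                    f"sidecar label file {f} not found next to {path.name}")
        mat = spio.mmread(path)
        values = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        gene_ids = rows_file.read_text().split()
        sample_ids = cols_file.read_text().split()
        if len(gene_ids) != values.shape[0] or len(sample_ids) != values.shape[1]:
            raise ValueError(
                f"label files ({len(gene_ids)} rows, {len(sample_ids)} cols) do not "
                f"match matrix shape {values.shape}")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        values = values.T
        gene_ids, sample_ids = sample_ids, gene_ids
    if not np.issubdtype(np.asarray(values).dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in count matrix")
    return ExpressionMatrix(values, np.asarray(gene_ids), np.asarray(sample_ids),
                            kind="counts")


def write_counts(matrix: ExpressionMatrix, path: str | Path,
                 format: str | None = None) -> None:
    """Write a matrix in any supported format (lossless for integer counts)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("tsv", "csv"):
        df = matrix.to_frame()
        if matrix.kind == "counts":
            df = df.astype(np.int64)
        df.to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        vals = matrix.values
        if matrix.kind == "counts":
            vals = vals.astype(np.int64)
        spio.mmwrite(path, sparse.coo_matrix(vals))
        path.with_name(path.name + ".rows").write_text(
            "\n".join(matrix.gene_ids) + "\n")
        path.with_name(path.name + ".cols").write_text(
            "\n".join(matrix.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_annotations(path: str | Path, batch_col: str, group_col: str,
                     sample_col: str | None = None,
                     format: str | None = None) -> SampleAnnotations:
    """Read per-sample batch/group labels from a TSV/CSV metadata table.

    ``sample_col`` names the sample-id column; by default the first column is
    used.  Label order is preserved as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, format)
    if fmt not in ("tsv", "csv"):
        raise ValueError("metadata must be TSV or CSV")
    df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty metadata table")
    if sample_col is None:
        sample_col = df.columns[0]
    for col in (sample_col, batch_col, group_col):
        if col not in df.columns:
            raise KeyError(
                f"column {col!r} not in metadata; available: {list(df.columns)}")
    return SampleAnnotations(
        df[sample_col].astype(str).to_numpy(),
        df[batch_col].astype(str).to_numpy(),
        df[group_col].astype(str).to_numpy(),
    )


def align(matrix: ExpressionMatrix,
          ann: SampleAnnotations) -> tuple[ExpressionMatrix, SampleAnnotations]:
    """Restrict matrix and annotations to shared samples, in matrix order.

    Sample-id matching is exact, case-sensitive string equality.  A warning is
    issued when samples are dropped from either side; disjoint id sets raise.
    """
    mat_ids = list(matrix.sample_ids)
    ann_index = {s: i for i, s in enumerate(ann.sample_ids)}
    shared = [s for s in mat_ids if s in ann_index]
    if not shared:
        raise ValueError("no shared sample ids between matrix and annotations")
    n_drop_mat = matrix.n_samples - len(shared)
    n_drop_ann = ann.n_samples - len(shared)
    if n_drop_mat or n_drop_ann:
        warnings.warn(
            f"align dropped {n_drop_mat} matrix sample(s) and "
            f"{n_drop_ann} annotation row(s) not present on both sides",
            UserWarning, stacklevel=2)
    mat_pos = {s: i for i, s in enumerate(mat_ids)}
    mcols = np.array([mat_pos[s] for s in shared], dtype=int)
    acols = np.array([ann_index[s] for s in shared], dtype=int)
    new_mat = ExpressionMatrix(
        matrix.values[:, mcols], matrix.gene_ids.copy(),
        matrix.sample_ids[mcols], matrix.kind)
    return new_mat, ann.subset(acols)
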