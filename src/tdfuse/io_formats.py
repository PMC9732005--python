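"""Readers, writers and in-memory containers for expression data.

The pipeline touches three on-disk representations:

* dense delimited matrices (TSV/CSV; header row = sample ids, first
  column = gene ids) for bulk studies,
* MatrixMarket coordinate bundles (``matrix.mtx`` + ``features`` +
  ``barcodes``, plain or gzipped) for single-cell measurements,
* a delimited gene table for selection results.

Gene identifiers are treated as opaque strings throughout: the studies
this package integrates mix Ensembl IDs and symbols, and mapping between
namespaces is deliberately left to the caller.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "ExpressionTensor",
    "ScrnaBundle",
    "ParseError",
    "read_dense_matrix",
    "write_dense_matrix",
    "read_mtx_bundle",
    "write_gene_table",
    "read_gene_table",
]


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """One study's genes x samples expression values.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``. ``labels``, when present, carries one categorical
    class label per sample (used only by the association screen).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        n, m = self.values.shape
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise ValueError("identifier lengths do not match values shape")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ParseError(f"duplicate gene identifiers: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.labels is not None and len(self.labels) != m:
            raise ValueError("labels length does not match sample count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionTensor:
    """A study laid out as genes x condition-mode-1 x ... x condition-mode-S.

    The first axis is always genes; the remaining ``S >= 1`` axes index
    experimental conditions (drug, dose, replicate, ...). ``mode_labels``
    optionally annotates each condition mode with per-level labels.
    """

    gene_ids: list[str]
    values: np.ndarray
    mode_labels: list[list[str]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim < 2:
            raise ValueError("tensor must have at least one condition mode")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match first axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def mode_sizes(self) -> tuple[int, ...]:
        return self.values.shape[1:]

    @property
    def n_condition_modes(self) -> int:
        return self.values.ndim - 1


@dataclass
class ScrnaBundle:
    """A single-cell measurement: sparse genes x cells counts.

    ``measurement_id`` indexes the measurement within a collection;
    ``group`` is its categorical annotation (e.g. disease x region).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.spmatrix
    measurement_id: int = 0
    group: str | None = None

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            raise ValueError("counts must be a scipy sparse matrix")
        self.counts = self.counts.tocsc()
        n, m = self.counts.shape
        if len(self.gene_ids) != n:
            raise ParseError(
                f"feature list length {len(self.gene_ids)} does not match "
                f"matrix rows {n}"
            )
        if len(self.cell_ids) != m:
            raise ParseError(
                f"barcode list length {len(self.cell_ids)} does not match "
                f"matrix columns {m}"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def to_dense(self) -> ExpressionMatrix:
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.cell_ids),
            values=np.asarray(self.counts.todense(), dtype=float),
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_dense_matrix(
    path: str | Path,
    orientation: str = "genes-in-rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Parameters
    ----------
    path:
        Delimited text file with one header row and one identifier column.
    orientation:
        ``"genes-in-rows"`` (default) or ``"genes-in-columns"``. The
        returned matrix is always genes x samples.
    delimiter:
        Explicit field separator; by default inferred from the extension
        (``.csv`` -> comma, anything else -> tab).
    """
    path = Path(path)
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows/columns")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(dt) for dt in df.dtypes]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ParseError(
            f"{path}: non-numeric value at row {row!r}, column {col!r}"
        )
    if orientation == "genes-in-columns":
        df = df.T
    gene_ids = [str(g) for g in df.index]
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ParseError(
            f"{path}: duplicate gene identifiers: {sorted(dupes)[:5]}"
        )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_dense_matrix(
    X: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write genes-in-rows delimited text (inverse of :func:`read_dense_matrix`)."""
    path = Path(path)
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.to_csv(path, sep=_sep_for(path, delimiter))


_FEATURE_NAMES = ("features.tsv", "genes.tsv", "features.txt", "genes.txt")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.txt")
_MATRIX_NAMES = ("matrix.mtx",)


def _find_member(directory: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        for cand in (directory / name, directory / (name + ".gz")):
            if cand.exists():
                return cand
    raise ParseError(f"{directory}: none of {names} (plain or .gz) found")


def _read_id_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx_bundle(
    directory: str | Path, measurement_id: int = 0, group: str | None = None
) -> ScrnaBundle:
    """Read a MatrixMarket bundle (matrix + features + barcodes).

    Members may be plain or gzip-compressed; sparsity is preserved.
    """
    directory = Path(directory)
    mtx_path = _find_member(directory, _MATRIX_NAMES)
    opener = gzip.open if mtx_path.suffix == ".gz" else open
    with opener(mtx_path, "rb") as fh:
        counts = scipy.io.mmread(fh)
    counts = sp.csc_matrix(counts)
    gene_ids = _read_id_column(_find_member(directory, _FEATURE_NAMES))
    cell_ids = _read_id_column(_find_member(directory, _BARCODE_NAMES))
    return ScrnaBundle(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=counts,
        measurement_id=measurement_id,
        group=group,
    )


def write_mtx_bundle(bundle: ScrnaBundle, directory: str | Path) -> None:
    """Write a bundle in MatrixMarket layout (uncompressed members)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(bundle.counts))
    (directory / "features.tsv").write_text(
        "".join(g + "\n" for g in bundle.gene_ids)
    )
    (directory / "barcodes.tsv").write_text(
        "".join(b + "\n" for b in bundle.cell_ids)
    )


def write_gene_table(selection, path: str | Path) -> None:
    """Write a gene-selection result as TSV.

    Columns: gene_id, statistic, P, adjusted P, selected flag. Rows are
    ordered by adjusted P ascending with gene_id as the tie-break, so the
    output is deterministic.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "gene_id": selection.gene_ids,
            "statistic": selection.statistic,
            "p_value": selection.p_values,
            "adj_p_value": selection.adj_p_values,
            "selected": selection.selected.astype(int),
        }
    )
    df = df.sort_values(["adj_p_value", "gene_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_gene_table`."""
    return pd.read_csv(path, sep="\t")
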