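"""Labeled compressed sparse row (CSR) matrices of genomes x features.

A pan-genome screen maps each genome to a row and each feature — a Pfam
domain accession, or a whole domain-architecture string — to a column.  With
thousands of genomes and thousands of features the dense matrix is almost
entirely zeros, so it is stored compressed:

1. *Coordinate transformation*: enumerate only the nonzero cells as parallel
   (row, column, value) vectors, abolishing the zeros.
2. *Row compression*: replace the sorted row vector by adjacent pairs of
   index pointers ``P`` of length ``n_rows + 1``, where ``P[i]:P[i+1]``
   slices row *i* out of the column and value vectors.

Memory is then proportional to the number of nonzeros, so matrices at the
100,000-genome scale fit in local RAM.  Both count matrices (cell = number of
occurrences of the feature in the genome) and binary presence/absence
matrices are supported; the binary form is derived from counts at load time
without densifying.

The on-disk artifact is a *matrix folder*: a small JSON metadata file, three
flat little-endian int64 array files (index pointers, column indices,
values), newline-delimited row/column label files, and — when built with the
keep option — a protein-id store mapping (genome, feature) cells back to the
protein accessions that produced them.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import DomatrixError, MatrixFormatError
from .hmmer_io import DomainHit, GenomeManifest, hits_by_protein, parse_domain_hits

__all__ = [
    "CooTriples",
    "LabeledCSR",
    "dense_to_coo",
    "compress_rows",
    "build_count_matrix",
    "build_domain_matrix",
    "build_architecture_matrix",
    "domain_features",
    "architecture_features",
    "binarize",
    "save_matrix",
    "load_matrix",
    "load_binary_matrix",
]

FORMAT_VERSION = 1
_META_NAME = "matrix.json"
_INDPTR_NAME = "indptr.bin"
_INDICES_NAME = "indices.bin"
_VALUES_NAME = "values.bin"
_ROWS_NAME = "rows.txt"
_COLS_NAME = "cols.txt"
_STORE_NAME = "protein_ids.tsv"
_KEEP_NAME = "keep.tsv"


@dataclass(frozen=True)
class CooTriples:
    """Sparse matrix in coordinate form: nonzero cells only, row-major sorted."""

    row: np.ndarray
    col: np.ndarray
    val: np.ndarray
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if not (len(self.row) == len(self.col) == len(self.val)):
            raise DomatrixError("COO vectors must have equal length")

    @property
    def nnz(self) -> int:
        return len(self.val)


def dense_to_coo(dense) -> CooTriples:
    """Convert a dense nonnegative integer matrix to coordinate form.

    Scans in row-major order and keeps exactly the nonzero cells, so the
    resulting triples are sorted by (row, column) with no duplicates.
    """
    dense = np.asarray(dense)
    if dense.ndim != 2:
        raise DomatrixError(f"expected a 2-d matrix, got {dense.ndim}-d")
    if dense.size and dense.min() < 0:
        raise DomatrixError("matrix values must be nonnegative")
    row, col = np.nonzero(dense)  # row-major: sorted by (row, col)
    return CooTriples(
        row=row.astype(np.int64),
        col=col.astype(np.int64),
        val=dense[row, col].astype(np.int64),
        n_rows=dense.shape[0],
        n_cols=dense.shape[1],
    )


def compress_rows(row: Sequence[int] | np.ndarray, n_rows: int) -> np.ndarray:
    """Compress a sorted row vector into index pointers.

    ``P[i+1] - P[i]`` is the multiplicity of row ``i``; ``P`` has length
    ``n_rows + 1`` with ``P[0] == 0`` and ``P[n_rows] == len(row)``.
    """
    row = np.asarray(row, dtype=np.int64)
    if row.size:
        if row.min() < 0 or row.max() >= n_rows:
            raise DomatrixError("row index out of range")
        if np.any(np.diff(row) < 0):
            raise DomatrixError("row vector must be sorted ascending")
    indptr = np.zeros(n_rows + 1, dtype=np.int64)
    np.cumsum(np.bincount(row, minlength=n_rows), out=indptr[1:])
    return indptr


@dataclass
class LabeledCSR:
    """A CSR matrix with genome row labels and feature column labels.

    ``indptr``/``indices``/``values`` are int64; within each row slice the
    column indices are strictly increasing.  ``mode`` records whether columns
    are Pfam domains or architecture strings.  ``protein_store``, if present,
    is the (genome_id, feature, protein_id) association table written by a
    keep-mode build.
    """

    indptr: np.ndarray
    indices: np.ndarray
    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    is_binary: bool = False
    mode: str | None = None  # "domain" | "architecture" | None
    protein_store: "object | None" = field(default=None, repr=False)  # pandas.DataFrame

    def __post_init__(self) -> None:
        self.indptr = np.asarray(self.indptr, dtype=np.int64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.int64)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_rows, n_cols = self.shape
        if len(self.indptr) != n_rows + 1 or self.indptr[0] != 0:
            raise MatrixFormatError("index pointers must start at 0 with length n_rows+1")
        if np.any(np.diff(self.indptr) < 0):
            raise MatrixFormatError("index pointers must be nondecreasing")
        if self.indptr[-1] != len(self.indices) or len(self.indices) != len(self.values):
            raise MatrixFormatError("index pointer terminus must equal nnz")
        if len(self.indices) and (self.indices.min() < 0 or self.indices.max() >= n_cols):
            raise MatrixFormatError("column index out of range")
        for i in range(n_rows):
            sl = self.indices[self.indptr[i] : self.indptr[i + 1]]
            if np.any(np.diff(sl) <= 0):
                raise MatrixFormatError(f"row {i}: column indices not strictly increasing")
        if np.any(self.values == 0):
            raise MatrixFormatError("stored values must be nonzero")
        if self.is_binary and np.any(self.values != 1):
            raise MatrixFormatError("binary matrix must store only 1s")
        if len(set(self.row_labels)) != n_rows or len(set(self.col_labels)) != n_cols:
            raise MatrixFormatError("row/column labels must be unique")

    # -- basic accessors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return len(self.row_labels), len(self.col_labels)

    @property
    def nnz(self) -> int:
        return len(self.values)

    def to_dense(self) -> np.ndarray:
        """Densify (small matrices / tests only)."""
        dense = np.zeros(self.shape, dtype=np.int64)
        for i in range(self.shape[0]):
            sl = slice(self.indptr[i], self.indptr[i + 1])
            dense[i, self.indices[sl]] = self.values[sl]
        return dense

    # -- query layer (Table-style utilities; see analysis module) --------
    def get_rows(self) -> list[str]:
        return list(self.row_labels)

    def get_columns(self) -> list[str]:
        return list(self.col_labels)

    def sum_rows(self, list_row=None, list_col=None):
        from . import analysis

        return analysis.sum_rows(self, list_row, list_col)

    def sum_columns(self, list_row=None, list_col=None):
        from . import analysis

        return analysis.sum_columns(self, list_row, list_col)

    def cal_core(self, list_row=None, list_col=None, cutoff: float = 0.95):
        from . import analysis

        return analysis.cal_core(self, list_row, list_col, cutoff)

    def get_protein_ids(self, list_row=None, list_col=None, output=None):
        from . import analysis

        return analysis.get_protein_ids(self, list_row, list_col, output)


# ---------------------------------------------------------------------------
# building


def domain_features(hits: Iterable[DomainHit]) -> list[tuple[str, str]]:
    """Domain mode: one (protein, accession) pair per hit (repeats counted)."""
    return [(h.protein_id, h.domain_accession) for h in hits]


def architecture_features(hits: Iterable[DomainHit]) -> list[tuple[str, str]]:
    """Architecture mode: one (protein, architecture string) pair per protein."""
    from .architectures import architectures_for_genome

    return [(a.protein_id, a.architecture) for a in architectures_for_genome(hits)]


def build_count_matrix(
    manifest: GenomeManifest,
    feature_fn: Callable[[list[DomainHit]], list[tuple[str, str]]],
    *,
    max_i_evalue: float | None = None,
    keep: bool = False,
    mode: str | None = None,
    progress: Callable[[str], None] | None = None,
) -> LabeledCSR:
    """Stream the manifest into a labeled CSR count matrix.

    Rows follow manifest order.  Columns are all distinct features observed
    across genomes, in first-seen order during the sweep, which keeps the
    build single-pass and deterministic for a fixed manifest.  Cell (g, f) is
    the number of occurrences of feature f in genome g.  Only per-genome
    (column, count) pairs are accumulated — no dense intermediate exists.

    ``feature_fn`` maps a genome's hit list to (protein_id, feature) pairs;
    with ``keep`` the pairs also populate the protein-id store.
    """
    col_index: dict[str, int] = {}
    row_cols: list[np.ndarray] = []
    row_vals: list[np.ndarray] = []
    store_records: list[tuple[str, str, str]] = []

    for genome_id, path in manifest:
        try:
            hits = parse_domain_hits(path, max_i_evalue=max_i_evalue)
        except (OSError, DomatrixError) as exc:
            raise DomatrixError(f"genome {genome_id!r}: {exc}") from exc
        counts: dict[int, int] = {}
        for protein_id, feat in feature_fn(hits):
            j = col_index.setdefault(feat, len(col_index))
            counts[j] = counts.get(j, 0) + 1
            if keep:
                store_records.append((genome_id, feat, protein_id))
        cols = np.sort(np.fromiter(counts.keys(), dtype=np.int64, count=len(counts)))
        row_cols.append(cols)
        row_vals.append(np.array([counts[int(j)] for j in cols], dtype=np.int64))
        if progress is not None:
            progress(genome_id)

    lengths = np.array([len(c) for c in row_cols], dtype=np.int64)
    indptr = np.zeros(len(manifest) + 1, dtype=np.int64)
    np.cumsum(lengths, out=indptr[1:])
    indices = (
        np.concatenate(row_cols) if row_cols else np.empty(0, dtype=np.int64)
    )
    values = np.concatenate(row_vals) if row_vals else np.empty(0, dtype=np.int64)

    matrix = LabeledCSR(
        indptr=indptr,
        indices=indices,
        values=values,
        row_labels=list(manifest.genome_ids),
        col_labels=list(col_index),
        is_binary=False,
        mode=mode,
    )
    if keep:
        import pandas as pd

        matrix.protein_store = (
            pd.DataFrame(store_records, columns=["genome_id", "feature", "protein_id"])
            .drop_duplicates()
            .sort_values(["genome_id", "feature", "protein_id"], kind="stable")
            .reset_index(drop=True)
        )
    return matrix


def build_domain_matrix(manifest: GenomeManifest, **kwargs) -> LabeledCSR:
    """Genome x Pfam-domain count matrix (cell = total domain-hit count)."""
    return build_count_matrix(manifest, domain_features, mode="domain", **kwargs)


def build_architecture_matrix(manifest: GenomeManifest, **kwargs) -> LabeledCSR:
    """Genome x architecture count matrix (cell = proteins with that string)."""
    return build_count_matrix(manifest, architecture_features, mode="architecture", **kwargs)


# ---------------------------------------------------------------------------
# binarization


def binarize(m: LabeledCSR) -> LabeledCSR:
    """Presence/absence view: same sparsity pattern and labels, all values 1."""
    return replace(
        m,
        indptr=m.indptr.copy(),
        indices=m.indices.copy(),
        values=np.ones_like(m.values),
        row_labels=list(m.row_labels),
        col_labels=list(m.col_labels),
        is_binary=True,
    )


# ---------------------------------------------------------------------------
# matrix folder serialization


def save_matrix(
    m: LabeledCSR,
    folder: str | Path,
    *,
    overwrite: bool = False,
    keep_records=None,
) -> Path:
    """Write a matrix folder.

    The layout is deterministic for fixed content (no timestamps): JSON
    metadata, three flat little-endian int64 array files, newline-delimited
    UTF-8 label files, and optionally the protein-id store plus the raw keep
    TSV of (genome_id, protein_id, feature) rows in build order.
    """
    folder = Path(folder)
    if folder.exists() and (folder / _META_NAME).exists() and not overwrite:
        raise MatrixFormatError(f"{folder} already contains a matrix folder (use overwrite)")
    folder.mkdir(parents=True, exist_ok=True)

    meta = {
        "format_version": FORMAT_VERSION,
        "n_rows": m.shape[0],
        "n_cols": m.shape[1],
        "nnz": m.nnz,
        "is_binary": m.is_binary,
        "mode": m.mode,
        "has_protein_store": m.protein_store is not None,
    }
    (folder / _META_NAME).write_text(json.dumps(meta, sort_keys=True, indent=0) + "\n")
    m.indptr.astype("<i8").tofile(folder / _INDPTR_NAME)
    m.indices.astype("<i8").tofile(folder / _INDICES_NAME)
    m.values.astype("<i8").tofile(folder / _VALUES_NAME)
    _write_labels(folder / _ROWS_NAME, m.row_labels)
    _write_labels(folder / _COLS_NAME, m.col_labels)
    if m.protein_store is not None:
        m.protein_store.to_csv(folder / _STORE_NAME, sep="\t", header=False, index=False)
    if keep_records is not None:
        with open(folder / _KEEP_NAME, "w", encoding="utf-8") as fh:
            for genome_id, protein_id, feat in keep_records:
                fh.write(f"{genome_id}\t{protein_id}\t{feat}\n")
    return folder


def _write_labels(path: Path, labels: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for label in labels:
            fh.write(label + "\n")


def _read_labels(path: Path) -> list[str]:
    text = path.read_text(encoding="utf-8")
    return text.splitlines()


def _require(folder: Path, name: str) -> Path:
    path = folder / name
    if not path.exists():
        raise MatrixFormatError(f"matrix folder {folder} is missing {name}")
    return path


def load_matrix(folder: str | Path) -> LabeledCSR:
    """Load a matrix folder as saved, count values included.

    Raises :class:`MatrixFormatError` on a missing component file, an unknown
    format version, or arrays inconsistent with the recorded shape.
    """
    folder = Path(folder)
    meta_path = _require(folder, _META_NAME)
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise MatrixFormatError(f"corrupt metadata in {meta_path}: {exc}") from None
    if meta.get("format_version") != FORMAT_VERSION:
        raise MatrixFormatError(
            f"unknown matrix folder format version {meta.get('format_version')!r}"
        )
    indptr = np.fromfile(_require(folder, _INDPTR_NAME), dtype="<i8")
    indices = np.fromfile(_require(folder, _INDICES_NAME), dtype="<i8")
    values = np.fromfile(_require(folder, _VALUES_NAME), dtype="<i8")
    row_labels = _read_labels(_require(folder, _ROWS_NAME))
    col_labels = _read_labels(_require(folder, _COLS_NAME))
    if len(row_labels) != meta["n_rows"] or len(col_labels) != meta["n_cols"]:
        raise MatrixFormatError(f"label files inconsistent with metadata in {folder}")
    if len(values) != meta["nnz"]:
        raise MatrixFormatError(f"value file inconsistent with metadata in {folder}")
    matrix = LabeledCSR(
        indptr=indptr,
        indices=indices,
        values=values,
        row_labels=row_labels,
        col_labels=col_labels,
        is_binary=bool(meta["is_binary"]),
        mode=meta.get("mode"),
    )
    if meta.get("has_protein_store"):
        import pandas as pd

        store_path = _require(folder, _STORE_NAME)
        matrix.protein_store = pd.read_csv(
            store_path,
            sep="\t",
            header=None,
            names=["genome_id", "feature", "protein_id"],
            dtype=str,
            keep_default_na=False,
        )
    return matrix


def load_binary_matrix(folder: str | Path) -> LabeledCSR:
    """Load the presence/absence view of a matrix folder (never densifies)."""
    return binarize(load_matrix(folder))


def remove_matrix_folder(folder: str | Path) -> None:
    """Delete a (possibly partial) matrix folder; used for build cleanup."""
    shutil.rmtree(folder, ignore_errors=True)
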