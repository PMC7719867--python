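"""Query layer over a loaded :class:`~domatrix.sparse_matrix.LabeledCSR`.

Everything here runs directly on the compressed arrays — index pointers,
column indices, values — without densifying, so queries stay O(nnz) and work
at pan-genome scale:

* ``sum_rows`` / ``sum_columns``: per-genome and per-feature totals of the
  stored values (counts, or presence 0/1 on a binary matrix) restricted to
  requested genome/feature subsets.
* ``cal_core``: the core-feature calculation — which features are present in
  at least a cutoff fraction (default 95%, inclusive) of the queried
  genomes.  Requires the binary matrix so "present twice" cannot count
  double.
* ``get_protein_ids``: map queried (genome, feature) cells back to the
  protein accessions that produced them, via the keep-mode store.
"""

from __future__ import annotations

from decimal import Decimal, InvalidOperation
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomatrixError, LabelError, ProteinStoreError
from .sparse_matrix import LabeledCSR

__all__ = [
    "get_rows",
    "get_columns",
    "sum_rows",
    "sum_columns",
    "cal_core",
    "get_protein_ids",
]


def get_rows(m: LabeledCSR) -> list[str]:
    """All genome (row) labels, in matrix order."""
    return m.get_rows()


def get_columns(m: LabeledCSR) -> list[str]:
    """All feature (column) labels, in matrix order."""
    return m.get_columns()


def _resolve(labels: Sequence[str] | None, index: dict[str, int], kind: str) -> np.ndarray:
    if labels is None:
        return np.arange(len(index), dtype=np.int64)
    out = np.empty(len(labels), dtype=np.int64)
    for k, label in enumerate(labels):
        try:
            out[k] = index[label]
        except KeyError:
            raise LabelError(f"unknown {kind} label: {label!r}") from None
    return out


def _row_index(m: LabeledCSR) -> dict[str, int]:
    return {g: i for i, g in enumerate(m.row_labels)}


def _col_index(m: LabeledCSR) -> dict[str, int]:
    return {f: j for j, f in enumerate(m.col_labels)}


def _masked_entries(m: LabeledCSR, rows: np.ndarray, cols: np.ndarray):
    """Return (row-of-entry, col-of-entry, value) for entries in the subset."""
    entry_row = np.repeat(np.arange(m.shape[0], dtype=np.int64), np.diff(m.indptr))
    row_mask = np.zeros(m.shape[0], dtype=bool)
    row_mask[rows] = True
    col_mask = np.zeros(m.shape[1], dtype=bool)
    col_mask[cols] = True
    keep = row_mask[entry_row] & col_mask[m.indices]
    return entry_row[keep], m.indices[keep], m.values[keep]


def sum_rows(
    m: LabeledCSR,
    list_row: Sequence[str] | None = None,
    list_col: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Row-wise summation: total stored value per requested genome.

    On a binary matrix this is the number of requested features present in
    each genome; on a count matrix, the total occurrence count.  Returns a
    frame with columns ``row_name``, ``row_sum`` in ``list_row`` order.
    """
    rows = _resolve(list_row, _row_index(m), "genome")
    cols = _resolve(list_col, _col_index(m), "feature")
    entry_row, _, vals = _masked_entries(m, rows, cols)
    per_row = np.bincount(entry_row, weights=vals, minlength=m.shape[0]).astype(np.int64)
    names = list_row if list_row is not None else m.row_labels
    return pd.DataFrame({"row_name": list(names), "row_sum": per_row[rows]})


def sum_columns(
    m: LabeledCSR,
    list_row: Sequence[str] | None = None,
    list_col: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Column-wise summation: total stored value per requested feature.

    On a binary matrix this is the number of requested genomes carrying each
    feature.  Returns a frame with columns ``col_name``, ``col_sum`` in
    ``list_col`` order.
    """
    rows = _resolve(list_row, _row_index(m), "genome")
    cols = _resolve(list_col, _col_index(m), "feature")
    _, entry_col, vals = _masked_entries(m, rows, cols)
    per_col = np.bincount(entry_col, weights=vals, minlength=m.shape[1]).astype(np.int64)
    names = list_col if list_col is not None else m.col_labels
    return pd.DataFrame({"col_name": list(names), "col_sum": per_col[cols]})


def _cutoff_fraction(cutoff: float) -> Fraction:
    # Interpret the cutoff as the decimal the user wrote (0.95 means 19/20
    # exactly), not its binary-float image, so the 95% boundary is inclusive.
    try:
        return Fraction(Decimal(str(cutoff)))
    except (InvalidOperation, ValueError):
        raise DomatrixError(f"invalid cutoff: {cutoff!r}") from None


def cal_core(
    m: LabeledCSR,
    list_row: Sequence[str] | None = None,
    list_col: Sequence[str] | None = None,
    cutoff: float = 0.95,
) -> pd.DataFrame:
    """Core features: presence fraction over the queried genomes >= cutoff.

    The matrix must be binary (load the presence/absence view first); a count
    matrix is refused rather than silently thresholded.  The comparison is
    exact-rational and inclusive: a feature in exactly 19 of 20 queried
    genomes survives the default 95% cutoff.  Fractions use the size of
    ``list_row`` as the denominator, so genomes with zero hits still count.

    Returns a frame with columns ``col_name``, ``genome_count``, ``fraction``
    containing only the retained features, in ``list_col`` order.
    """
    if not m.is_binary:
        raise DomatrixError(
            "cal_core requires a binary matrix; use load_binary_matrix or binarize first"
        )
    cut = _cutoff_fraction(cutoff)
    if not 0 <= cut <= 1:
        raise DomatrixError(f"cutoff must be in [0, 1], got {cutoff}")
    rows = _resolve(list_row, _row_index(m), "genome")
    if len(rows) == 0:
        raise DomatrixError("cal_core: empty genome list (conservation fraction undefined)")
    cols = _resolve(list_col, _col_index(m), "feature")
    _, entry_col, vals = _masked_entries(m, rows, cols)
    per_col = np.bincount(entry_col, weights=vals, minlength=m.shape[1]).astype(np.int64)
    denom = len(rows)
    counts = per_col[cols]
    keep = np.array([Fraction(int(c), denom) >= cut for c in counts], dtype=bool)
    names = list_col if list_col is not None else m.col_labels
    kept_names = [names[k] for k in np.nonzero(keep)[0]]
    kept_counts = counts[keep]
    return pd.DataFrame(
        {
            "col_name": kept_names,
            "genome_count": kept_counts,
            "fraction": kept_counts / denom,
        }
    )


def get_protein_ids(
    m: LabeledCSR,
    list_row: Sequence[str] | None = None,
    list_col: Sequence[str] | None = None,
    output: str | Path | None = None,
) -> pd.DataFrame:
    """Protein ids behind the queried (genome, feature) cells.

    Requires the protein-id store (matrix built with the keep option).  Rows
    are (genome_id, feature, protein_id), restricted to the query lists and
    sorted lexicographically; written as a headerless 3-column TSV when
    ``output`` is given.
    """
    if m.protein_store is None:
        raise ProteinStoreError(
            "no protein-id store in this matrix folder; rebuild with the keep option (-k)"
        )
    # Validate labels against the matrix even though the store drives the join.
    _resolve(list_row, _row_index(m), "genome")
    _resolve(list_col, _col_index(m), "feature")
    store = m.protein_store
    mask = np.ones(len(store), dtype=bool)
    if list_row is not None:
        mask &= store["genome_id"].isin(set(list_row)).to_numpy()
    if list_col is not None:
        mask &= store["feature"].isin(set(list_col)).to_numpy()
    report = (
        store.loc[mask]
        .sort_values(["genome_id", "feature", "protein_id"], kind="stable")
        .reset_index(drop=True)
    )
    if output is not None:
        report.to_csv(output, sep="\t", header=False, index=False)
    return report
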