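"""CSR construction, compression, binarization, and folder serialization."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from domatrix import (
    DomainHit,
    LabeledCSR,
    binarize,
    build_architecture_matrix,
    build_domain_matrix,
    compress_rows,
    dense_to_coo,
    load_binary_matrix,
    load_matrix,
    read_manifest,
    save_matrix,
)
from domatrix.errors import DomatrixError, MatrixFormatError
from domatrix.fixtures import TCDB_ARCHITECTURE, _sequential_hits, write_domtblout

dense_matrices = hnp.arrays(
    np.int64,
    st.tuples(st.integers(0, 50), st.integers(0, 80)),
    elements=st.integers(0, 5),
)


def _write_fixture_manifest(tmp_path, genome_hits):
    """genome_hits: dict genome_id -> list[DomainHit]; returns a manifest."""
    lines = []
    for genome_id, hits in genome_hits.items():
        p = tmp_path / f"{genome_id}.domtbl"
        write_domtblout(p, hits)
        lines.append(f"{genome_id}\t{p}")
    mp = tmp_path / "manifest.tsv"
    mp.write_text("\n".join(lines) + ("\n" if lines else ""))
    return read_manifest(mp)


class TestDenseToCoo:
    def test_all_zero_matrix_has_empty_triples(self):
        coo = dense_to_coo(np.zeros((3, 4), dtype=int))
        assert coo.nnz == 0 and (coo.n_rows, coo.n_cols) == (3, 4)

    def test_row_major_enumeration(self):
        coo = dense_to_coo([[0, 3], [1, 0]])
        assert coo.row.tolist() == [0, 1]
        assert coo.col.tolist() == [1, 0]
        assert coo.val.tolist() == [3, 1]

    def test_identity_matrix(self):
        coo = dense_to_coo(np.eye(3, dtype=int))
        assert coo.row.tolist() == [0, 1, 2]
        assert coo.col.tolist() == [0, 1, 2]
        assert coo.val.tolist() == [1, 1, 1]

    def test_negative_values_rejected(self):
        with pytest.raises(DomatrixError):
            dense_to_coo([[-1, 0]])


class TestCompressRows:
    @pytest.mark.parametrize(
        "row, n_rows, expected",
        [
            ([0, 0, 1, 3], 4, [0, 2, 3, 3, 4]),
            ([], 3, [0, 0, 0, 0]),
            ([0, 1, 2], 3, [0, 1, 2, 3]),
        ],
    )
    def test_examples(self, row, n_rows, expected):
        assert compress_rows(row, n_rows).tolist() == expected

    def test_unsorted_or_out_of_range_rejected(self):
        with pytest.raises(DomatrixError):
            compress_rows([1, 0], 2)
        with pytest.raises(DomatrixError):
            compress_rows([5], 3)

    @given(st.lists(st.integers(0, 9), max_size=60), st.integers(10, 12))
    def test_pointer_gaps_equal_row_multiplicities(self, rows, n_rows):
        rows = sorted(rows)
        indptr = compress_rows(rows, n_rows)
        # brute-force histogram oracle
        for i in range(n_rows):
            assert indptr[i + 1] - indptr[i] == rows.count(i)
        assert indptr[0] == 0 and indptr[-1] == len(rows)


class TestCsrIdentity:
    @given(dense_matrices)
    def test_coo_compress_reconstruct_is_identity(self, dense):
        coo = dense_to_coo(dense)
        indptr = compress_rows(coo.row, coo.n_rows)
        # independent reconstruction through scipy's CSR
        rebuilt = sp.csr_matrix(
            (coo.val, coo.col, indptr), shape=(coo.n_rows, coo.n_cols)
        ).toarray()
        assert np.array_equal(rebuilt, dense)
        assert indptr[-1] == np.count_nonzero(dense)  # nnz conservation

    @given(dense_matrices)
    def test_arrays_match_scipy_csr_conversion(self, dense):
        coo = dense_to_coo(dense)
        indptr = compress_rows(coo.row, coo.n_rows)
        ref = sp.csr_matrix(dense)
        assert np.array_equal(indptr, ref.indptr)
        assert np.array_equal(coo.col, ref.indices)
        assert np.array_equal(coo.val, ref.data)


class TestBuildCountMatrix:
    def test_domain_tally(self, tmp_path):
        manifest = _write_fixture_manifest(
            tmp_path,
            {
                "g1": _sequential_hits("g1_p1", ["PF00001", "PF00001", "PF00002"]),
                "g2": _sequential_hits("g2_p1", ["PF00002", "PF00002"])
                + _sequential_hits("g2_p2", ["PF00002"]),
            },
        )
        m = build_domain_matrix(manifest)
        assert m.get_rows() == ["g1", "g2"]
        assert m.get_columns() == ["PF00001", "PF00002"]  # first-seen order
        assert m.to_dense().tolist() == [[2, 1], [0, 3]]

    def test_zero_hit_genome_keeps_its_row(self, tmp_path):
        manifest = _write_fixture_manifest(
            tmp_path,
            {"g1": _sequential_hits("p", ["PF00001"]), "g2": []},
        )
        m = build_domain_matrix(manifest)
        assert m.shape == (2, 1)
        assert m.to_dense().tolist() == [[1], [0]]
        assert m.indptr.tolist() == [0, 1, 1]  # flat pointer across the empty row

    def test_architecture_mode_single_tcdb_protein(self, tmp_path):
        manifest = _write_fixture_manifest(
            tmp_path, {"g1": _sequential_hits("p", TCDB_ARCHITECTURE.split("_"))}
        )
        m = build_architecture_matrix(manifest)
        assert m.shape == (1, 1)
        assert m.get_columns() == [TCDB_ARCHITECTURE]
        assert m.to_dense().tolist() == [[1]]

    def test_unreadable_hit_file_names_the_genome(self, tmp_path):
        mp = tmp_path / "manifest.tsv"
        mp.write_text(f"gX\t{tmp_path / 'missing.domtbl'}\n")
        with pytest.raises(DomatrixError, match="gX"):
            build_domain_matrix(read_manifest(mp))


class TestBinarize:
    def test_counts_become_ones(self):
        coo = dense_to_coo([[2, 0], [0, 3]])
        m = LabeledCSR(
            compress_rows(coo.row, 2), coo.col, coo.val, ["g1", "g2"], ["a", "b"]
        )
        b = binarize(m)
        assert b.is_binary and b.to_dense().tolist() == [[1, 0], [0, 1]]
        assert not m.is_binary  # original untouched

    def test_idempotent_and_empty(self):
        m = LabeledCSR(np.zeros(1, dtype=int), [], [], [], [])
        assert binarize(binarize(m)).to_dense().shape == (0, 0)
        coo = dense_to_coo([[5]])
        m2 = LabeledCSR(compress_rows(coo.row, 1), coo.col, coo.val, ["g"], ["f"])
        assert np.array_equal(binarize(binarize(m2)).values, binarize(m2).values)


class TestFolderRoundtrip:
    def test_roundtrip_field_by_field(self, tmp_path, small_fixture):
        manifest, _ = small_fixture
        m = build_domain_matrix(manifest, keep=True)
        save_matrix(m, tmp_path / "fol")
        loaded = load_matrix(tmp_path / "fol")
        assert np.array_equal(loaded.indptr, m.indptr)
        assert np.array_equal(loaded.indices, m.indices)
        assert np.array_equal(loaded.values, m.values)
        assert loaded.row_labels == m.row_labels
        assert loaded.col_labels == m.col_labels
        assert loaded.is_binary == m.is_binary and loaded.mode == m.mode
        assert loaded.protein_store.equals(m.protein_store)

    def test_binary_load_equals_binarize_of_load(self, tmp_path, small_fixture):
        manifest, _ = small_fixture
        save_matrix(build_domain_matrix(manifest), tmp_path / "fol")
        b = load_binary_matrix(tmp_path / "fol")
        ref = binarize(load_matrix(tmp_path / "fol"))
        assert b.is_binary and np.array_equal(b.to_dense(), ref.to_dense())

    def test_empty_matrix_roundtrip(self, tmp_path):
        m = LabeledCSR(np.zeros(1, dtype=int), [], [], [], [])
        save_matrix(m, tmp_path / "fol")
        loaded = load_matrix(tmp_path / "fol")
        assert loaded.shape == (0, 0) and loaded.nnz == 0

    def test_missing_column_index_is_a_load_error(self, tmp_path):
        m = LabeledCSR(np.zeros(1, dtype=int), [], [], [], [])
        save_matrix(m, tmp_path / "fol")
        (tmp_path / "fol" / "cols.txt").unlink()
        with pytest.raises(MatrixFormatError, match="cols.txt"):
            load_matrix(tmp_path / "fol")

    def test_unknown_format_version_rejected(self, tmp_path):
        m = LabeledCSR(np.zeros(1, dtype=int), [], [], [], [])
        save_matrix(m, tmp_path / "fol")
        meta = tmp_path / "fol" / "matrix.json"
        meta.write_text(meta.read_text().replace('"format_version": 1', '"format_version": 99'))
        with pytest.raises(MatrixFormatError, match="version"):
            load_matrix(tmp_path / "fol")

    def test_overwrite_protection(self, tmp_path):
        m = LabeledCSR(np.zeros(1, dtype=int), [], [], [], [])
        save_matrix(m, tmp_path / "fol")
        with pytest.raises(MatrixFormatError, match="overwrite"):
            save_matrix(m, tmp_path / "fol")
        save_matrix(m, tmp_path / "fol", overwrite=True)  # no error
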