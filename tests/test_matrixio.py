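"""matrix_io: data model, round-trips, and balancing."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from loopdelta.errors import ConvergenceError, FormatError, ValidationError
from loopdelta.matrixio import (
    BinTable,
    ContactMatrix,
    Loop,
    PeakSet,
    balance,
    coarsen,
    read_bedgraph,
    read_bedpe,
    read_matrix,
    read_narrowpeak,
    write_bedgraph,
    write_bedpe,
    write_matrix,
    write_narrowpeak,
)


def make_matrix(dense, bin_size=10_000, chrom="chr1"):
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    bins = BinTable.from_chromsizes({chrom: n * bin_size}, bin_size)
    return ContactMatrix(bins, sp.csr_matrix(dense), bin_size)


class TestBinTable:
    def test_tiling(self):
        bt = BinTable.from_chromsizes({"chr1": 95_000}, 10_000)
        assert bt.n_bins == 10
        assert bt.ends[-1] == 95_000  # short last bin allowed

    def test_gap_rejected(self):
        with pytest.raises(ValidationError):
            BinTable(("chr1", "chr1"), np.array([0, 20_000]), np.array([10_000, 30_000]), 10_000)

    def test_bin_of(self):
        bt = BinTable.from_chromsizes({"chr1": 100_000, "chr2": 50_000}, 10_000)
        assert bt.bin_of("chr1", 0) == 0
        assert bt.bin_of("chr2", 15_000) == 11
        with pytest.raises(ValidationError):
            bt.bin_of("chr2", 60_000)


class TestMatrixRoundTrip:
    def test_write_read_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        dense = rng.integers(0, 20, size=(10, 10))
        dense = np.triu(dense) + np.triu(dense, 1).T
        m = make_matrix(dense)
        write_matrix(m, tmp_path / "bins.tsv", tmp_path / "coo.tsv")
        m2 = read_matrix(tmp_path / "bins.tsv", tmp_path / "coo.tsv")
        assert (m.counts != m2.counts).nnz == 0
        assert m2.bins.same_as(m.bins)

    def test_duplicate_pair_error(self, tmp_path):
        bins = BinTable.from_chromsizes({"chr1": 100_000}, 10_000)
        pd.DataFrame(
            {"chrom": bins.chroms, "start": bins.starts, "end": bins.ends,
             "bin_id": range(10)}
        ).to_csv(tmp_path / "bins.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"bin1_id": [2, 5], "bin2_id": [5, 2], "count": [3, 4]}
        ).to_csv(tmp_path / "coo.tsv", sep="\t", index=False)
        with pytest.raises(FormatError, match="duplicate"):
            read_matrix(tmp_path / "bins.tsv", tmp_path / "coo.tsv")

    def test_empty_coo_is_zero_matrix(self, tmp_path):
        m = make_matrix(np.zeros((5, 5)))
        write_matrix(m, tmp_path / "b.tsv", tmp_path / "c.tsv")
        m2 = read_matrix(tmp_path / "b.tsv", tmp_path / "c.tsv")
        assert m2.counts.nnz == 0

    def test_out_of_range_bin_id(self, tmp_path):
        m = make_matrix(np.eye(4))
        write_matrix(m, tmp_path / "b.tsv", tmp_path / "c.tsv")
        with open(tmp_path / "c.tsv", "a") as fh:
            fh.write("2\t99\t1\n")
        with pytest.raises(FormatError, match="out-of-range"):
            read_matrix(tmp_path / "b.tsv", tmp_path / "c.tsv")

    def test_non_integer_count(self, tmp_path):
        m = make_matrix(np.eye(4))
        write_matrix(m, tmp_path / "b.tsv", tmp_path / "c.tsv")
        with open(tmp_path / "c.tsv", "a") as fh:
            fh.write("1\t2\t1.5\n")
        with pytest.raises(FormatError, match="non-integer"):
            read_matrix(tmp_path / "b.tsv", tmp_path / "c.tsv")

    def test_lower_triangle_folded(self, tmp_path):
        bins = BinTable.from_chromsizes({"chr1": 100_000}, 10_000)
        pd.DataFrame(
            {"chrom": bins.chroms, "start": bins.starts, "end": bins.ends,
             "bin_id": range(10)}
        ).to_csv(tmp_path / "bins.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"bin1_id": [7], "bin2_id": [3], "count": [5]}
        ).to_csv(tmp_path / "coo.tsv", sep="\t", index=False)
        m = read_matrix(tmp_path / "bins.tsv", tmp_path / "coo.tsv")
        assert m.counts[3, 7] == 5
        assert m.counts[7, 3] == 5


class TestBedpe:
    def test_anchor_separation(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t100000\t110000\tchr1\t400000\t410000\n")
        loops = read_bedpe(p)
        assert len(loops) == 1
        assert loops[0].length == 300_000

    def test_roundtrip_with_extra_columns(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t0\t10000\tchr1\t50000\t60000\tname1\t0.5\n")
        loops = read_bedpe(p)
        assert loops[0].extra == ("name1", "0.5")
        out = tmp_path / "out.bedpe"
        write_bedpe(loops, out)
        assert out.read_text() == p.read_text()

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text("chr1\t0\t10000\tchr1\t50000\n")
        with pytest.raises(FormatError):
            read_bedpe(p)

    def test_interchromosomal_rejected(self):
        with pytest.raises(ValidationError):
            Loop("chr1", 0, 10_000, "chr2", 0, 10_000)

    def test_anchor_ordering_normalized(self):
        lp = Loop("chr1", 50_000, 60_000, "chr1", 0, 10_000)
        assert lp.start1 == 0 and lp.start2 == 50_000

    def test_snap_misaligned(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t100001\t110000\tchr1\t400000\t410000\n")
        loops = read_bedpe(p, resolution=10_000)
        assert loops[0].start1 == 100_000
        p.write_text("chr1\t100500\t110000\tchr1\t400000\t410000\n")
        with pytest.raises(ValidationError, match="misaligned"):
            read_bedpe(p, resolution=10_000)


class TestNarrowPeak:
    def test_nine_columns_rejected(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t0\t100\tpk\t0\t.\t1.0\t2.0\t3.0\n")
        with pytest.raises(FormatError, match="10 columns"):
            read_narrowpeak(p)

    def test_roundtrip(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t100\t500\tpk1\t850\t.\t12.5\t5.0\t3.0\t200\n")
        peaks = read_narrowpeak(p)
        assert len(peaks) == 1
        out = tmp_path / "out.narrowPeak"
        write_narrowpeak(peaks, out)
        assert read_narrowpeak(out).frame.equals(peaks.frame)

    def test_summit_validated(self):
        frame = pd.DataFrame(
            [["chr1", 0, 100, "p", 0, ".", 1.0, 1.0, 1.0, 150]],
            columns=list(PeakSet.COLUMNS),
        )
        with pytest.raises(ValidationError):
            PeakSet(frame)


class TestBedgraph:
    def test_roundtrip(self, tmp_path):
        track = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 10_000, 20_000],
                "end": [10_000, 20_000, 30_000],
                "value": [0.125, -1.5, 3.0],
            }
        )
        p = tmp_path / "t.bedgraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p)
        np.testing.assert_allclose(back["value"], track["value"], rtol=1e-5)


class TestBalance:
    def test_constant_matrix_uniform_weights(self):
        dense = np.full((8, 8), 5.0)
        m = balance(make_matrix(dense))
        w = m.weights
        assert np.allclose(w, w[0])
        rows = m.balanced_dense().sum(axis=1)
        assert np.allclose(rows, rows[0], rtol=1e-4)

    def test_zero_row_masked(self):
        dense = np.full((8, 8), 5.0)
        dense[3, :] = 0
        dense[:, 3] = 0
        m = balance(make_matrix(dense))
        assert np.isnan(m.weights[3])
        rows = np.nansum(m.balanced_dense(), axis=1)
        keep = ~np.isnan(m.weights)
        assert np.allclose(rows[keep], 1.0, atol=1e-3)

    def test_against_fixed_point_oracle(self):
        # independent Sinkhorn-Knopp run to 10x tighter tolerance
        rng = np.random.default_rng(3)
        dense = rng.uniform(1.0, 10.0, size=(6, 6))
        dense = (dense + dense.T) / 2
        m = balance(make_matrix(dense), tol=1e-7)

        a = dense.copy()
        x = np.ones(6)
        for _ in range(100_000):
            s = x * (a @ x)
            if np.abs(s / s.mean() - 1).max() < 1e-8:
                break
            x /= np.sqrt(s / s.mean())
        x /= np.sqrt((x * (a @ x)).mean())
        oracle = np.outer(x, x) * a
        np.testing.assert_allclose(
            m.balanced_dense().sum(axis=1), oracle.sum(axis=1), rtol=1e-5
        )

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        dense = rng.uniform(1, 10, (10, 10))
        dense = dense + dense.T
        m = balance(make_matrix(dense), tol=1e-8, mad_max=np.inf)
        m2 = balance(make_matrix(m.balanced_dense()), tol=1e-6, mad_max=np.inf)
        assert np.allclose(m2.weights, m2.weights[0], rtol=1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        dense = rng.uniform(1, 10, (10, 10))
        dense = dense + dense.T
        m1 = balance(make_matrix(dense), tol=1e-8)
        m2 = balance(make_matrix(4.0 * dense), tol=1e-8)
        np.testing.assert_allclose(m2.weights, m1.weights / 2.0, rtol=1e-4)
        np.testing.assert_allclose(
            m2.balanced_dense(), m1.balanced_dense(), rtol=1e-4
        )

    def test_mad_max_masks_outlier(self):
        rng = np.random.default_rng(11)
        dense = rng.uniform(4.0, 6.0, (12, 12))
        dense = dense + dense.T
        dense[0, :] *= 100
        dense[:, 0] *= 100
        m = balance(make_matrix(dense), mad_max=5)
        assert np.isnan(m.weights[0])
        assert not np.isnan(m.weights[1:]).any()

    def test_convergence_error(self):
        dense = np.full((6, 6), 5.0)
        with pytest.raises(ConvergenceError):
            balance(make_matrix(dense), max_iter=0)


class TestCoarsen:
    def test_counts_conserved(self, small_matrix):
        c = coarsen(
            ContactMatrix(small_matrix.bins, small_matrix.counts, small_matrix.resolution_bp),
            10,
        )
        assert c.counts.sum() == small_matrix.counts.sum()
        assert c.resolution_bp == 10 * small_matrix.resolution_bp
        assert c.bins.n_bins == -(-small_matrix.bins.n_bins // 10)

    def test_block_sum(self):
        dense = np.arange(16, dtype=float).reshape(4, 4)
        dense = dense + dense.T
        m = make_matrix(dense)
        c = coarsen(m, 2)
        expected = dense.reshape(2, 2, 2, 2).sum(axis=(1, 3))
        np.testing.assert_allclose(np.asarray(c.counts.todense()), expected)


@settings(max_examples=25, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=30), min_size=36, max_size=36)
)
def test_balance_rows_uniform_property(values):
    dense = np.array(values, dtype=float).reshape(6, 6)
    dense = dense + dense.T + 1.0  # strictly positive, symmetric
    m = balance(make_matrix(dense), tol=1e-7, max_iter=2000)
    rows = np.nansum(m.balanced_dense(), axis=1)
    keep = ~np.isnan(m.weights)
    assert np.allclose(rows[keep], 1.0, atol=1e-4)
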