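"""Contact-matrix data model, standard-format I/O, and matrix balancing.

The canonical on-disk matrix representation is a pair of TSV files: a bin
table (chrom, start, end, bin_id) and a sparse upper-triangle COO listing
(bin1_id, bin2_id, count).  All genomic coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConvergenceError, FormatError, ValidationError

__all__ = [
    "BinTable",
    "ContactMatrix",
    "Loop",
    "PeakSet",
    "read_matrix",
    "write_matrix",
    "read_bedpe",
    "write_bedpe",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_genes",
    "write_genes",
    "read_bedgraph",
    "write_bedgraph",
    "balance",
    "coarsen",
]


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinTable:
    """Uniform genomic bins tiling one or more chromosomes.

    Bin ids are consecutive integers in table order.  Bins tile each
    chromosome without gaps or overlaps; every bin has the same width except
    possibly the last bin of each chromosome.
    """

    chroms: tuple[str, ...]
    starts: np.ndarray
    ends: np.ndarray
    bin_size: int

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if len(self.chroms) != len(starts) or len(starts) != len(ends):
            raise ValidationError("bin table columns have unequal lengths")
        if np.any(ends <= starts):
            raise ValidationError("bin with start >= end")
        # per-chromosome tiling check
        for chrom in dict.fromkeys(self.chroms):
            idx = [i for i, c in enumerate(self.chroms) if c == chrom]
            s, e = starts[idx], ends[idx]
            if s[0] != 0:
                raise ValidationError(f"{chrom}: first bin does not start at 0")
            if np.any(s[1:] != e[:-1]):
                raise ValidationError(f"{chrom}: bins have gaps or overlaps")
            widths = e - s
            if np.any(widths[:-1] != self.bin_size):
                raise ValidationError(f"{chrom}: ragged bins (non-uniform width)")
            if widths[-1] > self.bin_size:
                raise ValidationError(f"{chrom}: last bin wider than bin size")

    @classmethod
    def from_chromsizes(cls, chromsizes: dict[str, int], bin_size: int) -> "BinTable":
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        for chrom, length in chromsizes.items():
            edges = list(range(0, length, bin_size)) + [length]
            for s, e in zip(edges[:-1], edges[1:]):
                chroms.append(chrom)
                starts.append(s)
                ends.append(e)
        return cls(tuple(chroms), np.array(starts), np.array(ends), bin_size)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def chrom_names(self) -> list[str]:
        return list(dict.fromkeys(self.chroms))

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous bin-id range of one chromosome."""
        idx = np.flatnonzero(np.asarray(self.chroms, dtype=object) == chrom)
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin id containing a genomic position."""
        sl = self.chrom_slice(chrom)
        i = sl.start + int(pos) // self.bin_size
        if i >= sl.stop or pos < 0:
            raise ValidationError(f"position {chrom}:{pos} outside binned genome")
        return i

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": list(self.chroms),
                "start": self.starts,
                "end": self.ends,
                "bin_id": np.arange(self.n_bins),
            }
        )

    def same_as(self, other: "BinTable") -> bool:
        return (
            self.chroms == other.chroms
            and self.bin_size == other.bin_size
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact matrix.

    ``counts`` is a full symmetric sparse matrix over all bins; ``weights``
    are per-bin balancing weights (NaN = masked), present only after
    :func:`balance` has run.
    """

    bins: BinTable
    counts: sp.csr_matrix
    resolution_bp: int
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (self.bins.n_bins, self.bins.n_bins):
            raise ValidationError("count matrix shape does not match bin table")

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the bin is masked (no weight)."""
        if self.weights is None:
            return np.zeros(self.bins.n_bins, dtype=bool)
        return np.isnan(self.weights)

    def balanced_dense(self) -> np.ndarray:
        """Dense balanced matrix w_i * w_j * c_ij with NaN on masked bins."""
        if self.weights is None:
            raise ValidationError("matrix is not balanced")
        dense = np.asarray(self.counts.todense(), dtype=float)
        w = self.weights
        out = dense * w[:, None] * w[None, :]
        return out

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)


@dataclass
class Loop:
    """An anchor-bin pair with optional significance statistics."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    raw_count: float | None = None
    expected: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    score: float | None = None
    diff_class: str = "untested"
    extra: tuple = ()

    def __post_init__(self) -> None:
        if self.chrom1 != self.chrom2:
            raise ValidationError(
                f"inter-chromosomal loop rejected: {self.chrom1} vs {self.chrom2}"
            )
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValidationError("loop anchor with start >= end")
        if (self.start2, self.end2) < (self.start1, self.end1):
            # keep anchor1 upstream
            self.start1, self.start2 = self.start2, self.start1
            self.end1, self.end2 = self.end2, self.end1

    @property
    def length(self) -> int:
        return self.start2 - self.start1


@dataclass
class PeakSet:
    """ENCODE narrowPeak intervals."""

    frame: pd.DataFrame

    COLUMNS = (
        "chrom",
        "start",
        "end",
        "name",
        "score",
        "strand",
        "signal",
        "p",
        "q",
        "summit_offset",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"narrowPeak frame missing columns: {sorted(missing)}")
        if (self.frame["start"] >= self.frame["end"]).any():
            raise ValidationError("peak interval with start >= end")
        widths = self.frame["end"] - self.frame["start"]
        bad = (self.frame["summit_offset"] < -1) | (
            self.frame["summit_offset"] >= widths
        )
        if bad.any():
            raise ValidationError("summit offset outside peak interval")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------

def write_matrix(matrix: ContactMatrix, bin_table_path, coo_path) -> None:
    """Write bin table and upper-triangle COO TSVs."""
    matrix.bins.to_frame().to_csv(bin_table_path, sep="\t", index=False)
    coo = sp.triu(matrix.counts, k=0).tocoo()
    order = np.lexsort((coo.col, coo.row))
    df = pd.DataFrame(
        {
            "bin1_id": coo.row[order],
            "bin2_id": coo.col[order],
            "count": coo.data[order],
        }
    )
    if np.allclose(df["count"], np.round(df["count"])):
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(coo_path, sep="\t", index=False)


def read_matrix(bin_table_path, coo_path, weights: np.ndarray | None = None) -> ContactMatrix:
    """Read the canonical bin-table + COO representation.

    Lower-triangle entries are folded to the upper triangle; a pair present
    as both (i, j) and (j, i) — or listed twice — is a format error.
    """
    bins_df = pd.read_csv(bin_table_path, sep="\t")
    for col in ("chrom", "start", "end", "bin_id"):
        if col not in bins_df.columns:
            raise FormatError(f"bin table missing column {col!r}")
    if not np.array_equal(bins_df["bin_id"].to_numpy(), np.arange(len(bins_df))):
        raise FormatError("bin ids are not consecutive from 0")
    widths = (bins_df["end"] - bins_df["start"]).to_numpy()
    bin_size = int(widths.max()) if len(widths) else 0
    bins = BinTable(
        tuple(bins_df["chrom"].astype(str)),
        bins_df["start"].to_numpy(),
        bins_df["end"].to_numpy(),
        bin_size,
    )

    coo = pd.read_csv(coo_path, sep="\t")
    for col in ("bin1_id", "bin2_id", "count"):
        if col not in coo.columns:
            raise FormatError(f"COO file missing column {col!r}")
    n = bins.n_bins
    b1 = coo["bin1_id"].to_numpy()
    b2 = coo["bin2_id"].to_numpy()
    cnt = coo["count"].to_numpy()
    if len(b1) and (not np.issubdtype(cnt.dtype, np.number) or np.any(cnt != np.round(cnt))):
        bad = int(np.flatnonzero(cnt != np.round(cnt))[0]) + 2
        raise FormatError(f"non-integer count at line {bad}")
    oob = (b1 < 0) | (b1 >= n) | (b2 < 0) | (b2 >= n)
    if oob.any():
        bad = int(np.flatnonzero(oob)[0]) + 2
        raise FormatError(f"out-of-range bin id at line {bad}")
    # fold to upper triangle
    lo = np.minimum(b1, b2)
    hi = np.maximum(b1, b2)
    keys = lo.astype(np.int64) * n + hi
    uniq, counts = np.unique(keys, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise FormatError(
            f"duplicate pair ({dup // n}, {dup % n}) after folding to upper triangle"
        )
    chrom_arr = np.asarray(bins.chroms, dtype=object)
    if len(lo) and np.any(chrom_arr[lo] != chrom_arr[hi]):
        bad = int(np.flatnonzero(chrom_arr[lo] != chrom_arr[hi])[0]) + 2
        raise FormatError(f"inter-chromosomal pair rejected at line {bad}")
    upper = sp.coo_matrix((cnt.astype(float), (lo, hi)), shape=(n, n)).tocsr()
    full = upper + sp.triu(upper, k=1).T
    return ContactMatrix(bins, full.tocsr(), bins.bin_size, weights=weights)


# ---------------------------------------------------------------------------
# Interval-format I/O
# ---------------------------------------------------------------------------

def _snap(value: int, resolution: int | None) -> int:
    if resolution is None:
        return value
    rem = value % resolution
    if rem == 0:
        return value
    if rem <= 1:
        return value - rem
    if resolution - rem <= 1:
        return value + (resolution - rem)
    raise ValidationError(
        f"coordinate {value} misaligned with resolution {resolution} by more than 1 bp"
    )


def read_bedpe(path, resolution: int | None = None) -> list[Loop]:
    """Read loops from BEDPE (>= 6 columns); extra columns kept opaquely.

    If ``resolution`` is given, anchor coordinates are snapped to the grid
    with an error when misaligned by more than 1 bp.
    """
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
            try:
                c1, s1, e1, c2, s2, e2 = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    int(fields[4]),
                    int(fields[5]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            loops.append(
                Loop(
                    c1,
                    _snap(s1, resolution),
                    _snap(e1, resolution),
                    c2,
                    _snap(s2, resolution),
                    _snap(e2, resolution),
                    extra=tuple(fields[6:]),
                )
            )
    return loops


def write_bedpe(loops: Iterable[Loop], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fields = [
                lp.chrom1,
                str(lp.start1),
                str(lp.end1),
                lp.chrom2,
                str(lp.start2),
                str(lp.end2),
            ]
            fields.extend(str(x) for x in lp.extra)
            fh.write("\t".join(fields) + "\n")


def read_narrowpeak(path) -> PeakSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: narrowPeak needs exactly 10 columns, got {len(fields)}"
                )
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                    "name": fields[3],
                    "score": int(fields[4]),
                    "strand": fields[5],
                    "signal": float(fields[6]),
                    "p": float(fields[7]),
                    "q": float(fields[8]),
                    "summit_offset": int(fields[9]),
                }
            )
    frame = pd.DataFrame(
        rows, columns=list(PeakSet.COLUMNS)
    )
    return PeakSet(frame)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    peaks.frame.loc[:, list(PeakSet.COLUMNS)].to_csv(
        path, sep="\t", header=False, index=False
    )


GENE_COLUMNS = ("chrom", "tss", "strand", "gene_id", "logFC", "logCPM", "FDR")


def read_genes(path) -> pd.DataFrame:
    """Read the gene/DE table (TSV with header); extra columns pass through."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gene table missing columns: {sorted(missing)}")
    return df


def write_genes(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    if df.isna().any().any():
        raise FormatError(f"{path}: bedGraph needs exactly 4 columns")
    if (df["start"] >= df["end"]).any():
        raise ValidationError("bedGraph interval with start >= end")
    return df


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write a (chrom, start, end, value) frame as bedGraph, skipping NaNs."""
    out = track.dropna(subset=["value"])
    out.to_csv(path, sep="\t", header=False, index=False,
               columns=["chrom", "start", "end", "value"], float_format="%.6g")


# ---------------------------------------------------------------------------
# Balancing (iterative correction)
# ---------------------------------------------------------------------------

def balance(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mad_max: float = 5.0,
) -> ContactMatrix:
    """Iterative-correction balancing.

    Bins whose coverage deviates from the median by more than ``mad_max``
    median absolute deviations (or with zero coverage) are masked before
    iteration.  On return, ``weights`` satisfy: the balanced matrix
    w_i * w_j * c_ij has uniform nonmasked row sums, normalized to mean 1.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    counts = matrix.counts.astype(float)
    if (abs(counts - counts.T) > 1e-9 * (abs(counts).max() or 1)).nnz:
        raise ValidationError("matrix is not symmetric")
    n = matrix.bins.n_bins
    coverage = np.asarray(counts.sum(axis=1)).ravel()
    masked = coverage == 0
    nz = coverage[~masked]
    if nz.size:
        med = np.median(nz)
        mad = np.median(np.abs(nz - med))
        if mad > 0:
            masked |= np.abs(coverage - med) > mad_max * mad
    keep = ~masked
    if not keep.any():
        raise ConvergenceError("all bins masked; nothing to balance")

    sub = counts[keep][:, keep]
    m = int(keep.sum())
    x = np.ones(m)
    residual = np.inf
    for _ in range(max_iter):
        s = x * (sub @ x)
        mean_s = s.mean()
        if mean_s == 0:
            raise ConvergenceError("zero total signal among nonmasked bins")
        rel = s / mean_s
        residual = float(np.abs(rel - 1.0).max())
        if residual < tol:
            break
        x /= np.sqrt(np.where(rel > 0, rel, 1.0))
    else:
        raise ConvergenceError(
            f"balancing did not converge in {max_iter} iterations "
            f"(residual {residual:.3g} > tol {tol:.3g})"
        )
    # normalize so the mean nonmasked row sum of the balanced matrix is 1
    s = x * (sub @ x)
    x /= np.sqrt(s.mean())
    weights = np.full(n, np.nan)
    weights[keep] = x
    return ContactMatrix(matrix.bins, matrix.counts, matrix.resolution_bp, weights=weights)


# ---------------------------------------------------------------------------
# Coarsening
# ---------------------------------------------------------------------------

def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum counts into bins ``factor`` times wider (per chromosome).

    Balancing weights are dropped; re-balance at the new resolution.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return ContactMatrix(matrix.bins, matrix.counts.copy(), matrix.resolution_bp)
    bins = matrix.bins
    new_size = bins.bin_size * factor
    # map old bin -> new bin, per chromosome
    mapping = np.empty(bins.n_bins, dtype=np.int64)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    offset = 0
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        n_old = sl.stop - sl.start
        n_new = -(-n_old // factor)
        local = np.arange(n_old) // factor
        mapping[sl] = offset + local
        chrom_len = int(bins.ends[sl.stop - 1])
        for j in range(n_new):
            chroms.append(chrom)
            starts.append(j * new_size)
            ends.append(min((j + 1) * new_size, chrom_len))
        offset += n_new
    new_bins = BinTable(tuple(chroms), np.array(starts), np.array(ends), new_size)
    coo = matrix.counts.tocoo()
    new_counts = sp.coo_matrix(
        (coo.data, (mapping[coo.row], mapping[coo.col])),
        shape=(new_bins.n_bins, new_bins.n_bins),
    ).tocsr()
    new_counts.sum_duplicates()
    return ContactMatrix(new_bins, new_counts, new_size)
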