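"""Insulation scores, boundary calling, aggregate-TAD maps, and
cross-sample insulation similarity/PCA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import AlignmentError, StateError
from .matrixio import BinTable, ContactMatrix

__all__ = [
    "InsulationTrack",
    "TadSet",
    "insulation_score",
    "call_boundaries",
    "tads_from_boundaries",
    "aggregate_tad",
    "insulation_similarity",
    "insulation_pca",
]


@dataclass
class InsulationTrack:
    """log2 diamond-mean insulation per bin; NaN where undefined."""

    bins: BinTable
    score: np.ndarray
    window_bp: int

    def to_bedgraph_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": list(self.bins.chroms),
                "start": self.bins.starts,
                "end": self.bins.ends,
                "value": self.score,
            }
        )


@dataclass
class TadSet:
    """Non-overlapping domains derived from insulation boundaries."""

    intervals: pd.DataFrame  # chrom, start, end (bp)
    boundaries: dict[str, np.ndarray]  # chrom -> chromosome-local boundary bins

    def __len__(self) -> int:
        return len(self.intervals)


def insulation_score(matrix: ContactMatrix, window_bp: int = 100_000) -> InsulationTrack:
    """Crane-style diamond insulation.

    score[i] = log2( diamond mean at i / chromosome mean of diamond means ),
    where the w x w diamond spans bins (i-w..i-1) x (i..i+w-1).  Scores are
    defined only where the full diamond fits inside the chromosome and at
    least half its cells involve nonmasked bins.
    """
    if not matrix.is_balanced:
        raise StateError("insulation_score requires a balanced matrix")
    res = matrix.resolution_bp
    if window_bp % res != 0:
        raise ValueError("window_bp must be a multiple of the matrix resolution")
    w = window_bp // res
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    bal = matrix.balanced_dense()
    mask = matrix.mask
    score = np.full(matrix.bins.n_bins, np.nan)
    for chrom in matrix.bins.chrom_names:
        sl = matrix.bins.chrom_slice(chrom)
        sub = bal[sl, sl].copy()
        m = mask[sl.start : sl.stop]
        sub[m, :] = np.nan
        sub[:, m] = np.nan
        n = sub.shape[0]
        means = np.full(n, np.nan)
        for i in range(w, n - w + 1):
            diamond = sub[i - w : i, i : i + w]
            defined = ~np.isnan(diamond)
            if defined.sum() < diamond.size / 2:
                continue
            means[i] = diamond[defined].mean()
        ok = ~np.isnan(means) & (means > 0)
        if ok.any():
            chrom_mean = means[ok].mean()
            vals = np.full(n, np.nan)
            vals[ok] = np.log2(means[ok] / chrom_mean)
            score[sl] = vals
    return InsulationTrack(matrix.bins, score, window_bp)


def call_boundaries(
    track: InsulationTrack,
    min_prominence: float = 0.2,
    max_score: float | None = -0.5,
) -> dict[str, np.ndarray]:
    """Local insulation minima with prominence >= min_prominence.

    Minima closer than the insulation window keep only the deeper one.  A
    minimum additionally has to lie at least |max_score| log2 units below
    the chromosome mean (set ``max_score=None`` to disable), which rejects
    shallow noise dips inside large domains.  Returns chromosome-local bin
    indices per chromosome.
    """
    w = track.window_bp // track.bins.bin_size
    out: dict[str, np.ndarray] = {}
    for chrom in track.bins.chrom_names:
        sl = track.bins.chrom_slice(chrom)
        s = track.score[sl]
        filled = np.where(np.isnan(s), np.nanmax(s) if np.isfinite(np.nanmax(s)) else 0.0, s)
        peaks, _ = find_peaks(-filled, prominence=min_prominence, distance=w)
        peaks = peaks[~np.isnan(s[peaks])]
        if max_score is not None:
            peaks = peaks[s[peaks] <= max_score]
        out[chrom] = peaks.astype(np.int64)
    if all(v.size == 0 for v in out.values()):
        warnings.warn("no insulation boundaries found", stacklevel=2)
    return out


def tads_from_boundaries(boundaries: dict[str, np.ndarray], bins: BinTable) -> TadSet:
    """Intervals between consecutive boundaries; domains under 3 bins dropped."""
    rows = []
    res = bins.bin_size
    for chrom, bnds in boundaries.items():
        bnds = np.sort(np.asarray(bnds))
        for a, b in zip(bnds[:-1], bnds[1:]):
            if b - a >= 3:
                rows.append((chrom, int(a) * res, int(b) * res))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if intervals.empty:
        warnings.warn("empty TAD set", stacklevel=2)
    return TadSet(intervals, {c: np.sort(np.asarray(v)) for c, v in boundaries.items()})


def _rescale_block_mean(block: np.ndarray, out_size: int) -> np.ndarray:
    """Average an (n x n) array onto an (out_size x out_size) grid."""
    n = block.shape[0]
    idx = (np.arange(n) * out_size) // n
    out = np.zeros((out_size, out_size))
    cnt = np.zeros((out_size, out_size))
    defined = ~np.isnan(block)
    vals = np.where(defined, block, 0.0)
    np.add.at(out, (idx[:, None].repeat(n, 1), idx[None, :].repeat(n, 0)), vals)
    np.add.at(cnt, (idx[:, None].repeat(n, 1), idx[None, :].repeat(n, 0)), defined.astype(float))
    with np.errstate(invalid="ignore"):
        return out / cnt


def aggregate_tad(
    matrix: ContactMatrix,
    tads: TadSet,
    rescale_bins: int = 30,
) -> tuple[np.ndarray, int]:
    """Average distance-normalized TAD-centered map on a fixed grid.

    Each TAD window (TAD plus one TAD-length flank on each side) is O/E
    normalized, block-averaged onto a (3*rescale_bins)^2 grid, and averaged
    over TADs.  Returns (grid, n_skipped) where skipped TADs were shorter
    than 3 bins or fell off the chromosome.
    """
    from .compartments import observed_over_expected

    if len(tads) < 1:
        raise ValueError("aggregate_tad needs at least one TAD")
    oe = observed_over_expected(matrix)
    res = matrix.resolution_bp
    size = 3 * rescale_bins
    acc = np.zeros((size, size))
    n_used = 0
    n_skipped = 0
    for _, t in tads.intervals.iterrows():
        sl = matrix.bins.chrom_slice(t["chrom"])
        a = sl.start + int(t["start"]) // res
        b = sl.start + int(t["end"]) // res
        length = b - a
        if length < 3:
            n_skipped += 1
            continue
        lo, hi = a - length, b + length
        if lo < sl.start or hi > sl.stop:
            n_skipped += 1
            continue
        window = oe[lo:hi, lo:hi]
        acc += np.nan_to_num(_rescale_block_mean(window, size), nan=1.0)
        n_used += 1
    if n_used == 0:
        raise ValueError("all TADs skipped; nothing to aggregate")
    return acc / n_used, n_skipped


def insulation_similarity(tracks: list[InsulationTrack]) -> np.ndarray:
    """Pairwise Pearson correlation of insulation tracks on common bins."""
    mat = _common_matrix(tracks)
    return np.corrcoef(mat)


def insulation_pca(tracks: list[InsulationTrack]) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples x bins insulation after per-bin centering.

    Returns (coordinates [n_samples x n_components], explained-variance
    fractions).
    """
    mat = _common_matrix(tracks)
    centered = mat - mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = u * s
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    return coords, explained


def _common_matrix(tracks: list[InsulationTrack]) -> np.ndarray:
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    for t in tracks[1:]:
        if not t.bins.same_as(tracks[0].bins):
            raise AlignmentError("insulation tracks are on different bin tables")
    stack = np.vstack([t.score for t in tracks])
    common = ~np.isnan(stack).any(axis=0)
    if common.sum() < 2:
        raise ValueError("fewer than 2 commonly defined bins")
    return stack[:, common]
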