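"""A/B compartment tracks, sign fixing, and switch classification.

Eigenvector 1 is taken from the Pearson correlation matrix of the
observed/expected map, per chromosome.  Sign is fixed so that the track
correlates positively with an activity reference (peak coverage or
housekeeping-gene density); positive values are compartment A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    DegenerateMatrixError,
    OrientationError,
    StateError,
)
from .matrixio import BinTable, ContactMatrix, PeakSet

__all__ = [
    "CompartmentTrack",
    "observed_over_expected",
    "compute_eigenvector",
    "orient_eigenvector",
    "reference_from_peaks",
    "compartment_track",
    "classify_switches",
    "expression_change_by_bin",
]


@dataclass
class CompartmentTrack:
    """Per-bin eigenvector-1 values; NaN where the bin is masked."""

    bins: BinTable
    ev1: np.ndarray

    @property
    def masked(self) -> np.ndarray:
        return np.isnan(self.ev1)

    def standardized(self) -> "CompartmentTrack":
        """Center defined values and scale to unit mean absolute deviation.

        Mean-absolute scaling (rather than unit sd) keeps the two
        compartment modes near +/-1 even when A/B proportions are
        unbalanced, so a fixed delta threshold stays scale-meaningful.
        """
        v = self.ev1.copy()
        ok = ~np.isnan(v)
        centered = v[ok] - v[ok].mean()
        scale = np.abs(centered).mean()
        if scale == 0:
            raise DegenerateMatrixError("constant eigenvector; cannot standardize")
        v[ok] = centered / scale
        return CompartmentTrack(self.bins, v)

    def to_bedgraph_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": list(self.bins.chroms),
                "start": self.bins.starts,
                "end": self.bins.ends,
                "value": self.ev1,
            }
        )


def observed_over_expected(matrix: ContactMatrix) -> np.ndarray:
    """Balanced value divided by the mean at its distance, per chromosome.

    Per-diagonal means run over nonmasked pairs (zeros included); diagonals
    with no nonmasked pair, and masked bins, are NaN.  Trans entries NaN.
    """
    if not matrix.is_balanced:
        raise StateError("observed_over_expected requires a balanced matrix")
    bal = matrix.balanced_dense()
    mask = matrix.mask
    n_total = matrix.bins.n_bins
    oe = np.full((n_total, n_total), np.nan)
    for chrom in matrix.bins.chrom_names:
        sl = matrix.bins.chrom_slice(chrom)
        sub = bal[sl, sl].copy()
        m = mask[sl.start : sl.stop]
        sub[m, :] = np.nan
        sub[:, m] = np.nan
        n = sub.shape[0]
        out = np.full_like(sub, np.nan)
        for d in range(n):
            diag = np.diagonal(sub, offset=d)
            ok = ~np.isnan(diag)
            if not ok.any():
                continue
            exp = diag[ok].mean()
            if exp == 0:
                continue
            vals = diag / exp
            idx = np.arange(n - d)
            out[idx, idx + d] = vals
            out[idx + d, idx] = vals
        oe[sl, sl] = out
    return oe


def compute_eigenvector(oe: np.ndarray, bins: BinTable, min_bins: int = 10) -> np.ndarray:
    """Leading eigenvector (largest |eigenvalue|) of the O/E correlation matrix.

    Computed per chromosome on nonmasked bins, unit-norm per chromosome;
    masked bins get NaN in the returned genome-wide array.
    """
    ev = np.full(bins.n_bins, np.nan)
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        sub = oe[sl, sl]
        ok = ~np.all(np.isnan(sub), axis=0)
        if ok.sum() < min_bins:
            raise DegenerateMatrixError(
                f"{chrom}: only {int(ok.sum())} nonmasked bins (< {min_bins})"
            )
        dense = sub[np.ix_(ok, ok)]
        # remaining NaNs (undefined far diagonals) -> neutral expectation 1
        dense = np.where(np.isnan(dense), 1.0, dense)
        sd = dense.std(axis=1)
        if np.any(sd == 0):
            raise DegenerateMatrixError(f"{chrom}: constant row in O/E matrix")
        corr = np.corrcoef(dense)
        vals, vecs = np.linalg.eigh(corr)
        lead = int(np.argmax(np.abs(vals)))
        vec = vecs[:, lead]
        vec = vec / np.linalg.norm(vec)
        ev_chrom = np.full(sl.stop - sl.start, np.nan)
        ev_chrom[ok] = vec
        ev[sl] = ev_chrom
    return ev


def orient_eigenvector(ev: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip sign so the correlation with the activity reference is >= 0."""
    ok = ~np.isnan(ev) & ~np.isnan(reference)
    if ok.sum() < 3:
        raise OrientationError("too few defined bins to orient eigenvector")
    r = reference[ok]
    if np.std(r) == 0 or np.std(ev[ok]) == 0:
        raise OrientationError("zero-variance reference; sign cannot be assigned")
    corr = np.corrcoef(ev[ok], r)[0, 1]
    return -ev if corr < 0 else ev.copy()


def reference_from_peaks(bins: BinTable, peaks: PeakSet) -> np.ndarray:
    """Per-bin peak base-pair coverage, the default orientation reference."""
    cov = np.zeros(bins.n_bins)
    for _, p in peaks.frame.iterrows():
        try:
            sl = bins.chrom_slice(p["chrom"])
        except KeyError:
            continue
        first = bins.bin_of(p["chrom"], int(p["start"]))
        last = bins.bin_of(p["chrom"], min(int(p["end"]) - 1, bins.ends[sl.stop - 1] - 1))
        for b in range(first, last + 1):
            lo = max(int(p["start"]), int(bins.starts[b]))
            hi = min(int(p["end"]), int(bins.ends[b]))
            cov[b] += max(0, hi - lo)
    return cov


def compartment_track(matrix: ContactMatrix, reference: np.ndarray) -> CompartmentTrack:
    """O/E -> correlation eigenvector -> sign fix, as one convenience call."""
    oe = observed_over_expected(matrix)
    ev = compute_eigenvector(oe, matrix.bins)
    return CompartmentTrack(matrix.bins, orient_eigenvector(ev, reference))


def classify_switches(
    track_a: CompartmentTrack,
    track_b: CompartmentTrack,
    delta_threshold: float = 1.5,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-bin switch categories between two conditions.

    AB iff ev_A > 0, ev_B < 0 and |ev_A - ev_B| > threshold; BA symmetric.
    Everything else inherits the sign of condition A (the reference
    condition): AA if ev_A > 0 else BB.  By default both tracks are
    standardized first (zero mean, unit mean absolute deviation) so the
    delta threshold is scale-meaningful.
    """
    if not track_a.bins.same_as(track_b.bins):
        raise AlignmentError("compartment tracks are on different bin tables")
    ta = track_a.standardized() if standardize else track_a
    tb = track_b.standardized() if standardize else track_b
    ev_a, ev_b = ta.ev1, tb.ev1
    delta = np.abs(ev_a - ev_b)
    category = np.full(track_a.bins.n_bins, "", dtype=object)
    defined = ~np.isnan(ev_a) & ~np.isnan(ev_b)
    ab = defined & (ev_a > 0) & (ev_b < 0) & (delta > delta_threshold)
    ba = defined & (ev_a < 0) & (ev_b > 0) & (delta > delta_threshold)
    aa = defined & ~ab & ~ba & (ev_a > 0)
    bb = defined & ~ab & ~ba & (ev_a <= 0)
    category[ab], category[ba], category[aa], category[bb] = "AB", "BA", "AA", "BB"
    out = track_a.bins.to_frame()
    out["ev_A"] = ev_a
    out["ev_B"] = ev_b
    out["delta"] = delta
    out["category"] = category
    return out[defined].reset_index(drop=True)


def expression_change_by_bin(
    switches: pd.DataFrame,
    genes: pd.DataFrame,
    logfc_cutoff: float = 0.58,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean DEG logFC per switch-table bin, plus pairwise rank-sum tests.

    Only genes with |logFC| >= cutoff count; bins with no qualifying gene are
    dropped.  Returns (per-bin table, category-comparison table).
    """
    deg = genes[np.abs(genes["logFC"]) >= logfc_cutoff]
    rows = []
    for _, b in switches.iterrows():
        sel = deg[
            (deg["chrom"] == b["chrom"])
            & (deg["tss"] >= b["start"])
            & (deg["tss"] < b["end"])
        ]
        if len(sel) == 0:
            continue
        rows.append(
            {
                "chrom": b["chrom"],
                "start": b["start"],
                "end": b["end"],
                "category": b["category"],
                "mean_logFC": float(sel["logFC"].mean()),
                "n_genes": len(sel),
            }
        )
    per_bin = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "category", "mean_logFC", "n_genes"]
    )
    comparisons = []
    cats = [c for c in ("AA", "AB", "BA", "BB") if (per_bin["category"] == c).any()]
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            x = per_bin.loc[per_bin["category"] == cats[i], "mean_logFC"].to_numpy()
            y = per_bin.loc[per_bin["category"] == cats[j], "mean_logFC"].to_numpy()
            p = rank_sum_pvalue(x, y)
            comparisons.append(
                {
                    "category1": cats[i],
                    "category2": cats[j],
                    "n1": len(x),
                    "n2": len(y),
                    "p_value": p,
                }
            )
    return per_bin, pd.DataFrame(
        comparisons, columns=["category1", "category2", "n1", "n2", "p_value"]
    )


def rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided unpaired rank-sum p-value.

    Exact null distribution when min(n) <= 8 and there are no ties;
    otherwise normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)
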