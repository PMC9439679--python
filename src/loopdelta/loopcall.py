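"""Loop significance testing and two-condition differential classification.

Candidate bin pairs are scored against a spline-smoothed contact-probability
prior over genomic distance, bias-corrected with the balancing weights, via
an upper-tail binomial test; Benjamini–Hochberg q-values call loops at
q < 0.01, and cross-condition comparison with a loose secondary cutoff
(q < 0.1) separates common from group-specific loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .errors import AlignmentError, StateError, ValidationError
from .matrixio import ContactMatrix, Loop

__all__ = [
    "LoopCallConfig",
    "DistancePrior",
    "fit_distance_prior",
    "pair_probabilities",
    "loop_pvalues",
    "bh_correct",
    "add_qvalues",
    "call_loops",
    "classify_differential",
    "loop_summaries",
]


@dataclass
class LoopCallConfig:
    resolution_bp: int = 10_000
    min_distance_bp: int = 30_000
    max_distance_bp: int = 5_000_000
    q_call: float = 0.01
    q_loose: float = 0.1

    def __post_init__(self) -> None:
        if self.min_distance_bp >= self.max_distance_bp:
            raise ValidationError("min_distance_bp must be < max_distance_bp")
        if not 0 < self.q_call <= self.q_loose < 1:
            raise ValidationError("need 0 < q_call <= q_loose < 1")


@dataclass
class DistancePrior:
    """Smoothed per-distance contact probability.

    ``probabilities[i]`` is the smoothed probability that a single read pair
    falls on one given bin pair at ``distances_bins[i]``, before bias
    adjustment and renormalization; non-increasing with distance.
    """

    distances_bins: np.ndarray
    probabilities: np.ndarray
    total_count: int
    empirical: np.ndarray = field(repr=False, default=None)

    def __call__(self, d_bins: np.ndarray) -> np.ndarray:
        return np.interp(d_bins, self.distances_bins, self.probabilities)


def _tested_geometry(matrix: ContactMatrix, config: LoopCallConfig):
    """Upper-triangle in-range nonmasked pairs as (rows, cols, dist_bins)."""
    res = matrix.resolution_bp
    dmin = -(-config.min_distance_bp // res)  # ceil
    dmax = config.max_distance_bp // res
    mask = matrix.mask
    rows_all, cols_all = [], []
    for chrom in matrix.bins.chrom_names:
        sl = matrix.bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        for d in range(dmin, min(dmax, n - 1) + 1):
            i = np.arange(sl.start, sl.stop - d)
            j = i + d
            ok = ~mask[i] & ~mask[j]
            rows_all.append(i[ok])
            cols_all.append(j[ok])
    rows = np.concatenate(rows_all) if rows_all else np.array([], dtype=int)
    cols = np.concatenate(cols_all) if cols_all else np.array([], dtype=int)
    return rows, cols, cols - rows


def fit_distance_prior(matrix: ContactMatrix, config: LoopCallConfig) -> DistancePrior:
    """Spline-smoothed, monotone-non-increasing contact probability vs distance."""
    if not matrix.is_balanced:
        raise StateError("fit_distance_prior requires balancing weights")
    rows, cols, dist = _tested_geometry(matrix, config)
    if rows.size == 0:
        raise StateError("no tested pairs in the configured distance range")
    counts = np.asarray(matrix.counts[rows, cols]).ravel()
    total = int(counts.sum())
    if total == 0:
        raise StateError("no contacts in the tested distance range")
    knots = np.unique(dist)
    if knots.size < 5:
        raise ValidationError(
            f"only {knots.size} distance bins in range; need >= 5 for the spline"
        )
    sums = np.bincount(dist, weights=counts)[knots]
    npairs = np.bincount(dist)[knots]
    phat = sums / (npairs * total)

    pos = phat > 0
    logd = np.log(knots[pos].astype(float))
    logp = np.log(phat[pos])
    # Poisson-motivated weights: sd(log phat) ~ 1/sqrt(count)
    w = np.sqrt(np.maximum(sums[pos], 1.0))
    if pos.sum() >= 5:
        spl = UnivariateSpline(logd, logp, w=w, k=3, s=float(pos.sum()))
        smooth = np.exp(spl(np.log(knots.astype(float))))
    else:
        smooth = phat.copy()
    smooth = np.minimum.accumulate(smooth)  # enforce non-increasing
    return DistancePrior(knots, smooth, total, empirical=phat)


def pair_probabilities(
    matrix: ContactMatrix,
    prior: DistancePrior,
    config: LoopCallConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bias-adjusted, renormalized per-pair probabilities over all tested pairs.

    Returns (rows, cols, dist_bins, p_pair) with p_pair summing to 1 across
    the tested universe.
    """
    if not matrix.is_balanced:
        raise StateError("pair_probabilities requires balancing weights")
    rows, cols, dist = _tested_geometry(matrix, config)
    weights = matrix.weights
    bias = np.full_like(weights, np.nan)
    ok = ~np.isnan(weights) & (weights > 0)
    bias[ok] = 1.0 / weights[ok]
    bias[ok] /= bias[ok].mean()
    base = prior(dist) * bias[rows] * bias[cols]
    return rows, cols, dist, base / base.sum()


def loop_pvalues(
    matrix: ContactMatrix,
    prior: DistancePrior,
    config: LoopCallConfig,
) -> pd.DataFrame:
    """Upper-tail binomial p-value for every in-range nonzero pair.

    p_ij = prior(d_ij) * b_i * b_j / Z with bias b = 1/weight normalized to
    unit mean over nonmasked bins and Z summing the bias-adjusted prior over
    all tested pairs (zero-count pairs included in Z and in the total count
    N, but reported only implicitly with p-value 1).
    """
    rows, cols, dist, p_pair = pair_probabilities(matrix, prior, config)
    counts = np.asarray(matrix.counts[rows, cols]).ravel()
    n_reads = int(counts.sum())
    if np.any(counts > n_reads):
        raise ValidationError("pair count exceeds total count")

    nz = counts > 0
    pvals = stats.binom.sf(counts[nz] - 1, n_reads, p_pair[nz])
    expected = n_reads * p_pair[nz]
    chrom_arr = np.asarray(matrix.bins.chroms, dtype=object)
    table = pd.DataFrame(
        {
            "chrom": chrom_arr[rows[nz]],
            "bin1": rows[nz],
            "bin2": cols[nz],
            "distance_bp": dist[nz] * matrix.resolution_bp,
            "count": counts[nz].astype(np.int64),
            "expected": expected,
            "score": counts[nz] / expected,
            "p_value": pvals,
        }
    )
    table.attrs["n_tested_pairs"] = int(rows.size)
    table.attrs["total_count"] = n_reads
    return table.sort_values(["bin1", "bin2"], kind="stable").reset_index(drop=True)


def bh_correct(pvalues: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    ``m`` is the number of tests; defaults to len(pvalues) but should be the
    full tested-pair count when zero-count pairs (p = 1) are left implicit.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValidationError("m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def add_qvalues(table: pd.DataFrame) -> pd.DataFrame:
    """Attach BH q-values using the full tested universe as m."""
    m = table.attrs.get("n_tested_pairs", len(table))
    out = table.copy()
    out["q_value"] = bh_correct(table["p_value"].to_numpy(), m=m)
    out.attrs.update(table.attrs)
    return out


def call_loops(table: pd.DataFrame, matrix: ContactMatrix, q_call: float = 0.01) -> list[Loop]:
    """Significant pairs (q < q_call) as Loop records with normalized scores."""
    if "q_value" not in table.columns:
        table = add_qvalues(table)
    res = matrix.resolution_bp
    starts = matrix.bins.starts
    loops = []
    for _, r in table[table["q_value"] < q_call].iterrows():
        b1, b2 = int(r["bin1"]), int(r["bin2"])
        loops.append(
            Loop(
                r["chrom"],
                int(starts[b1]),
                int(starts[b1]) + res,
                r["chrom"],
                int(starts[b2]),
                int(starts[b2]) + res,
                raw_count=float(r["count"]),
                expected=float(r["expected"]),
                p_value=float(r["p_value"]),
                q_value=float(r["q_value"]),
                score=float(r["score"]),
            )
        )
    return loops


def classify_differential(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    config: LoopCallConfig,
    bins_a=None,
    bins_b=None,
) -> pd.DataFrame:
    """Merge the two per-condition tables and assign diff_class per pair.

    A_specific iff q_A < q_call and q_B >= q_loose; B_specific symmetric;
    common iff both < q_call; significant on one side with the other in
    [q_call, q_loose) -> indeterminate; everything else untested.  Pairs
    absent from a table (zero count) carry q = 1 on that side.
    """
    if bins_a is not None and bins_b is not None and not bins_a.same_as(bins_b):
        raise AlignmentError("conditions were tested on different bin tables")
    ta = add_qvalues(table_a) if "q_value" not in table_a.columns else table_a
    tb = add_qvalues(table_b) if "q_value" not in table_b.columns else table_b
    merged = pd.merge(
        ta,
        tb,
        on=["chrom", "bin1", "bin2", "distance_bp"],
        how="outer",
        suffixes=("_A", "_B"),
    )
    for side in ("A", "B"):
        merged[f"q_{side}"] = merged[f"q_value_{side}"].fillna(1.0)
    qa = merged["q_A"].to_numpy()
    qb = merged["q_B"].to_numpy()
    qc, ql = config.q_call, config.q_loose
    cls = np.full(len(merged), "untested", dtype=object)
    cls[(qa < qc) & (qb < qc)] = "common"
    cls[(qa < qc) & (qb >= ql)] = "A_specific"
    cls[(qb < qc) & (qa >= ql)] = "B_specific"
    cls[(qa < qc) & (qb >= qc) & (qb < ql)] = "indeterminate"
    cls[(qb < qc) & (qa >= qc) & (qa < ql)] = "indeterminate"
    merged["diff_class"] = cls
    return merged


def loop_summaries(
    classified: pd.DataFrame,
    length_bin_bp: int = 100_000,
    max_length_bp: int = 5_000_000,
) -> dict:
    """Counts, length histograms and score-vs-distance profiles per class."""
    called = classified[classified["diff_class"] != "untested"]
    out: dict = {"counts": called["diff_class"].value_counts().to_dict()}
    edges = np.arange(0, max_length_bp + length_bin_bp, length_bin_bp)
    hists = {}
    for cls, grp in called.groupby("diff_class"):
        hist, _ = np.histogram(grp["distance_bp"], bins=edges)
        hists[cls] = hist
    out["length_histograms"] = hists
    out["length_bin_edges_bp"] = edges
    profiles = {}
    for side in ("A", "B"):
        col = f"score_{side}"
        if col in classified.columns:
            sub = classified.dropna(subset=[col])
            grp = sub.groupby(np.digitize(sub["distance_bp"], edges))[col].mean()
            profiles[side] = grp
    out["score_profiles"] = profiles
    return out
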