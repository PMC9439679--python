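"""Promoter-anchored loop annotation, DEG classification, ChIP-peak promoter
occupancy, stratified loop-score statistics, and pile-up analyses.

Interval logic is half-open throughout: a peak touching a promoter window
boundary exactly does not overlap it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import rank_sum_pvalue
from .errors import StateError, ValidationError
from .matrixio import ContactMatrix, Loop, PeakSet

__all__ = [
    "PileupResult",
    "classify_genes",
    "sample_stable_genes",
    "annotate_promoter_loops",
    "promoter_peak_overlap",
    "stratified_loop_scores",
    "pileup_dots",
    "pileup_tss",
]

PROMOTER_WINDOW_BP = 2_000


@dataclass
class PileupResult:
    """Averaged distance-normalized local map with summary enrichments."""

    mean_map: np.ndarray  # (2*pad+1) x (2*pad+1)
    n_windows: int
    central_enrichment: float | None = None
    stripe_score: float | None = None
    corner_block_size: int = 3
    n_skipped: int = 0


# ---------------------------------------------------------------------------
# Gene classification and sampling
# ---------------------------------------------------------------------------

def classify_genes(
    de_table: pd.DataFrame,
    fdr: float = 0.05,
    logfc: float = 0.58,
    stable_logfc: float = 0.38,
) -> pd.DataFrame:
    """Assign expr_class in {down, up, stable, other}.

    down: FDR < fdr and logFC <= -logfc and logCPM > 0; up symmetric;
    stable: |logFC| < stable_logfc and logCPM > 0; everything else other.
    """
    for col in ("logFC", "logCPM", "FDR"):
        if col not in de_table.columns:
            raise ValidationError(f"DE table missing column {col!r}")
    out = de_table.copy()
    lfc = out["logFC"].to_numpy(dtype=float)
    cpm = out["logCPM"].to_numpy(dtype=float)
    q = out["FDR"].to_numpy(dtype=float)
    active = cpm > 0
    down = (q < fdr) & (lfc <= -logfc) & active
    up = (q < fdr) & (lfc >= logfc) & active
    stable = ~down & ~up & (np.abs(lfc) < stable_logfc) & active
    cls = np.full(len(out), "other", dtype=object)
    cls[stable] = "stable"
    cls[down] = "down"
    cls[up] = "up"
    out["expr_class"] = cls
    return out


def sample_stable_genes(genes: pd.DataFrame, n: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Uniform sample of stable genes without replacement, seed-deterministic."""
    stable = genes[genes["expr_class"] == "stable"]
    if len(stable) <= n:
        if len(stable) < n:
            warnings.warn(
                f"only {len(stable)} stable genes available (< {n}); returning all",
                stacklevel=2,
            )
        return stable.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(stable), size=n, replace=False)
    return stable.iloc[np.sort(idx)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Promoter annotation
# ---------------------------------------------------------------------------

def _promoter_window(tss: int, window_bp: int) -> tuple[int, int]:
    return tss - window_bp, tss + window_bp


def annotate_promoter_loops(
    loops: list[Loop],
    genes: pd.DataFrame,
    window_bp: int = PROMOTER_WINDOW_BP,
) -> pd.DataFrame:
    """All (loop, gene, anchor side) pairs where an anchor hits a promoter.

    A loop is promoter-anchored for a gene iff either anchor interval
    intersects [tss - window, tss + window) — strand does not move the
    window, it stays centered on the TSS coordinate.
    """
    rows = []
    for li, lp in enumerate(loops):
        for side, (chrom, s, e) in (
            (1, (lp.chrom1, lp.start1, lp.end1)),
            (2, (lp.chrom2, lp.start2, lp.end2)),
        ):
            sub = genes[genes["chrom"] == chrom]
            w_lo = sub["tss"].to_numpy() - window_bp
            w_hi = sub["tss"].to_numpy() + window_bp
            hits = sub[(w_lo < e) & (s < w_hi)]
            for _, g in hits.iterrows():
                rows.append(
                    {
                        "loop_index": li,
                        "gene_id": g["gene_id"],
                        "anchor": side,
                        "chrom": chrom,
                        "anchor_start": s,
                        "anchor_end": e,
                        "tss": int(g["tss"]),
                        "expr_class": g.get("expr_class", "other"),
                        "score": lp.score,
                        "diff_class": lp.diff_class,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "loop_index",
            "gene_id",
            "anchor",
            "chrom",
            "anchor_start",
            "anchor_end",
            "tss",
            "expr_class",
            "score",
            "diff_class",
        ],
    )


def promoter_peak_overlap(
    genes: pd.DataFrame,
    peaks: PeakSet,
    window_bp: int = PROMOTER_WINDOW_BP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag genes whose promoter window intersects any peak.

    Returns (genes with ``promoter_peak`` column, per-expr_class occupancy
    fractions).
    """
    out = genes.copy()
    flags = np.zeros(len(out), dtype=bool)
    pk = peaks.frame
    for chrom, sub in out.groupby("chrom"):
        p = pk[pk["chrom"] == chrom]
        if p.empty:
            continue
        ps = p["start"].to_numpy()
        pe = p["end"].to_numpy()
        for i, tss in zip(sub.index, sub["tss"].to_numpy()):
            lo, hi = _promoter_window(int(tss), window_bp)
            flags[out.index.get_loc(i)] = bool(np.any((ps < hi) & (lo < pe)))
    out["promoter_peak"] = flags
    if "expr_class" in out.columns:
        frac = (
            out.groupby("expr_class")["promoter_peak"]
            .agg(["mean", "sum", "count"])
            .rename(columns={"mean": "fraction", "sum": "n_with_peak", "count": "n_genes"})
            .reset_index()
        )
    else:
        frac = pd.DataFrame(
            {
                "expr_class": ["all"],
                "fraction": [float(flags.mean()) if len(flags) else np.nan],
                "n_with_peak": [int(flags.sum())],
                "n_genes": [len(flags)],
            }
        )
    return out, frac


def stratified_loop_scores(
    p_loops: pd.DataFrame,
    genes: pd.DataFrame,
    min_n: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loop-score distributions per (expr_class, promoter_peak) stratum.

    Returns (per-stratum summary, pairwise rank-sum tests); strata with
    fewer than ``min_n`` scores are reported but excluded from testing.
    """
    flagged = genes.set_index("gene_id")["promoter_peak"]
    df = p_loops.copy()
    df["promoter_peak"] = df["gene_id"].map(flagged).astype(bool)
    df = df.dropna(subset=["score"])
    strata: dict[tuple, np.ndarray] = {}
    summary_rows = []
    for (cls, pk), grp in df.groupby(["expr_class", "promoter_peak"]):
        scores = grp["score"].to_numpy(dtype=float)
        strata[(cls, bool(pk))] = scores
        summary_rows.append(
            {
                "expr_class": cls,
                "promoter_peak": bool(pk),
                "n": len(scores),
                "median_score": float(np.median(scores)) if len(scores) else np.nan,
            }
        )
    summary = pd.DataFrame(
        summary_rows, columns=["expr_class", "promoter_peak", "n", "median_score"]
    )
    tests = []
    keys = sorted(strata)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            x, y = strata[keys[i]], strata[keys[j]]
            if len(x) < min_n or len(y) < min_n:
                tests.append(
                    {
                        "stratum1": keys[i],
                        "stratum2": keys[j],
                        "n1": len(x),
                        "n2": len(y),
                        "p_value": np.nan,
                        "skipped": True,
                    }
                )
                continue
            tests.append(
                {
                    "stratum1": keys[i],
                    "stratum2": keys[j],
                    "n1": len(x),
                    "n2": len(y),
                    "p_value": rank_sum_pvalue(x, y),
                    "skipped": False,
                }
            )
    return summary, pd.DataFrame(
        tests, columns=["stratum1", "stratum2", "n1", "n2", "p_value", "skipped"]
    )


# ---------------------------------------------------------------------------
# Pile-ups
# ---------------------------------------------------------------------------

def _shift_offsets(rng: np.random.Generator, n_shifts: int, pad: int) -> np.ndarray:
    mag = rng.integers(5 * pad, 50 * pad + 1, size=n_shifts)
    sign = rng.choice([-1, 1], size=n_shifts)
    return mag * sign


def _normalized_window(
    bal: np.ndarray,
    i: int,
    j: int,
    pad: int,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    n_shifts: int,
) -> np.ndarray | None:
    """Local window divided by the element-wise mean of shifted controls."""
    if i - pad < lo or j + pad >= hi:
        return None
    win = bal[i - pad : i + pad + 1, j - pad : j + pad + 1]
    ctrl_sum = np.zeros_like(win)
    ctrl_cnt = np.zeros_like(win)
    n_ok = 0
    for s in _shift_offsets(rng, n_shifts, pad):
        # clamp the common offset so the control stays inside the chromosome
        shift_lo = lo + pad - min(i, j)
        shift_hi = hi - pad - 1 - max(i, j)
        s = int(np.clip(s, shift_lo, shift_hi))
        ci, cj = i + s, j + s
        c = bal[ci - pad : ci + pad + 1, cj - pad : cj + pad + 1]
        if c.shape != win.shape:
            continue
        defined = ~np.isnan(c)  # masked-bin cells are excluded, not zeroed
        ctrl_sum[defined] += c[defined]
        ctrl_cnt += defined
        n_ok += 1
    if n_ok == 0:
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        ctrl = ctrl_sum / ctrl_cnt
        norm = np.where(ctrl > 0, win / ctrl, np.nan)
    return norm


def _central_enrichment(mean_map: np.ndarray, corner: int) -> float:
    pad = mean_map.shape[0] // 2
    center = mean_map[pad, pad]
    ul = mean_map[:corner, :corner]
    br = mean_map[-corner:, -corner:]
    corners = np.concatenate([ul.ravel(), br.ravel()])
    corners = corners[~np.isnan(corners)]
    if corners.size == 0 or np.nanmean(corners) == 0:
        raise StateError("corner blocks are all zero/undefined; enrichment undefined")
    return float(center / corners.mean())


def pileup_dots(
    matrix: ContactMatrix,
    loci: list[tuple[int, int]] | list[Loop],
    pad_bins: int = 10,
    n_shifts: int = 10,
    seed: int = 0,
    corner_block_size: int = 3,
) -> PileupResult:
    """Average dot-centered windows with random-shift distance normalization.

    ``loci`` are (bin1, bin2) genome-wide bin-id pairs or Loop records.
    central_enrichment = center pixel over the mean of the 3x3 upper-left
    and bottom-right corner blocks.
    """
    if not matrix.is_balanced:
        raise StateError("pileup_dots requires a balanced matrix")
    bal = matrix.balanced_dense()
    bal = np.nan_to_num(bal, nan=np.nan)
    rng = np.random.default_rng(seed)
    pairs = _loci_to_pairs(matrix, loci)
    size = 2 * pad_bins + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n_used = 0
    n_skipped = 0
    for i, j in pairs:
        chrom = matrix.bins.chroms[i]
        sl = matrix.bins.chrom_slice(chrom)
        norm = _normalized_window(bal, i, j, pad_bins, sl.start, sl.stop, rng, n_shifts)
        if norm is None:
            n_skipped += 1
            continue
        ok = ~np.isnan(norm)
        acc[ok] += norm[ok]
        cnt[ok] += 1
        n_used += 1
    if n_used == 0:
        raise StateError("all loci skipped (too close to chromosome edges)")
    with np.errstate(invalid="ignore"):
        mean_map = acc / cnt
    enrich = _central_enrichment(mean_map, corner_block_size)
    return PileupResult(
        mean_map=mean_map,
        n_windows=n_used,
        central_enrichment=enrich,
        corner_block_size=corner_block_size,
        n_skipped=n_skipped,
    )


def _loci_to_pairs(matrix: ContactMatrix, loci) -> list[tuple[int, int]]:
    pairs = []
    for item in loci:
        if isinstance(item, Loop):
            b1 = matrix.bins.bin_of(item.chrom1, (item.start1 + item.end1) // 2)
            b2 = matrix.bins.bin_of(item.chrom2, (item.start2 + item.end2) // 2)
            pairs.append((b1, b2))
        else:
            pairs.append((int(item[0]), int(item[1])))
    return pairs


def pileup_tss(
    matrix: ContactMatrix,
    genes: pd.DataFrame,
    pad_bins: int = 10,
    n_shifts: int = 10,
    seed: int = 0,
    omit_diagonal: bool = True,
) -> PileupResult:
    """Strand-oriented TSS-centered pile-up with one-sided stripe scoring.

    Each window is centered on the TSS diagonal pixel and reflected for
    minus-strand genes so transcription always points toward the positive
    axis.  stripe_score = mean of the TSS-row pixels downstream of the TSS
    over the mean upstream; diagonal pixels are excluded from the mean map.
    """
    if not matrix.is_balanced:
        raise StateError("pileup_tss requires a balanced matrix")
    if "strand" not in genes.columns or genes["strand"].isna().any():
        raise ValidationError("pileup_tss requires a strand for every gene")
    bad = genes[~genes["strand"].isin(["+", "-"])]
    if len(bad):
        raise ValidationError(
            f"unstranded gene(s): {', '.join(map(str, bad['gene_id'].head(3)))}"
        )
    bal = matrix.balanced_dense()
    rng = np.random.default_rng(seed)
    size = 2 * pad_bins + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n_used = 0
    n_skipped = 0
    for _, g in genes.iterrows():
        try:
            t = matrix.bins.bin_of(g["chrom"], int(g["tss"]))
        except (KeyError, ValidationError):
            n_skipped += 1
            continue
        sl = matrix.bins.chrom_slice(g["chrom"])
        norm = _normalized_window(bal, t, t, pad_bins, sl.start, sl.stop, rng, n_shifts)
        if norm is None:
            n_skipped += 1
            continue
        if g["strand"] == "-":
            norm = norm[::-1, ::-1]
        ok = ~np.isnan(norm)
        acc[ok] += norm[ok]
        cnt[ok] += 1
        n_used += 1
    if n_used == 0:
        raise StateError("all TSS windows skipped")
    with np.errstate(invalid="ignore"):
        mean_map = acc / cnt
    center = pad_bins
    down = mean_map[center, center + 1 :]
    up = mean_map[center, :center]
    stripe = float(np.nanmean(down) / np.nanmean(up))
    if omit_diagonal:
        out_map = mean_map.copy()
        np.fill_diagonal(out_map, np.nan)
    else:
        out_map = mean_map
    return PileupResult(
        mean_map=out_map,
        n_windows=n_used,
        stripe_score=stripe,
        n_skipped=n_skipped,
    )
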