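"""Two-condition synthetic Hi-C generator with planted ground truth.

Builds a noise-free mean contact model per condition — power-law distance
decay modulated by a compartment checkerboard, TAD blocks, focal loop dots
and one-sided promoter stripes — then draws Poisson counts at a configured
sequencing depth.  Matched gene/DE tables and promoter peak sets carry the
same planted labels, so every downstream stage can be scored against truth.

Seed derivation: ``simulate_truth`` consumes ``config.seed`` directly; count
matrices use ``replicate_seed``, conventionally derived by
:func:`condition_seed` as ``seed + 100_000 * (1 for A, 2 for B) + replicate``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, PlacementError
from .matrixio import (
    BinTable,
    ContactMatrix,
    Loop,
    PeakSet,
    write_bedpe,
    write_genes,
    write_matrix,
    write_narrowpeak,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "PlantedLoop",
    "simulate_truth",
    "simulate_contact_matrix",
    "noise_free_mean",
    "simulate_expression_table",
    "simulate_peaks",
    "condition_seed",
    "write_truth",
]

_CONDITIONS = ("A", "B")


@dataclass
class SimConfig:
    """Generator parameters; ``seed`` fully determines all outputs."""

    n_chromosomes: int = 1
    chrom_length_bp: int = 20_000_000
    bin_size_bp: int = 10_000
    decay_exponent: float = 1.0
    depth: int = 20_000_000
    compartment_block_mean_bp: int = 2_000_000
    compartment_strength: float = 2.0
    n_switch_blocks: int = 1  # blocks flipped per direction (AB and BA)
    tad_mean_size_bp: int = 500_000
    tad_insulation: float = 0.7
    n_loops_shared: int = 5
    n_loops_A_only: int = 3
    n_loops_B_only: int = 2
    loop_strength: float = 5.0
    loop_min_dist_bp: int = 200_000
    loop_max_dist_bp: int = 800_000
    n_genes: int = 300
    n_stripe_genes: int = 10
    stripe_strength: float = 3.0
    stripe_length_bp: int = 300_000
    de_fraction_down: float = 0.15
    de_fraction_up: float = 0.15
    de_logfc_mean: float = 1.5
    de_logfc_sd: float = 0.3
    peak_fraction_down: float = 0.8
    peak_fraction_other: float = 0.3
    loops_at_down_promoters: bool = True
    n_decoy_peaks: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_length_bp % self.bin_size_bp != 0:
            raise ConfigError("bin_size_bp must divide chrom_length_bp")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        for name in ("compartment_strength", "loop_strength", "stripe_strength"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 <= self.tad_insulation <= 1:
            raise ConfigError("tad_insulation must be in [0, 1]")
        for name in ("de_fraction_down", "de_fraction_up"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.de_fraction_down + self.de_fraction_up > 1:
            raise ConfigError("de_fraction_down + de_fraction_up must be <= 1")
        if self.loop_min_dist_bp < 2 * self.bin_size_bp:
            raise ConfigError("loop_min_dist_bp must span at least 2 bins")
        if self.loop_max_dist_bp <= self.loop_min_dist_bp:
            raise ConfigError("loop_max_dist_bp must exceed loop_min_dist_bp")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")

    @property
    def n_bins_per_chrom(self) -> int:
        return self.chrom_length_bp // self.bin_size_bp

    def chromsizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)}

    def bin_table(self) -> BinTable:
        return BinTable.from_chromsizes(self.chromsizes(), self.bin_size_bp)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedLoop:
    chrom: str
    bin1: int  # chromosome-local bin index
    bin2: int
    membership: str  # shared | A | B
    fold: float


@dataclass
class SyntheticTruth:
    """Planted structure for one simulated genome."""

    config: SimConfig
    bins: BinTable
    loops: list[PlantedLoop]
    # per-condition per-bin compartment labels, chromosome-local arrays
    compartment_label: dict[str, dict[str, np.ndarray]]  # chrom -> {A,B} -> labels
    switch_category: dict[str, np.ndarray]  # chrom -> {AA,AB,BA,BB} per bin
    tad_boundaries: dict[str, np.ndarray]  # chrom -> interior boundary bins
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, tss_bin, expr_class,
    #                      has_promoter_peak, has_stripe

    def loops_for(self, condition: str) -> list[PlantedLoop]:
        if condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {_CONDITIONS}")
        return [lp for lp in self.loops if lp.membership in ("shared", condition)]


def condition_seed(master_seed: int, condition: str, replicate: int = 0) -> int:
    """Fixed-offset replicate seed derivation (documented convention)."""
    if condition not in _CONDITIONS:
        raise ValueError(f"condition must be one of {_CONDITIONS}")
    return master_seed + 100_000 * (1 + _CONDITIONS.index(condition)) + replicate


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _draw_boundaries(rng: np.random.Generator, n_bins: int, mean_size_bins: float) -> np.ndarray:
    """Interior TAD boundaries with roughly exponential domain sizes.

    Domains are floored at 15 bins so they stay resolvable by a diamond
    insulation window of the default 10 bins.
    """
    min_size = 15
    edges = [0]
    while edges[-1] < n_bins:
        size = max(min_size, int(round(rng.exponential(mean_size_bins))))
        edges.append(edges[-1] + size)
    interior = np.array(edges[1:-1], dtype=np.int64)
    return interior[interior < n_bins - min_size]

def _compartment_blocks(
    rng: np.random.Generator,
    boundaries: np.ndarray,
    n_bins: int,
    mean_block_bins: float,
) -> list[tuple[int, int]]:
    """Group consecutive TADs into compartment blocks of ~mean_block_bins.

    Aligning compartment edges to TAD boundaries keeps the insulation track
    free of checkerboard-induced spurious minima.
    """
    edges = np.concatenate(([0], boundaries, [n_bins]))
    blocks: list[tuple[int, int]] = []
    i = 0
    while i < len(edges) - 1:
        target = max(1.0, rng.exponential(mean_block_bins))
        j = i + 1
        while j < len(edges) - 1 and edges[j] - edges[i] < target:
            j += 1
        blocks.append((int(edges[i]), int(edges[j])))
        i = j
    return blocks


def simulate_truth(config: SimConfig) -> SyntheticTruth:
    """Plant all structure; deterministic for a given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bins = config.bin_table()
    n = config.n_bins_per_chrom
    res = config.bin_size_bp

    compartment_label: dict[str, dict[str, np.ndarray]] = {}
    switch_category: dict[str, np.ndarray] = {}
    tad_boundaries: dict[str, np.ndarray] = {}
    gene_rows: list[dict] = []
    loops: list[PlantedLoop] = []

    per_chrom = {
        "shared": _split_counts(config.n_loops_shared, config.n_chromosomes),
        "A": _split_counts(config.n_loops_A_only, config.n_chromosomes),
        "B": _split_counts(config.n_loops_B_only, config.n_chromosomes),
    }
    genes_per_chrom = _split_counts(config.n_genes, config.n_chromosomes)

    for ci, chrom in enumerate(config.chromsizes()):
        boundaries = _draw_boundaries(rng, n, config.tad_mean_size_bp / res)
        tad_boundaries[chrom] = boundaries

        blocks = _compartment_blocks(
            rng, boundaries, n, config.compartment_block_mean_bp / res
        )
        label_a = np.empty(n, dtype="<U1")
        first = rng.choice(["A", "B"])
        for k, (s, e) in enumerate(blocks):
            label_a[s:e] = first if k % 2 == 0 else ("B" if first == "A" else "A")
        label_b = label_a.copy()
        # plant switches by flipping whole blocks, AB and BA
        a_blocks = [b for b in blocks if label_a[b[0]] == "A"]
        b_blocks = [b for b in blocks if label_a[b[0]] == "B"]
        rng.shuffle(a_blocks)
        rng.shuffle(b_blocks)
        for s, e in a_blocks[: config.n_switch_blocks]:
            label_b[s:e] = "B"
        for s, e in b_blocks[: config.n_switch_blocks]:
            label_b[s:e] = "A"
        compartment_label[chrom] = {"A": label_a, "B": label_b}
        cat = np.where(
            label_a == "A",
            np.where(label_b == "A", "AA", "AB"),
            np.where(label_b == "A", "BA", "BB"),
        )
        switch_category[chrom] = cat

        # --- genes ---
        max_d_bins = config.loop_max_dist_bp // res
        stripe_bins = config.stripe_length_bp // res
        margin = max(stripe_bins, max_d_bins, 15) + 2
        candidate = np.arange(margin, n - margin)
        # bias placement toward A-compartment bins so promoter-peak coverage
        # can orient the eigenvector (active chromatin = compartment A)
        n_a = (label_a[candidate] == "A").astype(float) + (
            label_b[candidate] == "A"
        ).astype(float)
        w = np.where(n_a == 2, 10.0, np.where(n_a == 1, 2.0, 1.0))
        n_genes = genes_per_chrom[ci]
        if n_genes > candidate.size:
            raise PlacementError("n_genes exceeds available bins (chrom too short)")
        tss_bins = rng.choice(candidate, size=n_genes, replace=False, p=w / w.sum())
        tss_bins = np.sort(tss_bins)
        strands = rng.choice(["+", "-"], size=n_genes)
        jitter = rng.integers(-res // 4, res // 4 + 1, size=n_genes)
        tss = tss_bins * res + res // 2 + jitter
        classes = _assign_classes(rng, n_genes, config)
        for g in range(n_genes):
            gene_rows.append(
                {
                    "gene_id": f"gene_{chrom}_{g:04d}",
                    "chrom": chrom,
                    "tss": int(tss[g]),
                    "strand": strands[g],
                    "tss_bin": int(tss_bins[g]),
                    "expr_class": classes[g],
                    "has_promoter_peak": False,
                    "has_stripe": False,
                }
            )

        chrom_genes = [r for r in gene_rows if r["chrom"] == chrom]

        # --- stripes: prefer down-regulated genes, relocated onto TAD
        # boundaries (stripe anchors coincide with domain borders, so the
        # insulation dip they cause falls on a planted boundary)
        n_stripes = _split_counts(config.n_stripe_genes, config.n_chromosomes)[ci]
        used_bins = {r["tss_bin"] for r in chrom_genes}
        free_boundaries = [
            int(b)
            for b in boundaries
            if margin <= b < n - margin and b not in used_bins
        ]
        rng.shuffle(free_boundaries)
        ordered = sorted(
            chrom_genes, key=lambda r: (r["expr_class"] != "down", r["gene_id"])
        )
        for r, bnd in zip(ordered[:n_stripes], free_boundaries):
            # the stripe must extend into the gene's own domain: boundary bin
            # for + genes (stripe runs into the downstream TAD), last bin of
            # the upstream TAD for - genes — otherwise the cross-boundary
            # down-weight cancels the planted stripe
            target = bnd if r["strand"] == "+" else bnd - 1
            if target in used_bins:
                continue
            r["has_stripe"] = True
            used_bins.discard(r["tss_bin"])
            r["tss_bin"] = target
            r["tss"] = target * res + res // 2
            used_bins.add(target)

        # --- loops --- (stripe genes excluded from the anchor pool so
        # condition-specific dots are not confounded by shared stripes)
        down_bins = [
            r["tss_bin"]
            for r in chrom_genes
            if r["expr_class"] == "down" and not r["has_stripe"]
        ]
        rng.shuffle(down_bins)
        occupied: set[tuple[int, int]] = set()
        min_d = config.loop_min_dist_bp // res
        for membership in ("shared", "A", "B"):
            count = per_chrom[membership][ci]
            anchor_pool: list[int] | None = None
            if membership == "A" and config.loops_at_down_promoters:
                anchor_pool = down_bins
            for k in range(count):
                placed = False
                for _attempt in range(1000):
                    if anchor_pool:
                        b1 = int(anchor_pool[(k + _attempt) % len(anchor_pool)])
                    else:
                        b1 = int(rng.integers(margin, n - margin))
                    d = int(rng.integers(min_d, max_d_bins + 1))
                    b2 = b1 + d
                    if b2 >= n - 2:
                        continue
                    if _collides(b1, b2, occupied):
                        continue
                    occupied.add((b1, b2))
                    loops.append(PlantedLoop(chrom, b1, b2, membership, config.loop_strength))
                    placed = True
                    break
                if not placed:
                    raise PlacementError(
                        f"could not place {membership} loop {k} on {chrom}: "
                        "n_loops_* too large for chrom_length_bp/loop distance range"
                    )

        # --- promoter peak flags ---
        for r in chrom_genes:
            frac = (
                config.peak_fraction_down
                if r["expr_class"] == "down"
                else config.peak_fraction_other
            )
            r["has_promoter_peak"] = bool(rng.random() < frac)

    genes = pd.DataFrame(
        gene_rows,
        columns=[
            "gene_id",
            "chrom",
            "tss",
            "strand",
            "tss_bin",
            "expr_class",
            "has_promoter_peak",
            "has_stripe",
        ],
    )
    return SyntheticTruth(
        config=config,
        bins=bins,
        loops=loops,
        compartment_label=compartment_label,
        switch_category=switch_category,
        tad_boundaries=tad_boundaries,
        genes=genes,
    )


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _collides(b1: int, b2: int, occupied: set[tuple[int, int]], pad: int = 2) -> bool:
    for o1, o2 in occupied:
        if abs(b1 - o1) <= pad and abs(b2 - o2) <= pad:
            return True
    return False


def _assign_classes(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    n_down = int(round(config.de_fraction_down * n))
    n_up = int(round(config.de_fraction_up * n))
    rest = n - n_down - n_up
    n_stable = int(round(0.7 * rest))
    classes = np.array(
        ["down"] * n_down
        + ["up"] * n_up
        + ["stable"] * n_stable
        + ["other"] * (rest - n_stable)
    )
    rng.shuffle(classes)
    return classes


# ---------------------------------------------------------------------------
# Contact-matrix simulation
# ---------------------------------------------------------------------------

def noise_free_mean(truth: SyntheticTruth, config: SimConfig, condition: str) -> np.ndarray:
    """Dense genome-wide Poisson-mean matrix scaled so its total is ``depth``.

    Trans blocks are zero (cis-only model).
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"condition must be one of {_CONDITIONS}")
    bins = truth.bins
    n_total = bins.n_bins
    mean = np.zeros((n_total, n_total))
    res = config.bin_size_bp
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :])
        block = np.maximum(d, 1).astype(float) ** (-config.decay_exponent)

        labels = truth.compartment_label[chrom][condition]
        same = labels[:, None] == labels[None, :]
        block *= np.where(same, config.compartment_strength, 1.0)

        # cross-boundary pairs are down-weighted once (not per boundary), so
        # long-range structure survives and only same-TAD pairs stand out
        boundaries = truth.tad_boundaries[chrom]
        if boundaries.size and config.tad_insulation > 0:
            cb = np.zeros(n + 1)
            cb[boundaries] = 1.0
            cum = np.cumsum(cb)[:n]
            crossings = np.abs(cum[:, None] - cum[None, :])
            block *= np.where(crossings > 0, 1.0 - config.tad_insulation, 1.0)

        # planted dot pixels are defined on the distance-decay baseline in
        # BOTH conditions (local TAD/compartment modulation overridden), with
        # the fold applied only in carrying conditions — so a condition-
        # specific dot is exactly background in the other condition and stays
        # detectable regardless of how many boundaries it spans
        carried = {(lp.bin1, lp.bin2) for lp in truth.loops_for(condition)}
        for lp in truth.loops:
            if lp.chrom != chrom:
                continue
            d_loop = abs(lp.bin2 - lp.bin1)
            base = float(max(d_loop, 1)) ** (-config.decay_exponent)
            value = base * (lp.fold if (lp.bin1, lp.bin2) in carried else 1.0)
            block[lp.bin1, lp.bin2] = value
            block[lp.bin2, lp.bin1] = value

        stripe_bins = config.stripe_length_bp // res
        stripe_genes = truth.genes[
            (truth.genes["chrom"] == chrom) & truth.genes["has_stripe"]
        ]
        for _, g in stripe_genes.iterrows():
            t = int(g["tss_bin"])
            if g["strand"] == "+":
                cols = np.arange(t + 1, min(t + 1 + stripe_bins, n))
            else:
                cols = np.arange(max(t - stripe_bins, 0), t)
            block[t, cols] *= config.stripe_strength
            block[cols, t] *= config.stripe_strength

        mean[sl, sl] = block

    total = mean.sum()
    mean *= config.depth / total
    return mean


def simulate_contact_matrix(
    truth: SyntheticTruth,
    config: SimConfig,
    condition: str,
    replicate_seed: int | None = None,
) -> ContactMatrix:
    """Poisson-sample a symmetric integer count matrix for one condition."""
    if replicate_seed is None:
        replicate_seed = condition_seed(config.seed, condition)
    mean = noise_free_mean(truth, config, condition)
    rng = np.random.default_rng(replicate_seed)
    n = mean.shape[0]
    iu = np.triu_indices(n, k=0)
    lam = mean[iu].copy()
    # off-diagonal mass appears twice in the mean; sample the pair once
    off = iu[0] != iu[1]
    lam[off] *= 1.0  # upper-triangle mean as-is; symmetric mirror below
    draws = rng.poisson(lam)
    counts = sp.coo_matrix((draws, iu), shape=(n, n)).tocsr()
    counts = counts + sp.triu(counts, k=1).T
    counts.eliminate_zeros()
    return ContactMatrix(truth.bins, counts, config.bin_size_bp)


# ---------------------------------------------------------------------------
# Expression table and peaks
# ---------------------------------------------------------------------------

def simulate_expression_table(truth: SyntheticTruth, config: SimConfig) -> pd.DataFrame:
    """DE table matching the planted classes.

    down/up genes get |logFC| centered at ``de_logfc_mean`` with FDR < 0.05;
    stable genes sit near logFC 0 with large FDR; "other" genes are inactive
    (logCPM <= 0) so no thresholded class claims them.
    """
    rng = np.random.default_rng(config.seed + 777)
    genes = truth.genes
    n = len(genes)
    logfc = np.empty(n)
    logcpm = np.empty(n)
    fdr = np.empty(n)
    cls = genes["expr_class"].to_numpy()
    for i, c in enumerate(cls):
        if c == "down":
            logfc[i] = -abs(rng.normal(config.de_logfc_mean, config.de_logfc_sd))
            fdr[i] = rng.uniform(1e-6, 0.04)
            logcpm[i] = rng.uniform(0.5, 5.0)
        elif c == "up":
            logfc[i] = abs(rng.normal(config.de_logfc_mean, config.de_logfc_sd))
            fdr[i] = rng.uniform(1e-6, 0.04)
            logcpm[i] = rng.uniform(0.5, 5.0)
        elif c == "stable":
            logfc[i] = rng.normal(0.0, 0.1)
            fdr[i] = rng.uniform(0.1, 1.0)
            logcpm[i] = rng.uniform(0.5, 5.0)
        else:  # inactive
            logfc[i] = rng.normal(0.0, 1.0)
            fdr[i] = rng.uniform(0.05, 1.0)
            logcpm[i] = rng.uniform(-3.0, 0.0)
    out = genes[["chrom", "tss", "strand", "gene_id"]].copy()
    out["logFC"] = logfc
    out["logCPM"] = logcpm
    out["FDR"] = fdr
    return out


def simulate_peaks(truth: SyntheticTruth, config: SimConfig) -> PeakSet:
    """Promoter peaks for flagged genes plus decoys in gene deserts."""
    rng = np.random.default_rng(config.seed + 999)
    rows = []
    chrom_len = config.chrom_length_bp
    for _, g in truth.genes[truth.genes["has_promoter_peak"]].iterrows():
        center = int(g["tss"]) + int(rng.integers(-1000, 1001))
        half = int(rng.integers(200, 600))
        start = max(0, center - half)
        end = min(chrom_len, center + half)
        rows.append((g["chrom"], start, end))
    # decoys: away from every promoter
    tss_by_chrom = {
        chrom: truth.genes.loc[truth.genes["chrom"] == chrom, "tss"].to_numpy()
        for chrom in truth.bins.chrom_names
    }
    per_chrom = _split_counts(config.n_decoy_peaks, config.n_chromosomes)
    for ci, chrom in enumerate(truth.bins.chrom_names):
        tss = tss_by_chrom[chrom]
        placed = 0
        while placed < per_chrom[ci]:
            pos = int(rng.integers(10_000, chrom_len - 10_000))
            if tss.size and np.min(np.abs(tss - pos)) < 10_000:
                continue
            half = int(rng.integers(200, 600))
            rows.append((chrom, pos - half, pos + half))
            placed += 1
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    frame = frame.sort_values(["chrom", "start"]).reset_index(drop=True)
    frame["name"] = [f"peak_{i}" for i in range(len(frame))]
    frame["score"] = 1000
    frame["strand"] = "."
    frame["signal"] = rng.uniform(5.0, 50.0, size=len(frame)).round(3)
    frame["p"] = 5.0
    frame["q"] = 3.0
    frame["summit_offset"] = ((frame["end"] - frame["start"]) // 2).astype(int)
    return PeakSet(frame)


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, config: SimConfig, outdir) -> dict[str, Path]:
    """Write matrices for both conditions plus all truth tables; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for condition in _CONDITIONS:
        mat = simulate_contact_matrix(truth, config, condition)
        bp = outdir / f"bins_{condition}.tsv"
        cp = outdir / f"matrix_{condition}.coo.tsv"
        write_matrix(mat, bp, cp)
        paths[f"bins_{condition}"] = bp
        paths[f"matrix_{condition}"] = cp
    res = config.bin_size_bp
    loop_records = []
    for lp in truth.loops:
        loop_records.append(
            Loop(
                lp.chrom,
                lp.bin1 * res,
                (lp.bin1 + 1) * res,
                lp.chrom,
                lp.bin2 * res,
                (lp.bin2 + 1) * res,
                extra=(lp.membership, f"{lp.fold:g}"),
            )
        )
    paths["loops"] = outdir / "truth_loops.bedpe"
    write_bedpe(loop_records, paths["loops"])
    paths["genes"] = outdir / "genes.tsv"
    write_genes(simulate_expression_table(truth, config), paths["genes"])
    paths["peaks"] = outdir / "peaks.narrowPeak"
    write_narrowpeak(simulate_peaks(truth, config), paths["peaks"])
    labels = []
    for chrom in truth.bins.chrom_names:
        sl = truth.bins.chrom_slice(chrom)
        for i in range(sl.stop - sl.start):
            labels.append(
                (
                    chrom,
                    i * res,
                    (i + 1) * res,
                    truth.compartment_label[chrom]["A"][i],
                    truth.compartment_label[chrom]["B"][i],
                    truth.switch_category[chrom][i],
                )
            )
    pd.DataFrame(
        labels, columns=["chrom", "start", "end", "label_A", "label_B", "switch"]
    ).to_csv(outdir / "truth_compartments.tsv", sep="\t", index=False)
    paths["compartments"] = outdir / "truth_compartments.tsv"
    tadrows = [
        (chrom, int(b))
        for chrom in truth.bins.chrom_names
        for b in truth.tad_boundaries[chrom]
    ]
    pd.DataFrame(tadrows, columns=["chrom", "boundary_bin"]).to_csv(
        outdir / "truth_boundaries.tsv", sep="\t", index=False
    )
    paths["boundaries"] = outdir / "truth_boundaries.tsv"
    return paths
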