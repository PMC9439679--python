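"""integrate: gene classes, promoter annotation, occupancy, pile-ups."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from loopdelta.errors import StateError, ValidationError
from loopdelta.integrate import (
    annotate_promoter_loops,
    classify_genes,
    pileup_dots,
    pileup_tss,
    promoter_peak_overlap,
    sample_stable_genes,
    stratified_loop_scores,
)
from loopdelta.matrixio import Loop, PeakSet, balance
from loopdelta.simulate import (
    simulate_contact_matrix,
    simulate_expression_table,
    simulate_peaks,
    simulate_truth,
)
from tests.conftest import decay_only_config


def de_row(logfc, fdr, logcpm):
    return {"gene_id": "g", "chrom": "chr1", "tss": 0, "strand": "+",
            "logFC": logfc, "FDR": fdr, "logCPM": logcpm}


def peaks_from_intervals(intervals):
    frame = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    frame["name"] = "pk"
    frame["score"] = 0
    frame["strand"] = "."
    frame["signal"] = 1.0
    frame["p"] = 1.0
    frame["q"] = 1.0
    frame["summit_offset"] = -1
    return PeakSet(frame)


class TestClassifyGenes:
    @pytest.mark.parametrize(
        "logfc,fdr,logcpm,expected",
        [
            (-1.0, 0.01, 1.2, "down"),
            (1.0, 0.01, 1.2, "up"),
            (0.2, 0.9, 0.5, "stable"),
            (2.0, 0.2, 1.0, "other"),  # fails FDR gate, exceeds stable band
            (-0.3, 0.01, 1.0, "stable"),  # significant but small effect
            (0.2, 0.9, -0.5, "other"),  # inactive
        ],
    )
    def test_worked_examples(self, logfc, fdr, logcpm, expected):
        out = classify_genes(pd.DataFrame([de_row(logfc, fdr, logcpm)]))
        assert out.loc[0, "expr_class"] == expected

    def test_partition(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            [de_row(rng.normal(0, 1), rng.uniform(), rng.normal(0.5, 1))
             for _ in range(200)]
        )
        out = classify_genes(table)
        counts = out["expr_class"].value_counts()
        assert counts.sum() == 200
        assert set(counts.index) <= {"down", "up", "stable", "other"}

    def test_missing_column(self):
        with pytest.raises(ValidationError, match="logCPM"):
            classify_genes(pd.DataFrame({"logFC": [1.0], "FDR": [0.5]}))


class TestSampleStable:
    def _genes(self, n):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "expr_class": ["stable"] * n,
            }
        )

    def test_deterministic(self):
        genes = self._genes(1500)
        s1 = sample_stable_genes(genes, n=1000, seed=7)
        s2 = sample_stable_genes(genes, n=1000, seed=7)
        assert list(s1["gene_id"]) == list(s2["gene_id"])
        assert len(s1) == 1000

    def test_fewer_than_n_returns_all_with_warning(self):
        genes = self._genes(800)
        with pytest.warns(UserWarning, match="800"):
            out = sample_stable_genes(genes, n=1000, seed=0)
        assert len(out) == 800

    def test_subset_of_stable(self):
        genes = pd.concat(
            [self._genes(50), pd.DataFrame({"gene_id": ["x"], "expr_class": ["up"]})]
        )
        out = sample_stable_genes(genes, n=10, seed=1)
        assert set(out["gene_id"]) <= set(f"g{i}" for i in range(50))


class TestPromoterLoops:
    def _gene(self, tss, strand="+"):
        return pd.DataFrame(
            [{"gene_id": "g1", "chrom": "chr1", "tss": tss, "strand": strand,
              "expr_class": "down"}]
        )

    def test_anchor_overlapping_promoter(self):
        lp = Loop("chr1", 95_000, 105_000, "chr1", 400_000, 410_000)
        ann = annotate_promoter_loops([lp], self._gene(100_000))
        assert list(ann["gene_id"]) == ["g1"]
        assert list(ann["anchor"]) == [1]

    def test_anchor_not_overlapping(self):
        lp = Loop("chr1", 110_000, 120_000, "chr1", 400_000, 410_000)
        ann = annotate_promoter_loops([lp], self._gene(100_000))
        assert ann.empty

    def test_minus_strand_window_centered_on_tss(self):
        lp = Loop("chr1", 95_000, 105_000, "chr1", 400_000, 410_000)
        ann = annotate_promoter_loops([lp], self._gene(100_000, strand="-"))
        assert len(ann) == 1

    def test_anchor_swap_symmetric(self):
        genes = self._gene(405_000)
        l1 = Loop("chr1", 95_000, 105_000, "chr1", 400_000, 410_000)
        ann = annotate_promoter_loops([l1], genes)
        assert set(ann["gene_id"]) == {"g1"}
        assert list(ann["anchor"]) == [2]


class TestPromoterPeakOverlap:
    def test_overlap_flagged(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "chr1", "tss": 100_000,
              "expr_class": "down"}]
        )
        pk = peaks_from_intervals([("chr1", 99_500, 100_400)])
        out, frac = promoter_peak_overlap(genes, pk)
        assert bool(out.loc[0, "promoter_peak"]) is True
        assert frac.loc[frac["expr_class"] == "down", "fraction"].iloc[0] == 1.0

    def test_boundary_touch_not_flagged(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "chr1", "tss": 100_000,
              "expr_class": "down"}]
        )
        # promoter window is [98_000, 102_000); a peak ending at 98_000 or
        # starting at 102_000 touches but does not overlap
        for iv in [("chr1", 97_000, 98_000), ("chr1", 102_000, 103_000)]:
            out, _ = promoter_peak_overlap(genes, peaks_from_intervals([iv]))
            assert bool(out.loc[0, "promoter_peak"]) is False

    def test_recovered_occupancy_fraction(self, truth, default_config, peaks):
        genes = truth.genes.copy()
        out, frac = promoter_peak_overlap(genes, peaks)
        down = frac[frac["expr_class"] == "down"].iloc[0]
        planted = truth.genes[truth.genes["expr_class"] == "down"][
            "has_promoter_peak"
        ].mean()
        # called fraction can exceed planted (decoys/nearby promoters) but
        # must match within sampling error
        assert down["fraction"] == pytest.approx(planted, abs=0.1)


class TestStratifiedScores:
    def _p_loops(self, scores, cls="down", gene="g1"):
        return pd.DataFrame(
            {
                "loop_index": range(len(scores)),
                "gene_id": [gene] * len(scores),
                "expr_class": [cls] * len(scores),
                "score": scores,
            }
        )

    def _genes(self):
        return pd.DataFrame(
            {"gene_id": ["g1", "g2"], "promoter_peak": [True, False]}
        )

    def test_identical_multisets_p_one(self):
        pl = pd.concat(
            [
                self._p_loops([1.0, 2.0, 3.0], "down", "g1"),
                self._p_loops([1.0, 2.0, 3.0], "stable", "g2"),
            ]
        )
        summary, tests = stratified_loop_scores(pl, self._genes())
        assert tests["p_value"].iloc[0] == pytest.approx(1.0)

    def test_small_stratum_skipped(self):
        pl = pd.concat(
            [
                self._p_loops([1.0, 2.0, 3.0], "down", "g1"),
                self._p_loops([5.0], "stable", "g2"),
            ]
        )
        _, tests = stratified_loop_scores(pl, self._genes())
        assert tests["skipped"].iloc[0]

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(3)
        strong = self._p_loops(rng.normal(4.0, 0.5, 25), "down", "g1")
        weak = self._p_loops(rng.normal(2.0, 0.5, 25), "stable", "g2")
        summary, tests = stratified_loop_scores(pd.concat([strong, weak]), self._genes())
        med = summary.set_index(["expr_class", "promoter_peak"])["median_score"]
        assert med[("down", True)] > med[("stable", False)]
        assert tests["p_value"].iloc[0] < 0.05


class TestPileupDots:
    def test_null_enrichment_near_one(self, null_matrix):
        m, cfg = null_matrix
        rng = np.random.default_rng(2)
        loci = [
            (int(b), int(b) + int(d))
            for b, d in zip(rng.integers(100, 1700, 50), rng.integers(25, 90, 50))
        ]
        res = pileup_dots(m, loci, seed=3)
        assert res.central_enrichment == pytest.approx(1.0, abs=0.1)

    def test_planted_dots_enriched_and_monotone(self):
        enrich = []
        for strength in (3.0, 6.0):
            cfg = decay_only_config(
                seed=8, n_loops_shared=10, loop_strength=strength,
            )
            truth = simulate_truth(cfg)
            m = balance(simulate_contact_matrix(truth, cfg, "A", 55))
            loci = [(lp.bin1, lp.bin2) for lp in truth.loops]
            res = pileup_dots(m, loci, seed=4)
            enrich.append(res.central_enrichment)
        assert enrich[0] > 1.5
        assert enrich[1] > enrich[0]

    def test_corner_zero_error(self):
        from tests.test_matrixio import make_matrix

        dense = np.zeros((100, 100))
        dense[40, 60] = dense[60, 40] = 5.0
        m = make_matrix(dense)
        m.weights = np.ones(100)
        with pytest.raises(StateError, match="corner"):
            pileup_dots(m, [(40, 60)], pad_bins=5, seed=0)

    def test_edge_locus_skipped(self, null_matrix):
        m, _ = null_matrix
        res = pileup_dots(m, [(2, 40), (500, 560)], pad_bins=10, seed=0)
        assert res.n_skipped == 1
        assert res.n_windows == 1

    def test_scale_invariance(self, null_matrix):
        m, _ = null_matrix
        loci = [(300, 350), (800, 870)]
        r1 = pileup_dots(m, loci, seed=5)
        import copy

        m2 = copy.copy(m)
        m2.weights = m.weights * 3.0  # scales balanced matrix by 9x
        r2 = pileup_dots(m2, loci, seed=5)
        assert r2.central_enrichment == pytest.approx(r1.central_enrichment, rel=1e-9)


class TestPileupTss:
    def test_stripe_genes_detected(self, truth, default_config, matrix_a):
        stripes = truth.genes[truth.genes["has_stripe"]]
        stable = truth.genes[
            (truth.genes["expr_class"] == "stable") & ~truth.genes["has_stripe"]
        ]
        s_res = pileup_tss(matrix_a, stripes, seed=6)
        st_res = pileup_tss(matrix_a, stable, seed=6)
        assert s_res.stripe_score > 1.5
        assert st_res.stripe_score == pytest.approx(1.0, abs=0.15)

    def test_strand_reversal_inverts_score(self, truth, default_config, matrix_a):
        stripes = truth.genes[truth.genes["has_stripe"]]
        fwd = pileup_tss(matrix_a, stripes, seed=7)
        rev = stripes.copy()
        rev["strand"] = rev["strand"].map({"+": "-", "-": "+"})
        bwd = pileup_tss(matrix_a, rev, seed=7)
        assert bwd.stripe_score == pytest.approx(1.0 / fwd.stripe_score, rel=0.05)

    def test_symmetric_matrix_score_one(self, null_matrix):
        m, cfg = null_matrix
        truth = simulate_truth(dataclasses.replace(cfg, seed=31))
        genes = truth.genes.head(40)
        res = pileup_tss(m, genes, seed=8)
        assert res.stripe_score == pytest.approx(1.0, abs=0.1)

    def test_unstranded_gene_error(self, matrix_a):
        genes = pd.DataFrame(
            [{"gene_id": "gX", "chrom": "chr1", "tss": 5_000_000, "strand": "."}]
        )
        with pytest.raises(ValidationError, match="gX"):
            pileup_tss(matrix_a, genes)

    def test_diagonal_omitted(self, truth, matrix_a):
        res = pileup_tss(matrix_a, truth.genes.head(20), seed=9)
        assert np.isnan(np.diagonal(res.mean_map)).all()


class TestEndToEndPattern:
    def test_downgene_enrichment_drops_a_to_b(self, default_config):
        cfg = dataclasses.replace(default_config, n_loops_A_only=10, seed=2)
        truth = simulate_truth(cfg)
        ma = balance(simulate_contact_matrix(truth, cfg, "A"))
        mb = balance(simulate_contact_matrix(truth, cfg, "B"))
        loci = [(lp.bin1, lp.bin2) for lp in truth.loops if lp.membership == "A"]
        down_a = pileup_dots(ma, loci, seed=1).central_enrichment
        down_b = pileup_dots(mb, loci, seed=1).central_enrichment
        stable_bins = truth.genes.loc[
            truth.genes["expr_class"] == "stable", "tss_bin"
        ].to_numpy()[:20]
        dists = [lp.bin2 - lp.bin1 for lp in truth.loops if lp.membership == "A"]
        loci_s = [
            (int(b), int(b) + int(dists[i % len(dists)]))
            for i, b in enumerate(stable_bins)
        ]
        stable_a = pileup_dots(ma, loci_s, seed=1).central_enrichment
        stable_b = pileup_dots(mb, loci_s, seed=1).central_enrichment
        assert down_a > 2.0 * down_b
        assert stable_a == pytest.approx(stable_b, abs=0.35)
        assert abs(stable_a - stable_b) < (down_a - down_b) / 3
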