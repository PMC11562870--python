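"""Mark-to-gene assignment, bivalency, tissue-specific chromatin,
enhancer-target pairing and the transcribed x mark cross-tabulation."""

import numpy as np
import pandas as pd
import pytest

from epimark.core_io import DETable, GeneModel, GenomicInterval, Peak
from epimark.integration import (
    GeneChromatinState,
    assign_marks_to_genes,
    bivalent_loci,
    enhancer_target_pairs,
    mark_state_crosstab,
    tissue_specific_chromatin,
)


def gene(gid, start, end, strand="+", chrom="c"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand, gid))


def peak(start, end, mark=None, tissue=None, chrom="c"):
    return Peak(GenomicInterval(chrom, start, end), mark=mark, tissue=tissue, score=1.0)


class TestAssignMarks:
    def test_bivalent_flag_from_both_marks(self):
        g = gene("g1", 10_000, 16_000)
        by_mark = {
            "H3K4me3": [peak(9_500, 10_500)],  # over TSS
            "H3K27me3": [peak(12_000, 15_000)],  # over body
            "H3K56ac": [],
            "H2A.Z": [],
        }
        (state,) = assign_marks_to_genes([g], by_mark)
        assert state.marks_present == frozenset({"H3K4me3", "H3K27me3"})
        assert state.bivalent

    def test_no_peaks_no_marks(self):
        (state,) = assign_marks_to_genes([gene("g1", 0, 5000)], {m: [] for m in ("H3K4me3",)})
        assert state.marks_present == frozenset() and not state.bivalent

    def test_promoter_extension_is_strand_aware(self):
        gp = gene("gp", 10_000, 16_000, "+")
        gm = gene("gm", 30_000, 36_000, "-")
        upstream_of_plus = [peak(9_200, 9_900)]
        downstream_of_minus = [peak(36_100, 36_800)]
        states = assign_marks_to_genes([gp, gm], {"H3K4me3": upstream_of_plus + downstream_of_minus})
        assert all("H3K4me3" in s.marks_present for s in states)
        # the same windows do NOT extend on the opposite side
        states2 = assign_marks_to_genes([gp, gm], {"H3K4me3": [peak(16_100, 16_800)]})
        assert all("H3K4me3" not in s.marks_present for s in states2)

    def test_allpairs_oracle(self):
        rng = np.random.default_rng(6)
        genes = [
            gene(f"g{i}", int(p), int(p) + 3000, "+" if rng.random() < 0.5 else "-")
            for i, p in enumerate(sorted(rng.choice(480_000, 60, replace=False) * 2))
        ]
        peaks = [peak(int(s), int(s) + int(rng.integers(200, 4000))) for s in rng.integers(0, 990_000, 150)]
        states = assign_marks_to_genes(genes, {"H3K4me3": peaks})
        for g, s in zip(genes, states):
            if g.interval.strand == "+":
                lo, hi = g.interval.start - 1000, g.interval.end
            else:
                lo, hi = g.interval.start, g.interval.end + 1000
            expected = any(p.start < hi and lo < p.end for p in peaks)
            assert ("H3K4me3" in s.marks_present) == expected

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            GeneChromatinState("g", "trichome", True, frozenset({"H3K4me3"}), bivalent=True)


class TestBivalentLoci:
    def test_disjoint_sets(self):
        frags, count = bivalent_loci([peak(0, 100)], [peak(500, 600)])
        assert frags == [] and count == 0

    def test_nested_pair_fragment(self):
        frags, count = bivalent_loci([peak(0, 1000)], [peak(200, 300)])
        assert frags == [GenomicInterval("c", 200, 300)] and count == 1

    def test_clean_bundle_exact_recovery(self, clean_bundle):
        b = clean_bundle
        k4 = b.peaks[("trichome", "H3K4me3", 1)]
        k27 = b.peaks[("trichome", "H3K27me3", 1)]
        genes = {g.gene_id: g for g in b.genes}
        states = assign_marks_to_genes(
            b.genes, {"H3K4me3": k4, "H3K27me3": k27}
        )
        predicted = {s.gene_id for s in states if s.bivalent}
        assert predicted == b.manifest.bivalent_genes


class TestTissueSpecificChromatin:
    def test_shared_peak_excluded(self):
        shared = peak(0, 1000, tissue="trichome")
        only = peak(50_000, 51_000, tissue="trichome")
        by_tissue = {
            "trichome": [shared, only],
            "stem": [peak(100, 900, tissue="stem")],
            "leaf": [],
        }
        got = tissue_specific_chromatin("H3K56ac", by_tissue, "trichome")
        assert [p.interval for p in got] == [only.interval]
        assert got[0].replicate == "consolidated" and got[0].tissue == "trichome"

    def test_missing_target_rejected(self):
        with pytest.raises(ValueError):
            tissue_specific_chromatin("H3K4me3", {"stem": []}, "trichome")


def _de_tables(genes_pass):
    rows_s, rows_l = [], []
    for gid, passes in genes_pass.items():
        lfc = 5.0 if passes else 0.5
        padj = 1e-6 if passes else 0.9
        rows_s.append((gid, lfc, padj / 10, padj))
        rows_l.append((gid, lfc, padj / 10, padj))
    cols = ["gene_id", "log2fc", "pvalue", "padj"]
    return [
        DETable("trichome_vs_stem", pd.DataFrame(rows_s, columns=cols)),
        DETable("trichome_vs_leaf", pd.DataFrame(rows_l, columns=cols)),
    ]


class TestEnhancerTargets:
    def setup_method(self):
        self.genes = [gene("gA", 100_000, 105_000, "+"), gene("gB", 200_000, 205_000, "+")]

    def test_proximal_locus_rejected(self):
        # midpoint 100,800: 800 bp from gA's TSS
        locus = peak(100_300, 101_300)
        pairs, rejects = enhancer_target_pairs(
            [locus], self.genes, {"gA"}, _de_tables({"gA": True, "gB": True})
        )
        assert pairs == [] and rejects["reason"].tolist() == ["proximal"]

    def test_distal_de_pair_emitted(self):
        locus = peak(89_500, 90_500)  # midpoint 90,000 -> 10 kb from gA TSS
        (pair,), rejects = enhancer_target_pairs(
            [locus], self.genes, {"gA"}, _de_tables({"gA": True, "gB": True})
        )
        assert pair.gene_id == "gA" and pair.distance == 10_000
        assert pair.de_stats["trichome_vs_stem"] == (5.0, 1e-6)
        assert not pair.intragenic

    def test_nearest_gene_not_de_rejected_with_reason(self):
        locus = peak(89_500, 90_500)
        pairs, rejects = enhancer_target_pairs(
            [locus], self.genes, {"gB"}, _de_tables({"gB": True})
        )
        assert pairs == []
        assert rejects.iloc[0]["reason"] == "nearest_gene_not_de"
        assert rejects.iloc[0]["nearest_gene"] == "gA"

    def test_intragenic_flag(self):
        # locus inside gB's body, nearest TSS is still gB but > 1.5 kb away
        locus = peak(203_000, 203_400)
        (pair,), _ = enhancer_target_pairs(
            [locus], self.genes, {"gB"}, _de_tables({"gB": True})
        )
        assert pair.intragenic

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            pairs, rejects = enhancer_target_pairs([], self.genes, set(), _de_tables({}))
        assert pairs == [] and len(rejects) == 0

    def test_emitted_genes_pass_filter_and_loci_are_distal(self, clean_bundle):
        from epimark.expression_enrichment import filter_tissue_specific_de, simple_de
        from epimark.integration import tissue_specific_chromatin
        from epimark import interval_algebra as ia

        b = clean_bundle
        by_tissue = {t: b.peaks[(t, "H3K56ac", 1)] for t in ("trichome", "stem", "leaf")}
        specific = tissue_specific_chromatin("H3K56ac", by_tissue, "trichome")
        de_s = simple_de(b.expression, "trichome", "stem")
        de_l = simple_de(b.expression, "trichome", "leaf")
        de_set = filter_tissue_specific_de(de_s, de_l)
        pairs, _ = enhancer_target_pairs(specific, b.genes, de_set, [de_s, de_l])
        assert all(p.gene_id in de_set for p in pairs)
        distal, _ = ia.distal_filter([p.locus for p in pairs], b.genes, 1500)
        assert len(distal) == len(pairs)
        # noise-free recovery of the planted pairs is exact
        truth = {(g, iv.start) for g, iv, _ in b.manifest.enhancer_pairs}
        assert {(p.gene_id, p.locus.start) for p in pairs} == truth


class TestCrosstab:
    def test_saturated_cell(self):
        states = [
            GeneChromatinState(f"g{i}", "trichome", True, frozenset({"H3K4me3"}), False)
            for i in range(7)
        ]
        tab = mark_state_crosstab(states)
        assert tab.loc["transcribed", "H3K4me3"] == 7
        assert tab.loc["untranscribed"].sum() == 0

    def test_empty(self):
        tab = mark_state_crosstab([])
        assert (tab.to_numpy() == 0).all()

    def test_tally_oracle(self):
        rng = np.random.default_rng(10)
        marks = ("H3K4me3", "H3K56ac", "H3K27me3", "H2A.Z")
        states = []
        for i in range(200):
            present = frozenset(m for m in marks if rng.random() < 0.4)
            biv = {"H3K4me3", "H3K27me3"} <= set(present)
            states.append(
                GeneChromatinState(f"g{i}", "trichome", bool(rng.random() < 0.5), present, biv)
            )
        tab = mark_state_crosstab(states)
        for status, row in (("transcribed", True), ("untranscribed", False)):
            sub = [s for s in states if s.transcribed == row]
            assert tab.loc[status, "n_genes"] == len(sub)
            for m in marks:
                assert tab.loc[status, m] == sum(m in s.marks_present for s in sub)
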