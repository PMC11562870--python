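"""Interval set operations against per-base bitmap / all-pairs oracles, and
exact-test behaviour of the Fisher co-localization machinery."""

from math import comb

import numpy as np
import pytest

from epimark import interval_algebra as ia
from epimark.core_io import GeneModel, GenomicInterval, Peak

from conftest import random_intervals

GENOME = 1_000_000


def bitmap(intervals, size=GENOME):
    bm = np.zeros(size, bool)
    for iv in intervals:
        bm[iv.start : iv.end] = True
    return bm


def fisher_enum(n11, n12, n21, n22):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, r2, c1 = n11 + n12, n21 + n22, n11 + n21
    N = r1 + r2
    denom = comb(N, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    p0 = probs[n11]
    return sum(p for p in probs.values() if p <= p0 * (1 + 1e-7))


class TestMerge:
    def test_overlapping_and_adjacent(self):
        got = ia.merge_intervals(
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 15), GenomicInterval("c", 15, 20)]
        )
        assert got == [GenomicInterval("c", 0, 20)]

    def test_empty(self):
        assert ia.merge_intervals([]) == []

    def test_bitmap_oracle(self):
        rng = np.random.default_rng(1)
        ivs = random_intervals(rng, 1000)
        merged = ia.merge_intervals(ivs)
        assert np.array_equal(bitmap(merged), bitmap(ivs))
        # sorted and disjoint
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start


class TestIntersectSubtract:
    def test_reciprocal_threshold(self):
        A = [GenomicInterval("c", 0, 100)]
        B = [GenomicInterval("c", 0, 10)]
        assert ia.intersect(A, B, min_frac_a=0.3, reciprocal=True) == []
        assert ia.intersect(A, B) == A

    def test_fragment_mode(self):
        A = [GenomicInterval("c", 0, 10)]
        B = [GenomicInterval("c", 5, 8)]
        assert ia.intersect(A, B, mode="fragment") == [GenomicInterval("c", 5, 8)]

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            ia.intersect([], [], min_frac_a=1.5)

    @pytest.mark.parametrize("fa,fb,recip", [(0, 0, False), (0.3, 0, False), (0.3, 0.3, False), (0.3, 0, True)])
    def test_allpairs_oracle(self, fa, fb, recip):
        rng = np.random.default_rng(7)
        A = random_intervals(rng, 500, chroms=("chr1", "chr2"))
        B = random_intervals(rng, 500, chroms=("chr1", "chr2"))
        got = ia.intersect(A, B, fa, fb, reciprocal=recip)
        fb_eff = max(fb, fa) if recip else fb
        expected = []
        for a in A:
            for b in B:
                ov = a.overlap_len(b)
                if ov > 0 and ov >= fa * len(a) and ov >= fb_eff * len(b):
                    expected.append(a)
                    break
        assert got == expected

    def test_subtract_allpairs_oracle(self):
        rng = np.random.default_rng(9)
        A = random_intervals(rng, 500)
        B = random_intervals(rng, 500)
        got = ia.subtract_exclusive(A, B)
        expected = [a for a in A if not any(a.overlaps(b) for b in B)]
        assert got == expected
        assert ia.subtract_exclusive(A, []) == A

    def test_subtract_and_intersect_partition(self):
        rng = np.random.default_rng(13)
        A = random_intervals(rng, 300)
        B = random_intervals(rng, 300)
        kept = ia.intersect(A, B, mode="whole_a")
        dropped = ia.subtract_exclusive(A, B)
        assert sorted(kept + dropped, key=lambda iv: (iv.chrom, iv.start, iv.end)) == sorted(
            A, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )


class TestTissueSpecific:
    def test_planted_example(self):
        p1 = GenomicInterval("c", 0, 100)
        p2 = GenomicInterval("c", 1000, 1100)
        stem = [GenomicInterval("c", 50, 60)]
        leaf = []
        assert ia.tissue_specific([p1, p2], [stem, leaf]) == [p2]
        assert ia.tissue_specific([p1, p2], [[], []]) == [p1, p2]
        with pytest.raises(ValueError):
            ia.tissue_specific([p1], [])


def _genes(positions, chrom="c", strand="+"):
    out = []
    for i, pos in enumerate(positions):
        out.append(GeneModel(f"g{i:03d}", GenomicInterval(chrom, pos, pos + 2000, strand)))
    return out


class TestNearestTssDistal:
    def test_midpoint_anchor(self):
        genes = _genes([4000, 6001])
        peak = GenomicInterval("c", 4900, 5100)  # midpoint 5000
        gid, d = ia.nearest_tss(peak, genes)
        assert gid == "g000" and d == 1000

    def test_tss_inside_peak_edges_anchor(self):
        genes = _genes([1500])
        peak = GenomicInterval("c", 1000, 2000)
        _, d = ia.nearest_tss(peak, genes, anchor="edges")
        assert d == 0

    def test_no_gene_on_chromosome(self):
        with pytest.raises(ValueError, match="chrX"):
            ia.nearest_tss(GenomicInterval("chrX", 0, 10), _genes([100]))

    def test_distal_boundary(self):
        genes = _genes([0])
        proximal = GenomicInterval("c", 900, 1100)  # midpoint 1000 <= 1500
        distal = GenomicInterval("c", 1401, 1601)  # midpoint 1501 > 1500
        kept, _ = ia.distal_filter([proximal, distal], genes)
        assert kept == [distal]

    def test_exhaustive_oracle(self):
        rng = np.random.default_rng(21)
        genes = _genes(sorted(rng.choice(900_000, 50, replace=False)), chrom="chr1")
        peaks = random_intervals(rng, 200)
        for p in peaks:
            gid, d = ia.nearest_tss(p, genes)
            dists = {g.gene_id: abs(g.tss - p.midpoint) for g in genes}
            best = min(dists.values())
            assert d == best and gid == min(g for g, v in dists.items() if v == best)
        kept, _ = ia.distal_filter(peaks, genes, 1500)
        expected = [p for p in peaks if min(abs(g.tss - p.midpoint) for g in genes) > 1500]
        assert kept == expected

    def test_distal_zero_partitions(self):
        rng = np.random.default_rng(5)
        genes = _genes(sorted(rng.choice(900_000, 20, replace=False)), chrom="chr1")
        peaks = random_intervals(rng, 100)
        kept, _ = ia.distal_filter(peaks, genes, 0)
        comp = [p for p in peaks if p not in kept]
        assert len(kept) + len(comp) == len(peaks)
        for p in comp:
            assert min(abs(g.tss - p.midpoint) for g in genes) == 0


class TestFeatureDistribution:
    def test_promoter_upstream_plus(self):
        genes = [GeneModel("g", GenomicInterval("c", 10_000, 15_000, "+"))]
        peak = GenomicInterval("c", 9400, 9600)  # midpoint 9500, 500 bp upstream
        assert ia.classify_peak(peak, genes) == "promoter"

    def test_gene_free_chromosome_is_intergenic(self):
        dist = ia.feature_distribution([GenomicInterval("chrZ", 0, 100)], _genes([0]))
        assert dist.counts["intergenic"] == 1

    def test_per_peak_oracle_and_fractions(self):
        rng = np.random.default_rng(3)
        genes = []
        for i, pos in enumerate(sorted(rng.choice(900_000, 40, replace=False))):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{i}", GenomicInterval("chr1", pos, pos + 3000, strand)))
        peaks = random_intervals(rng, 500)
        dist = ia.feature_distribution(peaks, genes)
        oracle = {k: 0 for k in ia.FEATURE_CLASSES}
        for p in peaks:
            oracle[ia.classify_peak(p, genes)] += 1
        assert dist.counts == oracle
        assert sum(dist.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert dist.total == 500


class TestFisher:
    def test_symmetric_table(self):
        p, odds = ia.fisher_exact_2x2(ia.ContingencyTable2x2(1, 1, 1, 1))
        assert p == pytest.approx(1.0) and odds == pytest.approx(1.0)

    def test_three_one_table(self):
        p, _ = ia.fisher_exact_2x2(ia.ContingencyTable2x2(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ia.ContingencyTable2x2(0, 0, 0, 0)

    def test_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            cells = rng.integers(0, 30, 4)
            if cells.sum() == 0:
                cells[0] = 1
            t = ia.ContingencyTable2x2(*map(int, cells))
            p, _ = ia.fisher_exact_2x2(t)
            assert p == pytest.approx(fisher_enum(*map(int, cells)), abs=1e-12)
            assert 0 < p <= 1

    def test_continuity_odds(self):
        _, odds = ia.fisher_exact_2x2(ia.ContingencyTable2x2(3, 0, 1, 3), continuity=True)
        assert odds == pytest.approx((3.5 * 3.5) / (0.5 * 1.5))


class TestColocalization:
    def test_identical_sets(self):
        rng = np.random.default_rng(2)
        A = random_intervals(rng, 50)
        table, p, _ = ia.colocalization_fisher(A, A, GENOME)
        assert table.n12 == 0 and table.n21 == 0 and table.n22 > 0
        assert p < 1e-10

    def test_disjoint_chromosomes(self):
        A = [GenomicInterval("chr1", 0, 100)]
        B = [GenomicInterval("chr2", 0, 100)]
        table, _, _ = ia.colocalization_fisher(A, B, GENOME)
        assert table.n11 == 0

    def test_genome_too_small(self):
        A = [GenomicInterval("chr1", 0, 600)]
        with pytest.raises(ValueError):
            ia.colocalization_fisher(A, A, 500)

    def test_monotone_in_overlap_fraction(self):
        rng = np.random.default_rng(23)
        n = 200
        starts = np.sort(rng.choice(GENOME // 1000 - 2, n, replace=False)) * 1000
        A = [GenomicInterval("chr1", int(s), int(s) + 500) for s in starts]
        pvals = []
        for frac in (0.0, 0.3, 0.6, 0.9):
            n_shared = int(frac * n)
            B = [GenomicInterval("chr1", iv.start, iv.end) for iv in A[:n_shared]]
            for s in starts[n_shared:]:
                B.append(GenomicInterval("chr1", int(s) + 600, int(s) + 900))
            _, p, _ = ia.colocalization_fisher(A, B, GENOME)
            pvals.append(p)
        assert all(b <= a * (1 + 1e-9) for a, b in zip(pvals, pvals[1:]))
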