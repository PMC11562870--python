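"""Set operations, distance queries and co-localization statistics on intervals.

These routines are the computational core of the pipeline: merging,
BEDTools-style intersect/subtract with (reciprocal) overlap fractions,
nearest-TSS queries, distal filtering, feature classification and the Fisher
co-localization test. Inputs are ``GenomicInterval``/``Peak`` collections;
peaks are accepted anywhere intervals are and their interval is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import GeneModel, GenomicInterval, Peak

__all__ = [
    "ContingencyTable2x2",
    "FeatureClassCounts",
    "merge_intervals",
    "intersect",
    "subtract_exclusive",
    "tissue_specific",
    "nearest_tss",
    "distal_filter",
    "feature_distribution",
    "fisher_exact_2x2",
    "colocalization_fisher",
]

FEATURE_CLASSES = ("promoter", "gene_body", "tts_flank", "intergenic")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (overlapping; A-only; B-only; neither) for a co-localization test."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self):
        cells = (self.n11, self.n12, self.n21, self.n22)
        if any(c < 0 for c in cells):
            raise ValueError("negative contingency cell")
        if sum(cells) == 0:
            raise ValueError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]])


@dataclass(frozen=True)
class FeatureClassCounts:
    """Peak counts and fractions over promoter / gene body / TTS flank / intergenic."""

    counts: dict

    def __post_init__(self):
        if set(self.counts) != set(FEATURE_CLASSES):
            raise ValueError(f"counts must cover exactly {FEATURE_CLASSES}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative class count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict:
        t = self.total
        if t == 0:
            return {k: 0.0 for k in FEATURE_CLASSES}
        return {k: self.counts[k] / t for k in FEATURE_CLASSES}


def _iv(x) -> GenomicInterval:
    return x.interval if isinstance(x, Peak) else x


def _by_chrom(items: Iterable) -> dict[str, list]:
    out: dict[str, list] = {}
    for x in items:
        out.setdefault(_iv(x).chrom, []).append(x)
    return out


def _sorted_arrays(intervals: Sequence) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) sorted by start."""
    grouped = _by_chrom(intervals)
    out = {}
    for chrom, items in grouped.items():
        s = np.array([_iv(x).start for x in items])
        e = np.array([_iv(x).end for x in items])
        order = np.lexsort((e, s))
        out[chrom] = (s[order], e[order])
    return out


def merge_intervals(intervals: Sequence) -> list[GenomicInterval]:
    """Union of intervals: sorted, non-overlapping; book-ended spans are merged."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        s, e = _sorted_arrays(intervals)[chrom]
        cur_s, cur_e = int(s[0]), int(e[0])
        for i in range(1, len(s)):
            if s[i] <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, int(e[i]))
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = int(s[i]), int(e[i])
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def _overlap_candidates(a: GenomicInterval, starts: np.ndarray, ends: np.ndarray):
    """Indices of sorted B intervals overlapping a (starts sorted ascending)."""
    hi = int(np.searchsorted(starts, a.end, side="left"))
    idx = np.nonzero(ends[:hi] > a.start)[0]
    return idx


def _qualifies(a: GenomicInterval, b_start: int, b_end: int, min_frac_a: float, min_frac_b: float) -> bool:
    ov = min(a.end, b_end) - max(a.start, b_start)
    if ov <= 0:
        return False
    if ov < min_frac_a * len(a):
        return False
    if ov < min_frac_b * (b_end - b_start):
        return False
    return True


def intersect(
    A: Sequence,
    B: Sequence,
    min_frac_a: float = 0.0,
    min_frac_b: float = 0.0,
    reciprocal: bool = False,
    mode: str = "whole_a",
) -> list:
    """BEDTools-style intersection of A against B.

    mode ``whole_a`` returns each A element with at least one qualifying
    overlap, once, in input order; mode ``fragment`` returns the overlap
    segments. With ``reciprocal=True`` the A-fraction threshold is applied to
    both sides (``-f x -r``).
    """
    for f in (min_frac_a, min_frac_b):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"overlap fraction {f} outside [0, 1]")
    if mode not in ("whole_a", "fragment"):
        raise ValueError(f"unknown mode {mode!r}")
    if reciprocal:
        min_frac_b = max(min_frac_b, min_frac_a)
    b_arrays = _sorted_arrays(B)
    out = []
    for a in A:
        aiv = _iv(a)
        if aiv.chrom not in b_arrays:
            continue
        starts, ends = b_arrays[aiv.chrom]
        hits = _overlap_candidates(aiv, starts, ends)
        if mode == "whole_a":
            for i in hits:
                if _qualifies(aiv, int(starts[i]), int(ends[i]), min_frac_a, min_frac_b):
                    out.append(a)
                    break
        else:
            for i in hits:
                if _qualifies(aiv, int(starts[i]), int(ends[i]), min_frac_a, min_frac_b):
                    out.append(
                        GenomicInterval(
                            aiv.chrom,
                            max(aiv.start, int(starts[i])),
                            min(aiv.end, int(ends[i])),
                        )
                    )
    return out


def subtract_exclusive(A: Sequence, B: Sequence) -> list:
    """Elements of A with zero overlap in B (BEDTools ``intersect -v``)."""
    b_arrays = _sorted_arrays(B)
    out = []
    for a in A:
        aiv = _iv(a)
        if aiv.chrom in b_arrays:
            starts, ends = b_arrays[aiv.chrom]
            if len(_overlap_candidates(aiv, starts, ends)) > 0:
                continue
        out.append(a)
    return out


def tissue_specific(target_peaks: Sequence, other_tissue_peaksets: Sequence[Sequence]) -> list:
    """Peaks of the target tissue overlapping no peak of any other tissue.

    Sequential exclusive subtraction against each other-tissue set, the
    two-step BEDTools ``intersect -v`` chain used to call tissue-specific
    chromatin.
    """
    if len(other_tissue_peaksets) < 1:
        raise ValueError("need at least one other tissue peak set")
    result = list(target_peaks)
    for other in other_tissue_peaksets:
        result = subtract_exclusive(result, other)
    return result


def _tss_index(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome TSS positions (sorted) with gene ids in matching order."""
    grouped: dict[str, list[GeneModel]] = {}
    for g in genes:
        grouped.setdefault(g.chrom, []).append(g)
    out = {}
    for chrom, gs in grouped.items():
        tss = np.array([g.tss for g in gs])
        ids = np.array([g.gene_id for g in gs], dtype=object)
        order = np.lexsort((ids, tss))
        out[chrom] = (tss[order], ids[order])
    return out


def nearest_tss(peak, genes: Sequence[GeneModel], anchor: str = "midpoint") -> tuple[str, int]:
    """Nearest gene TSS to a peak; ties break to the smallest gene_id.

    anchor ``midpoint`` measures |peak midpoint - TSS|; anchor ``edges``
    measures the gap to the peak boundary (0 if the TSS lies inside).
    """
    if anchor not in ("midpoint", "edges"):
        raise ValueError(f"unknown anchor {anchor!r}")
    piv = _iv(peak)
    index = _tss_index(genes)
    if piv.chrom not in index:
        raise ValueError(f"no gene on chromosome {piv.chrom!r}")
    tss, ids = index[piv.chrom]
    if anchor == "midpoint":
        d = np.abs(tss - piv.midpoint)
    else:
        d = np.where(
            (tss >= piv.start) & (tss < piv.end),
            0,
            np.minimum(np.abs(tss - piv.start), np.abs(tss - (piv.end - 1))),
        )
    best = d.min()
    cand = np.nonzero(d == best)[0]
    gid = min(str(ids[i]) for i in cand)
    return gid, int(best)


def distal_filter(
    peaks: Sequence, genes: Sequence[GeneModel], min_distance: int = 1500
) -> tuple[list, list]:
    """Peaks whose midpoint lies more than ``min_distance`` from every TSS.

    Returns ``(distal, gene_free)``: peaks on chromosomes without genes are
    retained in the first list and also flagged in the second.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    index = _tss_index(genes)
    distal, gene_free = [], []
    for p in peaks:
        piv = _iv(p)
        if piv.chrom not in index:
            distal.append(p)
            gene_free.append(p)
            continue
        tss, _ = index[piv.chrom]
        if int(np.abs(tss - piv.midpoint).min()) > min_distance:
            distal.append(p)
    return distal, gene_free


def classify_peak(
    peak,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
    tts_window: tuple[int, int] = (0, 100),
) -> str:
    """Classify one peak by its midpoint: promoter > tts_flank > gene_body > intergenic.

    Windows are strand-aware offsets relative to TSS (promoter) and TES (TTS
    flank); negative offsets point upstream of transcription.
    """
    mid = _iv(peak).midpoint
    chrom = _iv(peak).chrom
    in_promoter = in_tts = in_body = False
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.interval.strand == "+":
            plo, phi = g.tss + promoter_window[0], g.tss + promoter_window[1]
            tlo, thi = g.tes + tts_window[0], g.tes + tts_window[1]
        else:
            plo, phi = g.tss - promoter_window[1], g.tss - promoter_window[0]
            tlo, thi = g.tes - tts_window[1], g.tes - tts_window[0]
        if plo <= mid <= phi:
            in_promoter = True
            break
        if tlo <= mid <= thi:
            in_tts = True
        elif g.interval.start <= mid < g.interval.end:
            in_body = True
    if in_promoter:
        return "promoter"
    if in_tts:
        return "tts_flank"
    if in_body:
        return "gene_body"
    return "intergenic"


def feature_distribution(
    peaks: Sequence,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
    tts_window: tuple[int, int] = (0, 100),
) -> FeatureClassCounts:
    """Distribution of peaks across genome feature classes (midpoint rule)."""
    counts = {k: 0 for k in FEATURE_CLASSES}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for p in peaks:
        cls = classify_peak(p, genes_by_chrom.get(_iv(p).chrom, []), promoter_window, tts_window)
        counts[cls] += 1
    return FeatureClassCounts(counts)


def fisher_exact_2x2(
    table: ContingencyTable2x2,
    alternative: str = "two-sided",
    continuity: bool = False,
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns ``(p, odds_ratio)``; the odds ratio is the sample odds ratio
    n11*n22 / (n12*n21), with 0.5 added to every cell only when
    ``continuity=True``. Division by a zero denominator yields ``inf``.
    """
    arr = table.as_array().astype(float)
    p = float(stats.fisher_exact(arr, alternative=alternative).pvalue)
    if continuity:
        arr = arr + 0.5
    num = arr[0, 0] * arr[1, 1]
    den = arr[0, 1] * arr[1, 0]
    odds = float(num / den) if den > 0 else float("inf")
    return p, odds


def colocalization_fisher(
    A: Sequence, B: Sequence, genome_size: int
) -> tuple[ContingencyTable2x2, float, float]:
    """Fisher co-localization test of two peak sets against genome background.

    Both sets are merged; the table counts merged A interval with/without a B
    overlap and vice versa, and estimates the "neither" cell from the genome
    length over the mean interval length (bedtools-fisher style).
    """
    if not A or not B:
        raise ValueError("A and B must be non-empty")
    Am = merge_intervals(A)
    Bm = merge_intervals(B)
    covered = sum(len(iv) for iv in merge_intervals(list(Am) + list(Bm)))
    if genome_size < covered:
        raise ValueError(f"genome_size {genome_size} < covered bases {covered}")
    n11 = len(intersect(Am, Bm, mode="whole_a"))
    n12 = len(Am) - n11
    n21 = len(Bm) - len(intersect(Bm, Am, mode="whole_a"))
    mean_len = (sum(len(iv) for iv in Am) + sum(len(iv) for iv in Bm)) / (len(Am) + len(Bm))
    n22 = max(0, round(genome_size / mean_len) - n11 - n12 - n21)
    table = ContingencyTable2x2(n11, n12, n21, int(n22))
    p, odds = fisher_exact_2x2(table)
    return table, p, odds
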