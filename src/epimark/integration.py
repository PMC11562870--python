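"""Chromatin/expression joins.

Mark-to-gene assignment with a strand-aware promoter extension, the
transcribed x mark cross-tabulation, tissue-specific chromatin, bivalent
(H3K4me3 + H3K27me3) loci, and distal H3K56ac enhancer -> target-gene
pairing: distal filter against all TSSs, nearest gene over ALL genes, then
the both-contrast DE membership test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import pandas as pd

from .core_io import DETable, GeneModel, GenomicInterval, Peak
from . import interval_algebra as ia

__all__ = [
    "GeneChromatinState",
    "EnhancerTargetPair",
    "assign_marks_to_genes",
    "bivalent_loci",
    "tissue_specific_chromatin",
    "enhancer_target_pairs",
    "mark_state_crosstab",
]


@dataclass(frozen=True)
class GeneChromatinState:
    """Per-gene chromatin summary in one tissue."""

    gene_id: str
    tissue: str
    transcribed: bool
    marks_present: frozenset
    bivalent: bool

    def __post_init__(self):
        if self.bivalent and not {"H3K4me3", "H3K27me3"} <= set(self.marks_present):
            raise ValueError("bivalent flag requires both H3K4me3 and H3K27me3")


@dataclass(frozen=True)
class EnhancerTargetPair:
    """A distal tissue-specific H3K56ac locus joined to its nearest DE gene."""

    locus: GenomicInterval
    gene_id: str
    distance: int
    de_stats: Mapping[str, tuple[float, float]]  # contrast -> (log2fc, padj)
    intragenic: bool


def assign_marks_to_genes(
    genes: Sequence[GeneModel],
    consolidated_peaks_by_mark: Mapping[str, Sequence[Peak]],
    promoter_extension: int = 1000,
    transcribed: set | None = None,
    tissue: str = "trichome",
) -> list[GeneChromatinState]:
    """Mark present for a gene iff any consolidated peak of that mark overlaps
    the gene span extended ``promoter_extension`` bp upstream (strand-aware)."""
    windows = []
    for g in genes:
        iv = g.interval
        if iv.strand == "+":
            win = GenomicInterval(iv.chrom, max(0, iv.start - promoter_extension), iv.end)
        else:
            win = GenomicInterval(iv.chrom, iv.start, iv.end + promoter_extension)
        windows.append(win)
    states = []
    hit_sets: dict[str, set] = {}
    for mark, peaks in consolidated_peaks_by_mark.items():
        hits = ia.intersect(windows, [p.interval for p in peaks], mode="whole_a")
        hit_ids = {id(w) for w in hits}
        hit_sets[mark] = {g.gene_id for g, w in zip(genes, windows) if id(w) in hit_ids}
    for g in genes:
        marks = frozenset(m for m, s in hit_sets.items() if g.gene_id in s)
        states.append(
            GeneChromatinState(
                gene_id=g.gene_id,
                tissue=tissue,
                transcribed=bool(transcribed and g.gene_id in transcribed),
                marks_present=marks,
                bivalent={"H3K4me3", "H3K27me3"} <= set(marks),
            )
        )
    return states


def bivalent_loci(
    k4_peaks: Sequence[Peak], k27_peaks: Sequence[Peak]
) -> tuple[list[GenomicInterval], int]:
    """H3K4me3/H3K27me3 intersection fragments plus the overlapping-K4-peak count."""
    fragments = ia.intersect(
        [p.interval for p in k4_peaks], [p.interval for p in k27_peaks], mode="fragment"
    )
    count = len(ia.intersect(k4_peaks, k27_peaks, mode="whole_a"))
    return fragments, count


def tissue_specific_chromatin(
    mark: str, peaks_by_tissue: Mapping[str, Sequence[Peak]], target_tissue: str
) -> list[Peak]:
    """Consolidated peaks of one mark present only in the target tissue."""
    if target_tissue not in peaks_by_tissue:
        raise ValueError(f"target tissue {target_tissue!r} missing from peak sets")
    if len(peaks_by_tissue) < 2:
        raise ValueError("need >= 2 tissues")
    others = [v for t, v in peaks_by_tissue.items() if t != target_tissue]
    kept = ia.tissue_specific(peaks_by_tissue[target_tissue], others)
    return [
        Peak(
            p.interval,
            mark=mark,
            tissue=target_tissue,
            replicate="consolidated",
            score=p.score,
            neglog10p=p.neglog10p,
            neglog10q=p.neglog10q,
        )
        for p in kept
    ]


def enhancer_target_pairs(
    h3k56ac_tissue_specific: Sequence[Peak],
    genes: Sequence[GeneModel],
    de_filtered_gene_set: set,
    de_tables: Sequence[DETable],
    min_distance: int = 1500,
) -> tuple[list[EnhancerTargetPair], pd.DataFrame]:
    """Distal tissue-specific H3K56ac loci paired to nearest DE genes.

    Pipeline: (1) drop loci whose midpoint is within ``min_distance`` of any
    TSS; (2) find each survivor's nearest gene among ALL genes; (3) keep the
    pair iff that gene is in the tissue-specific DE set; (4) attach per-
    contrast DE stats and an intragenic flag (locus overlaps some OTHER
    gene's body). Rejected loci are returned as a table with reasons.
    """
    rejects: list[tuple[str, int, int, str, str]] = []
    pairs: list[EnhancerTargetPair] = []
    if not h3k56ac_tissue_specific:
        warnings.warn("no tissue-specific H3K56ac loci supplied", stacklevel=2)
        return [], pd.DataFrame(columns=["chrom", "start", "end", "nearest_gene", "reason"])

    distal, gene_free = ia.distal_filter(h3k56ac_tissue_specific, genes, min_distance)
    distal_ids = {id(p) for p in distal}
    gene_free_ids = {id(p) for p in gene_free}
    for p in h3k56ac_tissue_specific:
        iv = p.interval if isinstance(p, Peak) else p
        if id(p) not in distal_ids:
            rejects.append((iv.chrom, iv.start, iv.end, "", "proximal"))
    for p in distal:
        iv = p.interval if isinstance(p, Peak) else p
        if id(p) in gene_free_ids:
            rejects.append((iv.chrom, iv.start, iv.end, "", "gene_free_chromosome"))
            continue
        gid, dist = ia.nearest_tss(p, genes, anchor="midpoint")
        if gid not in de_filtered_gene_set:
            rejects.append((iv.chrom, iv.start, iv.end, gid, "nearest_gene_not_de"))
            continue
        stats = {}
        for de in de_tables:
            try:
                stats[de.contrast] = de.stats_for(gid)
            except KeyError:
                stats[de.contrast] = (float("nan"), float("nan"))
        intragenic = any(
            g.gene_id != gid and g.chrom == iv.chrom and g.interval.overlaps(iv) for g in genes
        ) or any(
            g.gene_id == gid and g.interval.overlaps(iv) for g in genes
        )
        pairs.append(
            EnhancerTargetPair(
                locus=iv, gene_id=gid, distance=dist, de_stats=stats, intragenic=intragenic
            )
        )
    reject_df = pd.DataFrame(
        rejects, columns=["chrom", "start", "end", "nearest_gene", "reason"]
    )
    return pairs, reject_df


def pairs_to_table(pairs: Sequence[EnhancerTargetPair]) -> pd.DataFrame:
    """Flatten enhancer-target pairs into a per-contrast wide table."""
    rows = []
    for p in pairs:
        row = {
            "gene_id": p.gene_id,
            "chrom": p.locus.chrom,
            "start": p.locus.start,
            "end": p.locus.end,
            "distance": p.distance,
            "intragenic": p.intragenic,
        }
        for contrast, (lfc, padj) in sorted(p.de_stats.items()):
            row[f"log2fc_{contrast}"] = lfc
            row[f"padj_{contrast}"] = padj
        rows.append(row)
    return pd.DataFrame(rows)


def mark_state_crosstab(states: Sequence[GeneChromatinState]) -> pd.DataFrame:
    """Gene counts per (transcribed x mark) cell; rows sum to partition sizes
    only when each gene carries exactly one mark, so a total column is added."""
    marks = ("H3K4me3", "H3K56ac", "H3K27me3", "H2A.Z")
    data = {}
    for status in (True, False):
        row = {m: 0 for m in marks}
        total = 0
        for s in states:
            if s.transcribed != status:
                continue
            total += 1
            for m in s.marks_present:
                if m in row:
                    row[m] += 1
        row["n_genes"] = total
        data["transcribed" if status else "untranscribed"] = row
    return pd.DataFrame(data).T[list(marks) + ["n_genes"]]
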