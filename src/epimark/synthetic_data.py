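"""Seeded generator of a miniature multi-tissue histone-mark study.

Emits a complete downstream dataset — genome FASTA, gene annotation,
per-tissue/mark/replicate peak calls, binned coverage tracks, TPM tables,
motif matrices and a term map — together with a ground-truth manifest of
every planted entity (tissue-specific peaks, bivalent genes, DE genes with
true effect sizes, enhancer-target pairs, motif-bearing loci), so every
pipeline stage has recoverable planted structure. Identical seeds give
byte-identical bundles.

Layout of the planted design, per tissue (trichome / stem / leaf):

* transcribed genes carry H3K4me3 and H3K56ac peaks centred on the TSS in
  every tissue; untranscribed genes carry H3K27me3 and H2A.Z domains over
  the gene body +/- 1 kb in every tissue;
* bivalent genes additionally carry a trichome-only H3K27me3 body domain on
  top of their shared H3K4me3 TSS peak;
* planted DE genes are upregulated in trichome against both other tissues;
* enhancer loci are trichome-only H3K56ac peaks placed 2-50 kb from the TSS
  of a planted DE gene, with that gene verified nearest;
* each mark x tissue additionally gets dedicated intergenic tissue-specific
  peaks;
* replicates add boundary jitter, spurious peaks and bivariate log-normal
  scores with reproducible correlation rho_true.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    ALPHABET,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    MotifPFM,
    Peak,
    SignalTrack,
    write_expression,
    write_fasta,
    write_gene_models,
    write_jaspar,
    write_peaks,
    write_signal,
)
from .expression_enrichment import TermMap, write_term_map

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "GroundTruthManifest",
    "generate",
    "truth_eval",
    "TruthEvalResult",
]

NARROW_MARKS = ("H3K4me3", "H3K56ac")
BROAD_MARKS = ("H3K27me3", "H2A.Z")
MARKS = NARROW_MARKS + BROAD_MARKS
TISSUES = ("trichome", "stem", "leaf")


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic miniature experiment."""

    seed: int = 0
    n_chrom: int = 3
    chrom_len: int = 1_000_000
    n_genes: int = 300
    gene_len_median: float = 3000.0
    gene_len_sigma: float = 0.6  # sd of log gene length
    gene_len_min: int = 500
    min_intergenic_gap: int = 1000
    n_de_genes: int = 40
    de_lfc_low: float = 2.5
    de_lfc_high: float = 8.0
    tpm_median: float = 8.0
    tpm_sigma: float = 1.0  # sd of log baseline TPM
    de_baseline_min: float = 4.0
    expressed_baseline_min: float = 1.5
    replicate_cv: float = 0.1
    untranscribed_fraction: float = 0.2
    n_rna_replicates: int = 3
    n_chip_replicates: int = 2
    narrow_width_low: int = 400
    narrow_width_high: int = 1500
    broad_flank: int = 1000
    broad_plant_width_low: int = 2000
    broad_plant_width_high: int = 6000
    n_bivalent: int = 15
    n_enhancers: int = 25
    enhancer_dist_low: int = 2000
    enhancer_dist_high: int = 50000
    enhancer_margin: int = 500  # nearest-TSS lead over the runner-up
    n_tissue_specific: int = 15  # intergenic plants per mark x tissue
    jitter_sd: float = 50.0
    spurious_rate: float = 0.2
    score_log_mean_true: float = 2.0
    score_log_mean_spurious: float = 1.0
    score_log_sd: float = 0.5
    rho_true: float = 0.8
    motif_plant_rate: float = 0.6
    motif_length: int = 10
    gc_content: float = 0.42
    track_bin: int = 100
    n_decoy_terms: int = 9

    def validate(self):
        if not 0 < self.untranscribed_fraction < 1:
            raise ValueError("untranscribed_fraction must be in (0, 1)")
        if self.n_genes % self.n_chrom:
            raise ValueError("n_genes must divide evenly across chromosomes")
        if self.enhancer_dist_low <= 1500:
            raise ValueError("enhancer distances must exceed the distal threshold")


@dataclass(frozen=True)
class PlantedLocus:
    """One true peak locus, shared (unjittered) across replicates."""

    interval: GenomicInterval
    mark: str
    tissues: tuple
    kind: str  # tss | broad_gene | bivalent_k27 | plant | enhancer
    gene_id: str | None = None


@dataclass
class GroundTruthManifest:
    """Every planted entity, for precision/recall evaluation."""

    tissue_specific_peaks: list  # (mark, tissue, GenomicInterval)
    bivalent_genes: set
    de_genes: pd.DataFrame  # gene_id, true_log2fc
    enhancer_pairs: list  # (gene_id, GenomicInterval, distance)
    motif_loci: list  # GenomicInterval bearing the planted motif
    transcribed_genes: set
    untranscribed_genes: set
    planted_term: str

    def specific_peaks_for(self, mark: str, tissue: str) -> list:
        return [iv for m, t, iv in self.tissue_specific_peaks if m == mark and t == tissue]


@dataclass
class SyntheticBundle:
    """In-memory dataset bundle; ``write`` lays it out on disk."""

    config: SyntheticConfig
    genes: list
    genome: dict
    expression: ExpressionTable
    peaks: dict  # (tissue, mark, replicate:int) -> list[Peak]
    tracks: dict  # (tissue, mark, replicate:int) -> SignalTrack
    motifs: list  # [planted, decoy] MotifPFM
    term_map: TermMap
    manifest: GroundTruthManifest
    true_score_pairs: np.ndarray  # n x 2 replicate scores of true loci

    def peak_dialect(self, mark: str) -> str:
        return "narrowPeak" if mark in NARROW_MARKS else "broadPeak"

    def write(self, outdir) -> None:
        out = Path(outdir)
        for sub in ("peaks", "tracks", "expression", "motifs", "terms", "manifest"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fa", self.genome)
        write_gene_models(out / "annotation.gff3", self.genes)
        for (tissue, mark, rep), plist in sorted(self.peaks.items()):
            dialect = self.peak_dialect(mark)
            safe_mark = mark.replace(".", "")
            write_peaks(
                out / "peaks" / f"{tissue}_{safe_mark}_rep{rep}.{dialect}", plist, dialect
            )
        for (tissue, mark, rep), track in sorted(self.tracks.items()):
            safe_mark = mark.replace(".", "")
            write_signal(out / "tracks" / f"{tissue}_{safe_mark}_rep{rep}.bedGraph", track)
        write_expression(out / "expression" / "tpm.tsv", self.expression)
        write_jaspar(out / "motifs" / "motifs.jaspar", self.motifs)
        write_term_map(out / "terms" / "term_map.tsv", self.term_map)
        self._write_manifest(out / "manifest")
        with open(out / "params.yaml", "w") as fh:
            yaml.safe_dump({"config": vars(self.config)}, fh, sort_keys=True)

    def _write_manifest(self, mdir: Path) -> None:
        m = self.manifest
        pd.DataFrame(
            [(mk, t, iv.chrom, iv.start, iv.end) for mk, t, iv in m.tissue_specific_peaks],
            columns=["mark", "tissue", "chrom", "start", "end"],
        ).to_csv(mdir / "tissue_specific_peaks.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(m.bivalent_genes), columns=["gene_id"]).to_csv(
            mdir / "bivalent_genes.tsv", sep="\t", index=False
        )
        m.de_genes.to_csv(mdir / "de_genes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(g, iv.chrom, iv.start, iv.end, d) for g, iv, d in m.enhancer_pairs],
            columns=["gene_id", "chrom", "start", "end", "distance"],
        ).to_csv(mdir / "enhancer_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(iv.chrom, iv.start, iv.end) for iv in m.motif_loci],
            columns=["chrom", "start", "end"],
        ).to_csv(mdir / "motif_loci.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(m.transcribed_genes), columns=["gene_id"]).to_csv(
            mdir / "transcribed_genes.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# placement helpers


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Place genes chromosome by chromosome with randomized intergenic gaps.

    Every gap gets the configured minimum plus a 1.2 kb guard (so promoter
    windows and TSS peaks of neighbours cannot collide) plus a random share
    of the remaining space.
    """
    per_chrom = cfg.n_genes // cfg.n_chrom
    guard = 1200
    genes: list[GeneModel] = []
    gid = 0
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        lengths = np.maximum(
            rng.lognormal(math.log(cfg.gene_len_median), cfg.gene_len_sigma, per_chrom),
            cfg.gene_len_min,
        ).astype(int)
        base_gap = cfg.min_intergenic_gap + guard
        needed = int(lengths.sum()) + (per_chrom + 1) * base_gap
        if needed > cfg.chrom_len:
            raise ValueError(
                f"infeasible placement: {per_chrom} genes need {needed} bp on a "
                f"{cfg.chrom_len} bp chromosome"
            )
        extra = cfg.chrom_len - needed
        shares = rng.random(per_chrom + 1)
        gaps = base_gap + np.floor(extra * shares / shares.sum()).astype(int)
        pos = 0
        for i in range(per_chrom):
            pos += int(gaps[i])
            start = pos
            end = start + int(lengths[i])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            name = f"gene{gid:04d}"
            genes.append(GeneModel(name, GenomicInterval(chrom, start, end, strand, name)))
    return genes


def _nearest_two_tss(tss_sorted: np.ndarray, pos: int) -> tuple[int, int]:
    d = np.abs(tss_sorted - pos)
    d.sort()
    return int(d[0]), int(d[1]) if d.size > 1 else int(1 << 30)


class _Occupancy:
    """Per-mark interval occupancy with padding, for collision-free plants."""

    def __init__(self, pad: int = 500):
        self.pad = pad
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def add(self, iv: GenomicInterval):
        self.by_chrom.setdefault(iv.chrom, []).append((iv.start - self.pad, iv.end + self.pad))

    def collides(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.by_chrom.get(chrom, ()):
            if start < e and s < end:
                return True
        return False


def generate(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate the full bundle plus ground-truth manifest (deterministic per seed)."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    stream_names = (
        "genes",
        "assign",
        "expression",
        "loci",
        "replicates",
        "tracks",
        "genome",
        "motifs",
        "terms",
    )
    seqs = np.random.SeedSequence(cfg.seed).spawn(len(stream_names))
    rng = {name: np.random.default_rng(s) for name, s in zip(stream_names, seqs)}

    genes = _place_genes(cfg, rng["genes"])
    by_id = {g.gene_id: g for g in genes}
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    # --- category assignment -------------------------------------------------
    order = list(rng["assign"].permutation([g.gene_id for g in genes]))
    n_untx = int(round(cfg.untranscribed_fraction * cfg.n_genes))
    untranscribed = set(order[:n_untx])
    bivalent = set(order[n_untx : n_untx + cfg.n_bivalent])
    de_genes = list(order[n_untx + cfg.n_bivalent : n_untx + cfg.n_bivalent + cfg.n_de_genes])
    transcribed = set(order[n_untx:])

    # --- expression ----------------------------------------------------------
    r = rng["expression"]
    base = {}
    true_lfc = {}
    for gid in order:
        if gid in untranscribed:
            base[gid] = float(r.uniform(0.05, 0.5))
        else:
            floor = cfg.de_baseline_min if gid in de_genes else cfg.expressed_baseline_min
            base[gid] = float(max(r.lognormal(math.log(cfg.tpm_median), cfg.tpm_sigma), floor))
        if gid in de_genes:
            true_lfc[gid] = float(r.uniform(cfg.de_lfc_low, cfg.de_lfc_high))
    sigma_rep = math.sqrt(math.log(1 + cfg.replicate_cv**2))
    cols = {}
    gene_order = [g.gene_id for g in genes]
    for tissue in TISSUES:
        for k in range(1, cfg.n_rna_replicates + 1):
            vals = []
            for gid in gene_order:
                mean = base[gid]
                if tissue == "trichome" and gid in true_lfc:
                    mean = mean * 2 ** true_lfc[gid]
                vals.append(mean * math.exp(r.normal(0.0, sigma_rep)))
            cols[f"{tissue}_rep{k}"] = vals
    tpm = pd.DataFrame(cols, index=pd.Index(gene_order, name="gene_id"))
    expression = ExpressionTable(tpm, {c: c.rsplit("_rep", 1)[0] for c in tpm.columns})

    # --- true peak loci ------------------------------------------------------
    rl = rng["loci"]
    loci: list[PlantedLocus] = []
    occupancy = {m: _Occupancy(pad=500) for m in MARKS}

    def clipped(chrom: str, start: int, end: int) -> GenomicInterval:
        return GenomicInterval(chrom, max(0, start), min(cfg.chrom_len, end))

    for g in genes:
        gid = g.gene_id
        if gid in transcribed:
            for mark in NARROW_MARKS:
                w = int(rl.integers(cfg.narrow_width_low, cfg.narrow_width_high + 1))
                iv = clipped(g.chrom, g.tss - w // 2, g.tss - w // 2 + w)
                loci.append(PlantedLocus(iv, mark, TISSUES, "tss", gid))
                occupancy[mark].add(iv)
        else:
            for mark in BROAD_MARKS:
                iv = clipped(
                    g.chrom, g.interval.start - cfg.broad_flank, g.interval.end + cfg.broad_flank
                )
                loci.append(PlantedLocus(iv, mark, TISSUES, "broad_gene", gid))
                occupancy[mark].add(iv)
        if gid in bivalent:
            iv = clipped(
                g.chrom, g.interval.start - cfg.broad_flank, g.interval.end + cfg.broad_flank
            )
            loci.append(PlantedLocus(iv, "H3K27me3", ("trichome",), "bivalent_k27", gid))
            occupancy["H3K27me3"].add(iv)

    # enhancers: trichome-only H3K56ac, target DE gene guaranteed nearest
    enhancer_pairs: list[tuple[str, GenomicInterval, int]] = []
    de_pool = list(de_genes)
    for gid in de_pool:
        if len(enhancer_pairs) >= cfg.n_enhancers:
            break
        g = by_id[gid]
        tss_all = tss_by_chrom[g.chrom]
        placed = False
        for _ in range(400):
            d = int(rl.integers(cfg.enhancer_dist_low, cfg.enhancer_dist_high + 1))
            sign = -1 if rl.random() < 0.5 else 1
            mid = g.tss + sign * d
            w = int(rl.integers(cfg.narrow_width_low, cfg.narrow_width_high + 1))
            start, end = mid - w // 2, mid - w // 2 + w
            if start < 0 or end > cfg.chrom_len:
                continue
            d1, d2 = _nearest_two_tss(tss_all, mid)
            if d1 != abs(mid - g.tss) or d2 - d1 < cfg.enhancer_margin:
                continue
            if occupancy["H3K56ac"].collides(g.chrom, start, end):
                continue
            iv = GenomicInterval(g.chrom, start, end)
            loci.append(PlantedLocus(iv, "H3K56ac", ("trichome",), "enhancer", gid))
            occupancy["H3K56ac"].add(iv)
            enhancer_pairs.append((gid, iv, d))
            placed = True
            break
        if not placed:
            continue
    if len(enhancer_pairs) < cfg.n_enhancers:
        raise ValueError(
            f"infeasible placement: only {len(enhancer_pairs)} of "
            f"{cfg.n_enhancers} enhancer loci could be placed"
        )

    # dedicated intergenic tissue-specific plants, one batch per mark x tissue
    de_set = set(de_genes)
    for mark in MARKS:
        broad = mark in BROAD_MARKS
        for tissue in TISSUES:
            placed = 0
            attempts = 0
            while placed < cfg.n_tissue_specific:
                attempts += 1
                if attempts > 20000:
                    raise ValueError(
                        f"infeasible placement: tissue-specific {mark}/{tissue} plants"
                    )
                chrom = f"chr{int(rl.integers(1, cfg.n_chrom + 1))}"
                if broad:
                    w = int(
                        rl.integers(cfg.broad_plant_width_low, cfg.broad_plant_width_high + 1)
                    )
                else:
                    w = int(rl.integers(cfg.narrow_width_low, cfg.narrow_width_high + 1))
                start = int(rl.integers(0, cfg.chrom_len - w))
                end = start + w
                mid = (start + end) // 2
                d1, _ = _nearest_two_tss(tss_by_chrom[chrom], mid)
                if d1 < 2200:  # keep plants clear of TSS peaks and promoters
                    continue
                if occupancy[mark].collides(chrom, start, end):
                    continue
                # plants are intergenic: stay clear of gene bodies plus the
                # promoter-extension margin so they never attach to a gene
                pad = (cfg.broad_flank if broad else 0) + 1300
                if any(
                    g.chrom == chrom
                    and start < g.interval.end + pad
                    and g.interval.start - pad < end
                    for g in genes
                ):
                    continue
                if mark == "H3K56ac" and tissue == "trichome":
                    gid_near = _nearest_gene_id(genes, chrom, mid)
                    if gid_near in de_set:
                        continue
                iv = GenomicInterval(chrom, start, end)
                loci.append(PlantedLocus(iv, mark, (tissue,), "plant", None))
                occupancy[mark].add(iv)
                placed += 1

    # --- replicate-level peak calls ------------------------------------------
    rr = rng["replicates"]
    cov = cfg.score_log_sd**2 * np.array([[1.0, cfg.rho_true], [cfg.rho_true, 1.0]])
    peaks: dict[tuple, list[Peak]] = {
        (t, m, k): [] for t in TISSUES for m in MARKS for k in range(1, cfg.n_chip_replicates + 1)
    }
    true_score_pairs = []
    jitter_on = cfg.jitter_sd > 0
    for idx, locus in enumerate(loci):
        for tissue in locus.tissues:
            log_scores = rr.multivariate_normal(
                [cfg.score_log_mean_true] * 2, cov, method="cholesky"
            )
            scores = np.exp(log_scores)
            true_score_pairs.append(scores)
            for k in range(1, cfg.n_chip_replicates + 1):
                iv = locus.interval
                if jitter_on:
                    s = iv.start + int(round(rr.normal(0, cfg.jitter_sd)))
                    e = iv.end + int(round(rr.normal(0, cfg.jitter_sd)))
                    s = max(0, s)
                    e = min(cfg.chrom_len, e)
                    if e <= s:
                        e = s + max(50, len(iv) // 4)
                    iv = GenomicInterval(iv.chrom, s, e, name=f"L{idx:05d}")
                else:
                    iv = GenomicInterval(iv.chrom, iv.start, iv.end, name=f"L{idx:05d}")
                sc = float(scores[min(k - 1, 1)])
                peaks[(tissue, locus.mark, k)].append(
                    Peak(
                        iv,
                        mark=locus.mark,
                        tissue=tissue,
                        replicate=f"rep{k}",
                        score=sc,
                        neglog10p=sc,
                        neglog10q=max(sc - 0.3, 0.0),
                        summit=len(iv) // 2 if locus.mark in NARROW_MARKS else None,
                    )
                )
    # spurious, per replicate, independent across replicates
    for tissue in TISSUES:
        for mark in MARKS:
            n_true = sum(1 for l in loci if mark == l.mark and tissue in l.tissues)
            n_spur = int(round(cfg.spurious_rate * n_true))
            for k in range(1, cfg.n_chip_replicates + 1):
                for s_i in range(n_spur):
                    chrom = f"chr{int(rr.integers(1, cfg.n_chrom + 1))}"
                    if mark in NARROW_MARKS:
                        w = int(rr.integers(cfg.narrow_width_low, cfg.narrow_width_high + 1))
                    else:
                        w = int(
                            rr.integers(cfg.broad_plant_width_low, cfg.broad_plant_width_high + 1)
                        )
                    start = int(rr.integers(0, cfg.chrom_len - w))
                    sc = float(math.exp(rr.normal(cfg.score_log_mean_spurious, cfg.score_log_sd)))
                    peaks[(tissue, mark, k)].append(
                        Peak(
                            GenomicInterval(chrom, start, start + w, name=f"S{k}_{s_i:04d}"),
                            mark=mark,
                            tissue=tissue,
                            replicate=f"rep{k}",
                            score=sc,
                            neglog10p=sc,
                            neglog10q=max(sc - 0.3, 0.0),
                            summit=w // 2 if mark in NARROW_MARKS else None,
                        )
                    )
    for key in peaks:
        peaks[key].sort(key=lambda p: (p.chrom, p.start, p.end))

    # --- coverage tracks ------------------------------------------------------
    rt = rng["tracks"]
    n_bins = cfg.chrom_len // cfg.track_bin
    tracks: dict[tuple, SignalTrack] = {}
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chrom)]
    starts = np.arange(n_bins) * cfg.track_bin
    for (tissue, mark, k), plist in sorted(peaks.items()):
        values = {c: rt.exponential(0.1, n_bins) for c in chrom_names}
        broad_mark = mark in BROAD_MARKS
        for p in plist:
            b0 = p.start // cfg.track_bin
            b1 = min((p.end - 1) // cfg.track_bin + 1, n_bins)
            if broad_mark and p.end - p.start > 2 * cfg.broad_flank:
                # broad domains shoulder off over their outer flanks
                c0 = (p.start + cfg.broad_flank) // cfg.track_bin
                c1 = min((p.end - cfg.broad_flank - 1) // cfg.track_bin + 1, n_bins)
                values[p.chrom][b0:b1] += 0.5 * p.score
                values[p.chrom][c0:c1] += 0.5 * p.score
            else:
                values[p.chrom][b0:b1] += p.score
        frames = []
        for c in chrom_names:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "start": starts,
                        "end": starts + cfg.track_bin,
                        "value": np.round(values[c], 4),
                    }
                )
            )
        label = f"{mark}_{tissue}_rep{k}"
        tracks[(tissue, mark, k)] = SignalTrack(label, pd.concat(frames, ignore_index=True))

    # --- genome and motif planting -------------------------------------------
    rg = rng["genome"]
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome_arr = {
        c: rg.choice(np.frombuffer("ACGT".encode(), dtype=np.uint8), cfg.chrom_len, p=probs)
        for c in chrom_names
    }
    rm = rng["motifs"]
    planted_cons = "".join(ALPHABET[i] for i in rm.integers(0, 4, cfg.motif_length))
    while True:
        decoy_cons = "".join(ALPHABET[i] for i in rm.integers(0, 4, cfg.motif_length))
        if decoy_cons != planted_cons and decoy_cons != _revcomp(planted_cons):
            break

    def consensus_pfm(mid: str, cons: str, name: str) -> MotifPFM:
        counts = np.ones((4, len(cons)))
        for j, b in enumerate(cons):
            counts[ALPHABET.index(b), j] = 197.0
        return MotifPFM(mid, counts, name=name)

    motifs = [
        consensus_pfm("MA9001.1", planted_cons, "PLANTED"),
        consensus_pfm("MA9002.1", decoy_cons, "DECOY"),
    ]
    motif_loci = []
    cons_bytes = np.frombuffer(planted_cons.encode(), dtype=np.uint8)
    for gid, iv, d in enhancer_pairs:
        if rm.random() < cfg.motif_plant_rate:
            off = int(rm.integers(0, len(iv) - cfg.motif_length))
            genome_arr[iv.chrom][iv.start + off : iv.start + off + cfg.motif_length] = cons_bytes
            motif_loci.append(iv)
    genome = {c: arr.tobytes().decode() for c, arr in genome_arr.items()}

    # --- term map --------------------------------------------------------------
    rt2 = rng["terms"]
    terms = {"TERM0001": set(de_genes)}
    all_ids = [g.gene_id for g in genes]
    for i in range(cfg.n_decoy_terms):
        size = int(rt2.integers(15, 40))
        terms[f"TERM{i + 2:04d}"] = set(rt2.choice(all_ids, size=size, replace=False))
    term_map = TermMap(terms, {"TERM0001": "planted trichome program"})

    # --- manifest ---------------------------------------------------------------
    specific = []
    for locus in loci:
        if len(locus.tissues) == 1:
            specific.append((locus.mark, locus.tissues[0], locus.interval))
    manifest = GroundTruthManifest(
        tissue_specific_peaks=specific,
        bivalent_genes=set(bivalent),
        de_genes=pd.DataFrame(
            sorted(true_lfc.items()), columns=["gene_id", "true_log2fc"]
        ),
        enhancer_pairs=enhancer_pairs,
        motif_loci=motif_loci,
        transcribed_genes=set(transcribed),
        untranscribed_genes=set(untranscribed),
        planted_term="TERM0001",
    )
    return SyntheticBundle(
        config=cfg,
        genes=genes,
        genome=genome,
        expression=expression,
        peaks=peaks,
        tracks=tracks,
        motifs=motifs,
        term_map=term_map,
        manifest=manifest,
        true_score_pairs=np.array(true_score_pairs),
    )


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _nearest_gene_id(genes: Sequence[GeneModel], chrom: str, pos: int) -> str | None:
    best, best_d = None, None
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(g.tss - pos)
        if best_d is None or d < best_d or (d == best_d and g.gene_id < best):
            best, best_d = g.gene_id, d
    return best


# ---------------------------------------------------------------------------
# evaluation against the manifest


@dataclass(frozen=True)
class TruthEvalResult:
    precision: float
    recall: float
    f1: float
    n_predicted: int
    n_truth: int
    degenerate: bool = False  # empty prediction: precision reported as 0


ENTITY_KINDS = ("tissue_specific_peak", "bivalent_gene", "de_gene", "enhancer_pair", "motif")


def _interval_of(x) -> GenomicInterval:
    if isinstance(x, GenomicInterval):
        return x
    if isinstance(x, Peak):
        return x.interval
    raise TypeError(f"expected interval or peak, got {type(x)}")


def _reciprocal_match(a: GenomicInterval, b: GenomicInterval, frac: float = 0.5) -> bool:
    ov = a.overlap_len(b)
    return ov >= frac * len(a) and ov >= frac * len(b)


def truth_eval(predicted: Sequence, manifest_entities: Sequence, entity_kind: str) -> TruthEvalResult:
    """Precision/recall/F1 of predictions against planted truth.

    Matching rules: peaks and motif loci by reciprocal overlap >= 0.5; gene
    kinds by id equality; enhancer pairs by same gene AND locus overlap.
    Predictions may be Peak/GenomicInterval, gene-id strings, or
    (gene_id, interval) pairs / EnhancerTargetPair-like objects depending on
    the kind.
    """
    if entity_kind not in ENTITY_KINDS:
        raise ValueError(f"unknown entity kind {entity_kind!r}")
    truth = list(manifest_entities)
    pred = list(predicted)
    n_p, n_t = len(pred), len(truth)
    if n_t == 0:
        raise ValueError("manifest has no entities of this kind")
    if n_p == 0:
        return TruthEvalResult(0.0, 0.0, 0.0, 0, n_t, degenerate=True)

    if entity_kind in ("tissue_specific_peak", "motif"):
        p_iv = [_interval_of(x) for x in pred]
        t_iv = [_interval_of(x) for x in truth]
        tp_pred = sum(any(_reciprocal_match(a, b) for b in t_iv) for a in p_iv)
        tp_truth = sum(any(_reciprocal_match(b, a) for a in p_iv) for b in t_iv)
    elif entity_kind in ("bivalent_gene", "de_gene"):
        pset, tset = set(pred), set(truth)
        tp_pred = len(pset & tset)
        tp_truth = tp_pred
        n_p, n_t = len(pset), len(tset)
    else:  # enhancer_pair
        def unpack(x):
            if hasattr(x, "gene_id") and hasattr(x, "locus"):
                return x.gene_id, x.locus
            gid, iv = x[0], x[1]
            return gid, _interval_of(iv)

        p_items = [unpack(x) for x in pred]
        t_items = [(g, _interval_of(iv)) for g, iv, *_ in truth]
        tp_pred = sum(
            any(g == tg and iv.overlaps(tiv) for tg, tiv in t_items) for g, iv in p_items
        )
        tp_truth = sum(
            any(g == tg and iv.overlaps(tiv) for g, iv in p_items) for tg, tiv in t_items
        )
    precision = tp_pred / n_p
    recall = tp_truth / n_t
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return TruthEvalResult(precision, recall, f1, n_p, n_t)
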