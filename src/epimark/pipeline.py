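"""End-to-end orchestration of the analysis stages.

Each stage reads the outputs of its upstream stages from the run directory,
writes its own outputs under ``<outdir>/<stage>/`` and records a
machine-readable ``log.json`` (version, resolved config, seed, input
checksums, summary counts). The stage dependency graph is explicit and
validated before any computation; deterministic stages are idempotent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import interval_algebra as ia
from .core_io import (
    Peak,
    GenomicInterval,
    read_expression,
    read_fasta,
    read_gene_models,
    read_jaspar,
    read_peaks,
    read_signal,
    write_peaks,
)
from .expression_enrichment import (
    filter_tissue_specific_de,
    gsea_preranked,
    ora_hypergeometric,
    partition_by_expression,
    read_term_map,
    simple_de,
)
from .integration import (
    assign_marks_to_genes,
    bivalent_loci,
    enhancer_target_pairs,
    pairs_to_table,
    tissue_specific_chromatin,
)
from .motif_enrichment import extract_peak_sequences, pfm_to_pwm, scan_sequence, sea_enrichment
from .reproducibility import fit_idr, match_replicate_peaks, replicable_broad, select_replicable_narrow
from .signal_profiles import fingerprint, metagene, spearman_matrix
from .synthetic_data import (
    BROAD_MARKS,
    MARKS,
    NARROW_MARKS,
    TISSUES,
    SyntheticConfig,
    generate,
    truth_eval,
)

__all__ = ["RunConfig", "run_stage", "run_all", "STAGE_ORDER", "load_config"]

_SAFE = {m: m.replace(".", "") for m in MARKS}
_UNSAFE = {v: k for k, v in _SAFE.items()}


@dataclass
class RunConfig:
    """Resolved run configuration; the shipped defaults are the study thresholds."""

    outdir: str = "epimark_run"
    seed: int = 0
    idr_narrow: float = 0.05
    idr_mixed: float = 0.10
    broad_frac: float = 0.3
    tpm: float = 1.0
    lfc: float = 2.0
    alpha: float = 0.05
    distal: int = 1500
    motif_q: float = 0.05
    motif_threshold_frac: float = 0.8
    gsea_permutations: int = 1000
    target_tissue: str = "trichome"

    def validate(self):
        for name, v, lo, hi in (
            ("idr_narrow", self.idr_narrow, 0, 1),
            ("idr_mixed", self.idr_mixed, 0, 1),
            ("broad_frac", self.broad_frac, 0, 1),
            ("alpha", self.alpha, 0, 1),
            ("motif_q", self.motif_q, 0, 1),
        ):
            if not lo < v <= hi:
                raise ValueError(f"threshold {name}={v} outside ({lo}, {hi}]")
        if self.distal < 0 or self.tpm < 0:
            raise ValueError("distal and tpm thresholds must be >= 0")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_log(stage_dir: Path, cfg: RunConfig, inputs: list[Path], counts: dict) -> None:
    log = {
        "stage": stage_dir.name,
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "input_checksums": {str(p): _md5(p) for p in inputs if p.is_file()},
        "counts": counts,
    }
    with open(stage_dir / "log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _peak_path(out: Path, stage: str, tissue: str, mark: str, suffix: str) -> Path:
    dialect = "narrowPeak" if mark in NARROW_MARKS else "broadPeak"
    return out / stage / f"{tissue}_{_SAFE[mark]}{suffix}.{dialect}"


def _read_stage_peaks(out: Path, stage: str, tissue: str, mark: str, suffix: str = "") -> list[Peak]:
    path = _peak_path(out, stage, tissue, mark, suffix)
    dialect = "narrowPeak" if mark in NARROW_MARKS else "broadPeak"
    return read_peaks(path, dialect, mark=mark, tissue=tissue, replicate="consolidated")


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    bundle = generate(SyntheticConfig(seed=cfg.seed))
    bundle.write(out / "simulate")
    return {
        "n_genes": len(bundle.genes),
        "n_de_planted": len(bundle.manifest.de_genes),
        "n_bivalent_planted": len(bundle.manifest.bivalent_genes),
        "n_enhancers_planted": len(bundle.manifest.enhancer_pairs),
    }


def _stage_consolidate(cfg: RunConfig, out: Path) -> dict:
    counts = {}
    for tissue in TISSUES:
        for mark in MARKS:
            dialect = "narrowPeak" if mark in NARROW_MARKS else "broadPeak"
            reps = [
                read_peaks(
                    out / "simulate" / "peaks" / f"{tissue}_{_SAFE[mark]}_rep{k}.{dialect}",
                    dialect,
                    mark=mark,
                    tissue=tissue,
                    replicate=f"rep{k}",
                )
                for k in (1, 2)
            ]
            if mark in NARROW_MARKS:
                pairs, _, _ = match_replicate_peaks(reps[0], reps[1])
                model = fit_idr(pairs, seed=cfg.seed)
                threshold = cfg.idr_narrow if mark == "H3K4me3" else cfg.idr_mixed
                consolidated = select_replicable_narrow(pairs, model, threshold)
            else:
                consolidated = replicable_broad(reps[0], reps[1], cfg.broad_frac)
            consolidated.sort(key=lambda p: (p.chrom, p.start, p.end))
            write_peaks(_peak_path(out, "consolidate", tissue, mark, ""), consolidated, dialect)
            counts[f"{tissue}_{mark}"] = len(consolidated)
    return counts


def _stage_correlate(cfg: RunConfig, out: Path) -> dict:
    track_dir = out / "simulate" / "tracks"
    tracks = []
    for tissue in TISSUES:
        for mark in MARKS:
            for k in (1, 2):
                path = track_dir / f"{tissue}_{_SAFE[mark]}_rep{k}.bedGraph"
                tracks.append(read_signal(path, label=f"{mark}_{tissue}_rep{k}"))
    mat = spearman_matrix(tracks)
    labels = [t.label for t in tracks]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(
        out / "correlate" / "spearman_matrix.tsv", sep="\t"
    )
    return {"n_tracks": len(tracks)}


def _stage_metagene(cfg: RunConfig, out: Path) -> dict:
    genes = read_gene_models(out / "simulate" / "annotation.gff3")
    expr = read_expression(out / "simulate" / "expression" / "tpm.tsv")
    transcribed, untranscribed = partition_by_expression(expr, cfg.target_tissue, cfg.tpm)
    rows = {}
    counts = {}
    for mark in MARKS:
        track = read_signal(
            out / "simulate" / "tracks" / f"{cfg.target_tissue}_{_SAFE[mark]}_rep1.bedGraph",
            label=mark,
        )
        for label, gene_set in (("transcribed", transcribed), ("untranscribed", untranscribed)):
            subset = [g for g in genes if g.gene_id in gene_set]
            prof = metagene(track, subset, label=label)
            rows[f"{mark}_{label}"] = prof.bin_values
            counts[f"{mark}_{label}_genes"] = prof.n_genes
        x, y = fingerprint(track)
        counts[f"{mark}_fingerprint_auc"] = float(np.trapezoid(y, x))
    pd.DataFrame(rows).to_csv(out / "metagene" / "profiles.tsv", sep="\t", index_label="bin")
    return counts


def _stage_feature_dist(cfg: RunConfig, out: Path) -> dict:
    genes = read_gene_models(out / "simulate" / "annotation.gff3")
    rows = []
    for mark in MARKS:
        peaks = _read_stage_peaks(out, "consolidate", cfg.target_tissue, mark)
        dist = ia.feature_distribution(peaks, genes)
        row = {"mark": mark, **dist.counts}
        row.update({f"frac_{k}": v for k, v in dist.fractions.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "feature-dist" / "feature_distribution.tsv", sep="\t", index=False)
    return {r["mark"]: sum(r[k] for k in ia.FEATURE_CLASSES) for r in rows}


def _stage_tissue_specific(cfg: RunConfig, out: Path) -> dict:
    counts = {}
    for mark in MARKS:
        by_tissue = {t: _read_stage_peaks(out, "consolidate", t, mark) for t in TISSUES}
        specific = tissue_specific_chromatin(mark, by_tissue, cfg.target_tissue)
        dialect = "narrowPeak" if mark in NARROW_MARKS else "broadPeak"
        write_peaks(
            _peak_path(out, "tissue-specific", cfg.target_tissue, mark, "_specific"),
            specific,
            dialect,
        )
        counts[mark] = len(specific)
    return counts


def _stage_bivalent(cfg: RunConfig, out: Path) -> dict:
    genes = read_gene_models(out / "simulate" / "annotation.gff3")
    expr = read_expression(out / "simulate" / "expression" / "tpm.tsv")
    transcribed, _ = partition_by_expression(expr, cfg.target_tissue, cfg.tpm)
    by_mark = {m: _read_stage_peaks(out, "consolidate", cfg.target_tissue, m) for m in MARKS}
    fragments, overlap_count = bivalent_loci(by_mark["H3K4me3"], by_mark["H3K27me3"])
    with open(out / "bivalent" / "bivalent_fragments.bed", "w") as fh:
        for iv in fragments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    states = assign_marks_to_genes(
        genes, by_mark, transcribed=transcribed, tissue=cfg.target_tissue
    )
    bivalent_genes = sorted(s.gene_id for s in states if s.bivalent)
    pd.DataFrame(bivalent_genes, columns=["gene_id"]).to_csv(
        out / "bivalent" / "bivalent_genes.tsv", sep="\t", index=False
    )
    # co-localization Fisher tests between mark pairs
    genome_size = 0
    sim_cfg = yaml.safe_load(open(out / "simulate" / "params.yaml"))["config"]
    genome_size = int(sim_cfg["n_chrom"]) * int(sim_cfg["chrom_len"])
    coloc_rows = []
    for a, b in (("H3K4me3", "H3K56ac"), ("H3K27me3", "H2A.Z"), ("H3K4me3", "H3K27me3")):
        table, p, odds = ia.colocalization_fisher(
            [pk.interval for pk in by_mark[a]], [pk.interval for pk in by_mark[b]], genome_size
        )
        coloc_rows.append(
            {
                "mark_a": a,
                "mark_b": b,
                "n_overlap": table.n11,
                "n_a_only": table.n12,
                "n_b_only": table.n21,
                "p": p,
                "odds_ratio": odds,
            }
        )
    pd.DataFrame(coloc_rows).to_csv(out / "bivalent" / "colocalization.tsv", sep="\t", index=False)
    return {
        "n_fragments": len(fragments),
        "n_overlapping_peaks": overlap_count,
        "n_bivalent_genes": len(bivalent_genes),
    }


def _stage_de(cfg: RunConfig, out: Path) -> dict:
    expr = read_expression(out / "simulate" / "expression" / "tpm.tsv")
    tissues = [t for t in expr.tissues() if t != cfg.target_tissue]
    tables = {}
    for other in tissues:
        de = simple_de(expr, cfg.target_tissue, other)
        tables[other] = de
        dest = out / "de" / f"{de.contrast}.tsv"
        tbl = de.table.copy()
        tbl.insert(0, "contrast", de.contrast)
        tbl.to_csv(dest, sep="\t", index=False)
    filtered = filter_tissue_specific_de(
        tables[tissues[0]], tables[tissues[1]], cfg.lfc, cfg.alpha
    )
    pd.DataFrame(sorted(filtered), columns=["gene_id"]).to_csv(
        out / "de" / "tissue_specific_genes.tsv", sep="\t", index=False
    )
    return {
        **{f"n_de_{t}": int(((tables[t].table.log2fc > cfg.lfc) & (tables[t].table.padj < cfg.alpha)).sum()) for t in tissues},
        "n_tissue_specific": len(filtered),
    }


def _stage_ora(cfg: RunConfig, out: Path) -> dict:
    term_map = read_term_map(out / "simulate" / "terms" / "term_map.tsv")
    expr = read_expression(out / "simulate" / "expression" / "tpm.tsv")
    universe = set(expr.gene_ids)
    query = set(
        pd.read_csv(out / "de" / "tissue_specific_genes.tsv", sep="\t")["gene_id"].astype(str)
    )
    results = ora_hypergeometric(query, term_map, universe)
    pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "padj": r.padj,
                "fold_enrichment": r.fold_enrichment,
            }
            for r in results
        ]
    ).to_csv(out / "ora" / "enrichment.tsv", sep="\t", index=False)
    return {"n_terms": len(results), "n_significant": sum(r.padj < cfg.alpha for r in results)}


def _stage_gsea(cfg: RunConfig, out: Path) -> dict:
    term_map = read_term_map(out / "simulate" / "terms" / "term_map.tsv")
    de_files = sorted((out / "de").glob(f"{cfg.target_tissue}_vs_*.tsv"))
    ranking_table = pd.read_csv(de_files[0], sep="\t")
    ranked = list(zip(ranking_table["gene_id"].astype(str), ranking_table["log2fc"].astype(float)))
    rows = []
    for tid, gene_set in sorted(term_map.items()):
        es, nes, p = gsea_preranked(
            ranked, gene_set, n_perm=cfg.gsea_permutations, seed=cfg.seed
        )
        rows.append({"term_id": tid, "ES": es, "NES": nes, "p": p})
    pd.DataFrame(rows).to_csv(out / "gsea" / "gsea.tsv", sep="\t", index=False)
    return {"n_terms": len(rows), "n_significant": sum(r["p"] < cfg.alpha for r in rows)}


def _stage_enhancer_targets(cfg: RunConfig, out: Path) -> dict:
    genes = read_gene_models(out / "simulate" / "annotation.gff3")
    specific = _read_stage_peaks(out, "tissue-specific", cfg.target_tissue, "H3K56ac", "_specific")
    de_set = set(
        pd.read_csv(out / "de" / "tissue_specific_genes.tsv", sep="\t")["gene_id"].astype(str)
    )
    from .core_io import read_de_table

    de_tables = [read_de_table(p) for p in sorted((out / "de").glob(f"{cfg.target_tissue}_vs_*.tsv"))]
    pairs, rejects = enhancer_target_pairs(specific, genes, de_set, de_tables, cfg.distal)
    pairs_to_table(pairs).to_csv(out / "enhancer-targets" / "pairs.tsv", sep="\t", index=False)
    rejects.to_csv(out / "enhancer-targets" / "rejects.tsv", sep="\t", index=False)
    return {"n_pairs": len(pairs), "n_rejects": len(rejects)}


def _stage_motif_enrich(cfg: RunConfig, out: Path) -> dict:
    genome = read_fasta(out / "simulate" / "genome.fa")
    specific = _read_stage_peaks(out, "tissue-specific", cfg.target_tissue, "H3K56ac", "_specific")
    all_k56 = _read_stage_peaks(out, "consolidate", cfg.target_tissue, "H3K56ac")
    motifs = read_jaspar(out / "simulate" / "motifs" / "motifs.jaspar")
    primary = extract_peak_sequences(specific, genome)
    control = extract_peak_sequences(all_k56, genome)
    results = sea_enrichment(
        primary, control, motifs, threshold_frac=cfg.motif_threshold_frac, alpha=cfg.motif_q
    )
    pd.DataFrame(
        [
            {
                "motif_id": r.motif_id,
                "tf_family": r.tf_family,
                "n_primary_hit": r.n_primary_hit,
                "n_primary": r.n_primary,
                "n_control_hit": r.n_control_hit,
                "n_control": r.n_control,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ]
    ).to_csv(out / "motif-enrich" / "motif_enrichment.tsv", sep="\t", index=False)
    return {"n_motifs": len(results), "n_significant": sum(r.q < cfg.motif_q for r in results)}


def _stage_evaluate(cfg: RunConfig, out: Path) -> dict:
    mdir = out / "simulate" / "manifest"
    rows = {}
    # tissue-specific peaks, per mark and pooled
    truth_df = pd.read_csv(mdir / "tissue_specific_peaks.tsv", sep="\t")
    pooled_pred, pooled_truth = [], []
    for mark in MARKS:
        pred = [
            p.interval
            for p in _read_stage_peaks(out, "tissue-specific", cfg.target_tissue, mark, "_specific")
        ]
        sub = truth_df[(truth_df["mark"] == mark) & (truth_df["tissue"] == cfg.target_tissue)]
        truth = [GenomicInterval(c, s, e) for c, s, e in zip(sub.chrom, sub.start, sub.end)]
        res = truth_eval(pred, truth, "tissue_specific_peak")
        rows[f"tissue_specific_{mark}"] = res
        pooled_pred += pred
        pooled_truth += truth
    rows["tissue_specific_all"] = truth_eval(pooled_pred, pooled_truth, "tissue_specific_peak")

    biv_truth = pd.read_csv(mdir / "bivalent_genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    biv_pred = pd.read_csv(out / "bivalent" / "bivalent_genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    rows["bivalent_gene"] = truth_eval(biv_pred, biv_truth, "bivalent_gene")

    de_truth = pd.read_csv(mdir / "de_genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    de_pred = pd.read_csv(out / "de" / "tissue_specific_genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    rows["de_gene"] = truth_eval(de_pred, de_truth, "de_gene")

    pair_truth_df = pd.read_csv(mdir / "enhancer_pairs.tsv", sep="\t")
    pair_truth = [
        (str(g), GenomicInterval(c, s, e), int(d))
        for g, c, s, e, d in zip(
            pair_truth_df.gene_id, pair_truth_df.chrom, pair_truth_df.start,
            pair_truth_df.end, pair_truth_df.distance,
        )
    ]
    pred_df = pd.read_csv(out / "enhancer-targets" / "pairs.tsv", sep="\t")
    pair_pred = [
        (str(g), GenomicInterval(c, s, e))
        for g, c, s, e in zip(pred_df.gene_id, pred_df.chrom, pred_df.start, pred_df.end)
    ] if len(pred_df) else []
    rows["enhancer_pair"] = truth_eval(pair_pred, pair_truth, "enhancer_pair")

    # motif-bearing loci: primary loci hit by a significantly enriched motif
    motif_truth_df = pd.read_csv(mdir / "motif_loci.tsv", sep="\t")
    motif_truth = [
        GenomicInterval(c, s, e)
        for c, s, e in zip(motif_truth_df.chrom, motif_truth_df.start, motif_truth_df.end)
    ]
    enr = pd.read_csv(out / "motif-enrich" / "motif_enrichment.tsv", sep="\t")
    sig_ids = set(enr.loc[enr["q"] < cfg.motif_q, "motif_id"].astype(str))
    genome = read_fasta(out / "simulate" / "genome.fa")
    specific = _read_stage_peaks(out, "tissue-specific", cfg.target_tissue, "H3K56ac", "_specific")
    motifs = [m for m in read_jaspar(out / "simulate" / "motifs" / "motifs.jaspar") if m.motif_id in sig_ids]
    motif_pred = []
    seqs = extract_peak_sequences(specific, genome)
    for p, (label, seq) in zip(specific, seqs.items()):
        for m in motifs:
            if scan_sequence(seq, pfm_to_pwm(m), cfg.motif_threshold_frac):
                motif_pred.append(p.interval)
                break
    if motif_truth:
        rows["motif"] = truth_eval(motif_pred, motif_truth, "motif")

    table = pd.DataFrame(
        [
            {
                "entity": name,
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
                "n_predicted": r.n_predicted,
                "n_truth": r.n_truth,
            }
            for name, r in rows.items()
        ]
    )
    table.to_csv(out / "evaluate" / "metrics.tsv", sep="\t", index=False)
    return {name: round(r.f1, 4) for name, r in rows.items()}


STAGES = {
    "simulate": ([], _stage_simulate),
    "consolidate": (["simulate"], _stage_consolidate),
    "correlate": (["simulate"], _stage_correlate),
    "metagene": (["simulate"], _stage_metagene),
    "feature-dist": (["simulate", "consolidate"], _stage_feature_dist),
    "tissue-specific": (["consolidate"], _stage_tissue_specific),
    "bivalent": (["simulate", "consolidate"], _stage_bivalent),
    "de": (["simulate"], _stage_de),
    "ora": (["simulate", "de"], _stage_ora),
    "gsea": (["simulate", "de"], _stage_gsea),
    "enhancer-targets": (["simulate", "tissue-specific", "de"], _stage_enhancer_targets),
    "motif-enrich": (["simulate", "consolidate", "tissue-specific"], _stage_motif_enrich),
    "evaluate": (
        ["simulate", "tissue-specific", "bivalent", "de", "enhancer-targets", "motif-enrich"],
        _stage_evaluate,
    ),
}
STAGE_ORDER = list(STAGES)


def run_stage(stage_name: str, config: RunConfig) -> dict:
    """Run one stage; upstream outputs must exist. Returns the summary counts."""
    if stage_name not in STAGES:
        raise ValueError(f"unknown stage {stage_name!r} (stages: {', '.join(STAGES)})")
    config.validate()
    out = Path(config.outdir)
    deps, fn = STAGES[stage_name]
    for dep in deps:
        if not (out / dep / "log.json").is_file():
            raise RuntimeError(
                f"stage {stage_name!r} requires stage {dep!r}; run it first"
            )
    stage_dir = out / stage_name
    stage_dir.mkdir(parents=True, exist_ok=True)
    counts = fn(config, out)
    inputs = [out / dep / "log.json" for dep in deps]
    _write_log(stage_dir, config, inputs, counts)
    return counts


def run_all(config: RunConfig) -> dict:
    """Run the full stage chain in dependency order."""
    summary = {}
    for stage in STAGE_ORDER:
        summary[stage] = run_stage(stage, config)
    return summary
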