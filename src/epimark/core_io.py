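"""Domain types and readers/writers for the formats the pipeline touches.

All coordinates are 0-based half-open internally; GFF3/GTF (1-based,
inclusive) are converted at the boundary. Chromosome names are taken
verbatim — no "chr" normalisation is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "ExpressionTable",
    "DETable",
    "SignalTrack",
    "MotifPFM",
    "read_peaks",
    "write_peaks",
    "read_gene_models",
    "write_gene_models",
    "read_expression",
    "write_expression",
    "read_de_table",
    "write_de_table",
    "read_signal",
    "write_signal",
    "read_fasta",
    "write_fasta",
    "read_jaspar",
    "write_jaspar",
    "check_chromosome_sets",
]

MARKS = ("H3K4me3", "H3K56ac", "H3K27me3", "H2A.Z")
TISSUES = ("trichome", "stem", "leaf")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if not self.start < self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0


@dataclass(frozen=True)
class Peak:
    """A called enrichment peak: an interval plus mark/tissue/replicate and scores.

    ``summit`` is the offset from ``interval.start`` (narrowPeak column 10);
    ``None`` means absent (encoded as -1 on disk).
    """

    interval: GenomicInterval
    mark: str | None = None
    tissue: str | None = None
    replicate: str | None = None
    score: float = 0.0
    neglog10p: float | None = None
    neglog10q: float | None = None
    summit: int | None = None

    def __post_init__(self):
        if self.score < 0:
            raise ValueError(f"negative score {self.score}")
        for label, v in (("neglog10p", self.neglog10p), ("neglog10q", self.neglog10q)):
            if v is not None and v < 0:
                raise ValueError(f"negative {label} {v}")
        if self.summit is not None and not 0 <= self.summit < len(self.interval):
            raise ValueError(
                f"summit {self.summit} outside [0, {len(self.interval)})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand-aware TSS/TES anchors.

    TSS is the first transcribed base: ``start`` on "+", ``end - 1`` on "-"
    (kept inside the interval). TES is the opposite end.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got {self.interval.strand!r}"
            )

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.interval.strand == "+" else self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class ExpressionTable:
    """Gene x sample TPM matrix with tissue/replicate sample metadata.

    Backed by a pandas DataFrame (genes as index, sample labels as columns);
    ``sample_tissue`` maps each sample label to its tissue.
    """

    def __init__(self, tpm: pd.DataFrame, sample_tissue: dict[str, str]):
        if tpm.index.duplicated().any():
            dups = tpm.index[tpm.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if (tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = [c for c in tpm.columns if c not in sample_tissue]
        if missing:
            raise ValueError(f"samples without tissue metadata: {missing}")
        self.tpm = tpm.astype(float)
        self.sample_tissue = dict(sample_tissue)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)

    def tissues(self) -> list[str]:
        seen = []
        for s in self.samples:
            t = self.sample_tissue[s]
            if t not in seen:
                seen.append(t)
        return seen

    def tissue_samples(self, tissue: str) -> list[str]:
        out = [s for s in self.samples if self.sample_tissue[s] == tissue]
        if not out:
            raise KeyError(f"unknown tissue {tissue!r}")
        return out

    def tissue_matrix(self, tissue: str) -> pd.DataFrame:
        return self.tpm[self.tissue_samples(tissue)]


class DETable:
    """Per-contrast differential-expression results (log2FC, p, BH-adjusted p)."""

    def __init__(self, contrast: str, table: pd.DataFrame):
        required = {"gene_id", "log2fc", "pvalue", "padj"}
        if not required.issubset(table.columns):
            raise ValueError(f"DE table needs columns {sorted(required)}")
        if table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in DE table")
        padj = table["padj"].to_numpy(float)
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError("padj outside [0, 1]")
        self.contrast = contrast
        self.table = table.reset_index(drop=True)

    def stats_for(self, gene_id: str) -> tuple[float, float]:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return float(row["log2fc"].iloc[0]), float(row["padj"].iloc[0])


class SignalTrack:
    """Binned coverage: sorted, non-overlapping (chrom, start, end, value) bins."""

    def __init__(self, label: str, bins: pd.DataFrame):
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(bins.columns):
            raise ValueError(f"signal track needs columns {sorted(required)}")
        bins = bins.reset_index(drop=True)
        if not np.isfinite(bins["value"].to_numpy(float)).all():
            raise ValueError("non-finite track value")
        for chrom, sub in bins.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if (e <= s).any():
                raise ValueError(f"empty bin on {chrom}")
            if len(s) > 1 and ((s[1:] < e[:-1]).any() or (s[1:] < s[:-1]).any()):
                raise FormatError(f"unsorted track (chromosome {chrom})")
        self.label = label
        self.bins = bins

    @property
    def values(self) -> np.ndarray:
        return self.bins["value"].to_numpy(float)

    def total(self) -> float:
        widths = (self.bins["end"] - self.bins["start"]).to_numpy(float)
        return float((self.values * widths).sum())

    def same_grid(self, other: "SignalTrack") -> bool:
        a, b = self.bins, other.bins
        return len(a) == len(b) and bool(
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )


ALPHABET = ("A", "C", "G", "T")


@dataclass
class MotifPFM:
    """A position frequency matrix over {A, C, G, T}: counts are 4 x L."""

    motif_id: str
    counts: np.ndarray
    name: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PFM counts must be a 4 x L matrix")
        if self.counts.shape[1] < 2:
            raise ValueError("motif length must be >= 2")
        if (self.counts < 0).any():
            raise ValueError("negative PFM count")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("PFM column with zero total count")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])


# ---------------------------------------------------------------------------
# peak files (BED6 / narrowPeak / broadPeak)

_DIALECT_MIN_COLS = {"bed6": 6, "broadPeak": 9, "narrowPeak": 10}


def _opt_float(tok: str) -> float | None:
    if tok in (".", "-1", "-1.0"):
        return None
    return float(tok)


def read_peaks(
    path,
    dialect: str = "narrowPeak",
    mark: str | None = None,
    tissue: str | None = None,
    replicate: str | None = None,
) -> list[Peak]:
    """Read a BED6/narrowPeak/broadPeak file into Peak records (order preserved)."""
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = _DIALECT_MIN_COLS[dialect]
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split("\t")
            if len(toks) < ncols:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= {ncols} columns, got {len(toks)}"
                )
            try:
                chrom = toks[0]
                start, end = int(toks[1]), int(toks[2])
                name = None if toks[3] == "." else toks[3]
                strand = toks[5] if toks[5] in ("+", "-", ".") else None
                if strand is None:
                    raise ValueError(f"unknown strand symbol {toks[5]!r}")
                if start < 0:
                    raise ValueError(f"negative coordinate {start}")
                if start >= end:
                    raise ValueError(f"start >= end ({start} >= {end})")
                score = 0.0
                nlp = nlq = None
                summit = None
                if dialect in ("narrowPeak", "broadPeak"):
                    sv = _opt_float(toks[6])
                    score = sv if sv is not None else 0.0
                    nlp = _opt_float(toks[7])
                    nlq = _opt_float(toks[8])
                    if dialect == "narrowPeak":
                        summit = int(toks[9])
                        if summit == -1:
                            summit = None
                else:
                    score = float(toks[4]) if toks[4] != "." else 0.0
                interval = GenomicInterval(chrom, start, end, strand, name)
                peaks.append(
                    Peak(
                        interval,
                        mark=mark,
                        tissue=tissue,
                        replicate=replicate,
                        score=score,
                        neglog10p=nlp,
                        neglog10q=nlq,
                        summit=summit,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return peaks


def _fmt_opt(v: float | None) -> str:
    return "-1" if v is None else format(v, "g")


def write_peaks(path, peaks: Iterable[Peak], dialect: str = "narrowPeak") -> None:
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            base = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.name or ".",
                str(int(min(1000, round(p.score)))),
                iv.strand,
            ]
            if dialect in ("narrowPeak", "broadPeak"):
                base += [format(p.score, "g"), _fmt_opt(p.neglog10p), _fmt_opt(p.neglog10q)]
            if dialect == "narrowPeak":
                base.append(str(p.summit) if p.summit is not None else "-1")
            fh.write("\t".join(base) + "\n")


# ---------------------------------------------------------------------------
# gene models (GFF3 / GTF)


def _gff3_gene_id(attrs: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:]
        if part.startswith("gene_id="):
            return part[8:]
    return None


def _gtf_gene_id(attrs: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith("gene_id"):
            return part.split(None, 1)[1].strip().strip('"')
    return None


def read_gene_models(path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene records (feature type ``gene``) from GFF3 or GTF.

    File coordinates are 1-based inclusive and converted to 0-based half-open.
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    extract = _gff3_gene_id if dialect == "gff3" else _gtf_gene_id
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) < 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            if toks[2] != "gene":
                continue
            try:
                start1, end1 = int(toks[3]), int(toks[4])
                strand = toks[6]
                if strand not in ("+", "-"):
                    raise ValueError(f"unknown strand symbol {strand!r}")
                gid = extract(toks[8])
                if gid is None:
                    raise ValueError("no gene id in attributes")
                if gid in seen:
                    raise ValueError(f"duplicate gene_id {gid!r}")
                seen.add(gid)
                genes.append(
                    GeneModel(gid, GenomicInterval(toks[0], start1 - 1, end1, strand, gid))
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def write_gene_models(path, genes: Iterable[GeneModel]) -> None:
    """Write genes as minimal GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "epimark",
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# expression / DE tables (TSV)


def read_expression(path) -> ExpressionTable:
    """Read a TPM TSV: gene_id column + one column per sample.

    Sample columns are named ``<tissue>_rep<k>``; tissue metadata is parsed
    from the label.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be gene_id")
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise FormatError(f"{path}: non-numeric cell at row {row + 2}, column {col!r}")
        df[col] = vals
    tpm = df.set_index("gene_id")
    sample_tissue = {c: c.rsplit("_rep", 1)[0] for c in tpm.columns}
    return ExpressionTable(tpm, sample_tissue)


def write_expression(path, expr: ExpressionTable) -> None:
    expr.tpm.rename_axis("gene_id").to_csv(path, sep="\t")


def read_de_table(path, contrast: str | None = None) -> DETable:
    df = pd.read_csv(path, sep="\t")
    for col in ("log2fc", "pvalue", "padj"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(f"{path}: non-numeric cell at row {row + 2}, column {col!r}")
        df[col] = vals
    if contrast is None:
        contrast = df["contrast"].iloc[0] if "contrast" in df.columns else "unnamed"
    return DETable(contrast, df[["gene_id", "log2fc", "pvalue", "padj"]])


def write_de_table(path, de: DETable) -> None:
    out = de.table.copy()
    out.insert(0, "contrast", de.contrast)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph


def read_signal(path, label: str | None = None) -> SignalTrack:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            toks = line.split("\t")
            if len(toks) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            try:
                rows.append((toks[0], int(toks[1]), int(toks[2]), float(toks[3])))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return SignalTrack(label or str(path), df)


def write_signal(path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.bins.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# JASPAR PFM text


def read_jaspar(path) -> list[MotifPFM]:
    """Read JASPAR-format PFMs.

    Accepts both the bracketed layout (``A  [ 3 5 ... ]``) and the bare
    matrix-only layout (4 numeric rows per motif in A/C/G/T order).
    """
    motifs: list[MotifPFM] = []
    header: tuple[str, str | None] | None = None
    rows: list[np.ndarray] = []

    def flush(lineno: int):
        nonlocal header, rows
        if not rows:
            header = None
            return
        if len(rows) != 4:
            raise FormatError(f"{path}: line {lineno}: motif with {len(rows)} rows (need 4)")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"{path}: line {lineno}: ragged PFM rows")
        mid, name = header if header else (f"motif{len(motifs) + 1}", None)
        motifs.append(MotifPFM(mid, np.vstack(rows), name=name))
        header, rows = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else None)
                continue
            body = line
            if body[0] in "ACGTacgt" and (len(body) == 1 or not body[1].isdigit()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            toks = body.split()
            try:
                row = np.array([float(t) for t in toks])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric cell ({exc})") from exc
            if row.size == 0:
                raise FormatError(f"{path}: line {lineno}: empty PFM row")
            rows.append(row)
            if len(rows) == 4 and header is None:
                flush(lineno)
        flush(lineno)
    return motifs


def write_jaspar(path, motifs: Sequence[MotifPFM]) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            name = f" {m.name}" if m.name else ""
            fh.write(f">{m.motif_id}{name}\n")
            for base, row in zip(ALPHABET, m.counts):
                cells = " ".join(format(v, "g") for v in row)
                fh.write(f"{base} [ {cells} ]\n")


def check_chromosome_sets(*named_sets: tuple[str, set[str]]) -> None:
    """Warn (not raise) when inputs disagree on chromosome names."""
    if len(named_sets) < 2:
        return
    union = set().union(*(s for _, s in named_sets))
    common = set.intersection(*(s for _, s in named_sets))
    if union != common:
        detail = "; ".join(
            f"{name}: missing {sorted(union - s)}" for name, s in named_sets if union - s
        )
        warnings.warn(f"chromosome sets disagree: {detail}", stacklevel=2)
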