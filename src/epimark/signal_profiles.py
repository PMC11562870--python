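"""Coverage-level QC: binned-track correlation, metagene profiles, fingerprints."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .core_io import GeneModel, SignalTrack

__all__ = ["MetageneProfile", "spearman_matrix", "metagene", "fingerprint"]


@dataclass
class MetageneProfile:
    """Mean normalized signal over upstream flank + scaled gene body + downstream flank."""

    gene_set_label: str
    bin_values: np.ndarray
    flank_bp: int
    flank_bins: int
    body_bins: int
    n_genes: int
    n_skipped: int

    def __post_init__(self):
        self.bin_values = np.asarray(self.bin_values, float)
        if self.bin_values.size != 2 * self.flank_bins + self.body_bins:
            raise ValueError("bin_values length does not match layout")
        if not np.isfinite(self.bin_values).all():
            raise ValueError("non-finite profile value")

    @property
    def tss_bin(self) -> int:
        """Index of the first body bin (the bin whose left edge is the TSS)."""
        return self.flank_bins


def spearman_matrix(tracks: Sequence[SignalTrack]) -> np.ndarray:
    """Pairwise Spearman rank correlation of tracks sharing one bin grid."""
    if len(tracks) < 2:
        raise ValueError("need >= 2 tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_grid(t):
            raise ValueError(f"track {t.label!r} is not on the same bin grid as {first.label!r}")
    ranks = np.vstack([rankdata(t.values, method="average") for t in tracks])
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    cov = rc @ rc.T
    sd = np.sqrt(np.diag(cov))
    mat = cov / np.outer(sd, sd)
    np.fill_diagonal(mat, 1.0)
    return mat


def _chrom_arrays(track: SignalTrack) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in track.bins.groupby("chrom", sort=False):
        out[chrom] = (
            sub["start"].to_numpy(int),
            sub["end"].to_numpy(int),
            sub["value"].to_numpy(float),
        )
    return out


def _interval_means(starts, ends, values, spans: np.ndarray) -> np.ndarray:
    """Mean track value over each half-open span, weighting bins by overlap."""
    # prefix sums of value*width and width let each query be two lookups
    widths = (ends - starts).astype(float)
    cum_vw = np.concatenate([[0.0], np.cumsum(values * widths)])
    edges = np.concatenate([starts, [ends[-1]]])

    def cum_at(pos: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, len(starts) - 1)
        base = cum_vw[idx]
        inside = np.clip(pos - starts[idx], 0, widths[idx].astype(int))
        return base + values[idx] * inside

    lo = np.clip(spans[:, 0], int(starts[0]), int(ends[-1]))
    hi = np.clip(spans[:, 1], int(starts[0]), int(ends[-1]))
    width = np.maximum(hi - lo, 0).astype(float)
    sums = cum_at(hi) - cum_at(lo)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(width > 0, sums / np.maximum(width, 1), 0.0)
    return means


def metagene(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
    flank_bins: int = 40,
    body_bins: int = 60,
    label: str = "genes",
) -> MetageneProfile:
    """Average strand-aware signal profile over flanks and length-scaled gene bodies.

    Genes shorter than ``body_bins`` bp are skipped (one body bin must cover
    at least one base) and counted in ``n_skipped``.
    """
    if not genes:
        raise ValueError("empty gene set")
    arrays = _chrom_arrays(track)
    profiles = []
    n_skipped = 0
    for g in genes:
        if g.chrom not in arrays or len(g.interval) < body_bins:
            n_skipped += 1
            continue
        starts, ends, values = arrays[g.chrom]
        gs, ge = g.interval.start, g.interval.end
        body_edges = np.linspace(gs, ge, body_bins + 1)
        up_edges = np.linspace(gs - flank_bp, gs, flank_bins + 1)
        down_edges = np.linspace(ge, ge + flank_bp, flank_bins + 1)
        edges = np.concatenate([up_edges[:-1], body_edges[:-1], down_edges])
        spans = np.column_stack([edges[:-1], edges[1:]]).round().astype(int)
        vec = _interval_means(starts, ends, values, spans)
        if g.interval.strand == "-":
            vec = vec[::-1]
        profiles.append(vec)
    if not profiles:
        raise ValueError("no gene long enough for the requested body binning")
    return MetageneProfile(
        gene_set_label=label,
        bin_values=np.mean(profiles, axis=0),
        flank_bp=flank_bp,
        flank_bins=flank_bins,
        body_bins=body_bins,
        n_genes=len(profiles),
        n_skipped=n_skipped,
    )


def fingerprint(track: SignalTrack) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative-enrichment (fingerprint) curve.

    Bins are sorted ascending by value; returns (fraction of bins, fraction
    of signal) with endpoints (0,0) and (1,1). A uniform track lies on the
    diagonal; concentrated signal hugs the x-axis.
    """
    v = np.sort(track.values)
    if v.size == 0:
        raise ValueError("empty track")
    if v[0] < 0:
        raise ValueError("negative track values")
    total = v.sum()
    if total <= 0:
        raise ValueError("zero-total track has no fingerprint")
    x = np.arange(0, v.size + 1) / v.size
    y = np.concatenate([[0.0], np.cumsum(v) / total])
    return x, y
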