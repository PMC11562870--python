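"""Known-motif enrichment in peak sequences.

Sequences under peaks are scanned on both strands with log-odds PWMs at a
fixed fraction of each motif's maximum score; enrichment of per-sequence hit
counts in a primary set versus a control set is tested with a one-sided
Fisher exact test and BH-adjusted across motifs (an SEA-style known-motif
test with a fixed rather than optimized threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ALPHABET, MotifPFM, Peak
from .expression_enrichment import bh_adjust

__all__ = [
    "PWM",
    "MotifEnrichmentResult",
    "extract_peak_sequences",
    "pfm_to_pwm",
    "scan_sequence",
    "sea_enrichment",
    "family_score_table",
]

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class PWM:
    """Log2-odds position weight matrix over a background composition."""

    motif_id: str
    log_odds: np.ndarray  # 4 x L
    background: np.ndarray  # length-4, sums to 1

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, float)
        self.background = np.asarray(self.background, float)
        if (self.background <= 0).any():
            raise ValueError("background must be strictly positive")
        if not np.isfinite(self.log_odds).all():
            raise ValueError("non-finite log-odds cell")

    @property
    def length(self) -> int:
        return int(self.log_odds.shape[1])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


@dataclass(frozen=True)
class MotifEnrichmentResult:
    """Per-motif sequence-level enrichment counts and Fisher/BH statistics."""

    motif_id: str
    tf_family: str
    n_primary_hit: int
    n_primary: int
    n_control_hit: int
    n_control: int
    p: float
    q: float

    def __post_init__(self):
        if not 0 <= self.n_primary_hit <= self.n_primary:
            raise ValueError("primary hit count outside [0, n_primary]")
        if not 0 <= self.n_control_hit <= self.n_control:
            raise ValueError("control hit count outside [0, n_control]")
        if self.q < self.p - 1e-12:
            raise ValueError("q must be >= p")


def extract_peak_sequences(peaks: Sequence[Peak], genome: Mapping[str, str]) -> dict[str, str]:
    """Upper-cased sequence under each peak, labelled ``chrom:start-end``."""
    out: dict[str, str] = {}
    for p in peaks:
        iv = p.interval if isinstance(p, Peak) else p
        if iv.chrom not in genome:
            raise KeyError(f"peak {iv.chrom}:{iv.start}-{iv.end}: unknown chromosome")
        seq = genome[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end ({len(seq)})"
            )
        out[f"{iv.chrom}:{iv.start}-{iv.end}"] = seq[iv.start : iv.end].upper()
    return out


def pfm_to_pwm(
    pfm: MotifPFM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.25,
) -> PWM:
    """Standard PFM -> log2-odds PWM with background-proportional pseudocounts.

    Per column: freq = (count + pseudocount*background) / (total + pseudocount).
    """
    bg = np.asarray(background, float)
    if (bg <= 0).any():
        raise ValueError("background with zero entry")
    totals = pfm.counts.sum(axis=0)
    freq = (pfm.counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    return PWM(pfm.motif_id, np.log2(freq / bg[:, None]), bg)


def _encode(seq: str) -> np.ndarray:
    """Sequence -> indices 0..3; any non-ACGT base becomes 4 (ambiguous)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Score of every length-L window; ambiguous bases contribute the
    background-weighted mean cell of their column."""
    L = lom.shape[1]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    for j in range(L):
        col = codes[j : j + n_win]
        scores += lom[np.minimum(col, 3), j] * (col < 4) + lom[4, j] * (col == 4)
    return scores


def _lom_with_ambiguous(pwm: PWM) -> np.ndarray:
    """5 x L matrix: rows A,C,G,T plus the N row (background-weighted mean)."""
    n_row = (pwm.background[:, None] * pwm.log_odds).sum(axis=0)
    return np.vstack([pwm.log_odds, n_row])


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def scan_sequence(
    seq: str, pwm: PWM, threshold_frac: float = 0.8
) -> list[tuple[int, str, float]]:
    """Both-strand PWM scan; hits are windows scoring >= threshold_frac * max_score.

    Offsets index the forward sequence (window start) on both strands.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError(f"threshold_frac {threshold_frac} outside (0, 1]")
    L = pwm.length
    if len(seq) < L:
        return []
    lom = _lom_with_ambiguous(pwm)
    threshold = threshold_frac * pwm.max_score
    hits = []
    fwd = _window_scores(_encode(seq), lom)
    rc = seq.translate(_COMPLEMENT)[::-1]
    rev = _window_scores(_encode(rc), lom)[::-1]  # rev[i]: window starting at i, minus strand
    for i in np.nonzero(fwd >= threshold)[0]:
        hits.append((int(i), "+", float(fwd[i])))
    for i in np.nonzero(rev >= threshold)[0]:
        hits.append((int(i), "-", float(rev[i])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def sea_enrichment(
    primary_seqs: Mapping[str, str] | Sequence[str],
    control_seqs: Mapping[str, str] | Sequence[str],
    motifs: Sequence[MotifPFM | PWM],
    threshold_frac: float = 0.8,
    alpha: float = 0.05,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    family_map: Mapping[str, str] | None = None,
) -> list[MotifEnrichmentResult]:
    """Per-motif one-sided Fisher test of per-sequence hit rates, primary vs control.

    Sequences count zero-or-one per motif (SEA's sequence-level table);
    q-values are BH over the scanned motifs.
    """
    primary = list(primary_seqs.values()) if isinstance(primary_seqs, Mapping) else list(primary_seqs)
    control = list(control_seqs.values()) if isinstance(control_seqs, Mapping) else list(control_seqs)
    if not primary or not control:
        raise ValueError("primary and control sequence sets must be non-empty")
    family_map = dict(family_map or {})
    rows = []
    for m in motifs:
        pwm = m if isinstance(m, PWM) else pfm_to_pwm(m, background)
        if all(len(s) < pwm.length for s in primary):
            warnings.warn(
                f"motif {pwm.motif_id} is longer than every primary sequence", stacklevel=2
            )
            rows.append((pwm.motif_id, 0, 0, 1.0))
            continue
        n_hit_p = sum(bool(scan_sequence(s, pwm, threshold_frac)) for s in primary)
        n_hit_c = sum(bool(scan_sequence(s, pwm, threshold_frac)) for s in control)
        table = np.array(
            [
                [n_hit_p, len(primary) - n_hit_p],
                [n_hit_c, len(control) - n_hit_c],
            ]
        )
        p = float(stats.fisher_exact(table, alternative="greater").pvalue)
        rows.append((pwm.motif_id, n_hit_p, n_hit_c, p))
    qs = bh_adjust([r[3] for r in rows])
    results = [
        MotifEnrichmentResult(
            motif_id=mid,
            tf_family=family_map.get(mid, "unknown"),
            n_primary_hit=nhp,
            n_primary=len(primary),
            n_control_hit=nhc,
            n_control=len(control),
            p=p,
            q=float(q),
        )
        for (mid, nhp, nhc, p), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.motif_id))
    return results


def family_score_table(
    results: Sequence[MotifEnrichmentResult], family_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-TF-family table of (motif, -log10 q) for beeswarm-style summaries."""
    family_map = dict(family_map or {})
    rows = [
        {
            "tf_family": family_map.get(r.motif_id, r.tf_family),
            "motif_id": r.motif_id,
            "neglog10_q": float(-np.log10(max(r.q, 1e-300))),
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=["tf_family", "motif_id", "neglog10_q"])
    return df.sort_values(["tf_family", "motif_id"], ignore_index=True)
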