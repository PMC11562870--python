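"""Replicate consolidation of peak calls.

Narrow and mixed peak types go through the two-component Gaussian copula
mixture behind the irreproducible discovery rate (IDR): matched replicate
peak pairs are ranked, mapped to pseudo-data under the current mixture
marginal, and a pseudo-EM alternates posterior reproducibility (E-step) with
moment updates of (pi1, mu, sigma, rho) (CM-step), recomputing the
pseudo-data each outer iteration. Broad domains are consolidated by the
30% reciprocal-overlap intersection of the two replicates instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm, rankdata

from .core_io import GenomicInterval, Peak, SignalTrack

__all__ = [
    "MatchedPeakPair",
    "IDRModel",
    "match_replicate_peaks",
    "fit_idr",
    "simulate_idr_pairs",
    "select_replicable_narrow",
    "replicable_broad",
    "scale_track",
]

_EPS = 1e-4  # clamp distance from each parameter's domain boundary
_RHO_DEGENERATE = 0.05  # below this the mixture cannot separate reproducibility


@dataclass(frozen=True)
class MatchedPeakPair:
    """One peak per replicate, matched by overlap."""

    peak1: Peak
    peak2: Peak
    overlap_len: int

    def __post_init__(self):
        if self.overlap_len < 1:
            raise ValueError("matched pair must overlap by >= 1 bp")
        if self.peak1.chrom != self.peak2.chrom:
            raise ValueError("matched peaks must share a chromosome")

    def scores(self, score_field: str = "neglog10p") -> tuple[float, float]:
        def get(p: Peak) -> float:
            v = getattr(p, score_field, None)
            if v is None:
                v = p.score
            return float(v)

        return get(self.peak1), get(self.peak2)


@dataclass
class IDRModel:
    """Fitted copula-mixture parameters plus per-pair local/global IDR."""

    pi1: float
    mu: float
    sigma: float
    rho: float
    local_idr: np.ndarray
    global_idr: np.ndarray
    converged: bool
    n_iter: int

    def __post_init__(self):
        for name, arr in (("local_idr", self.local_idr), ("global_idr", self.global_idr)):
            arr = np.asarray(arr, float)
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} outside [0, 1]")


def match_replicate_peaks(
    rep1: Sequence[Peak], rep2: Sequence[Peak]
) -> tuple[list[MatchedPeakPair], list[Peak], list[Peak]]:
    """Greedy one-to-one matching of overlapping peaks across two replicates.

    Candidate pairs are all overlapping pairs, taken by descending overlap
    length (ties by (chrom, start) of the replicate-1 peak, then of the
    replicate-2 peak); each peak is used at most once. Returns
    (pairs, unmatched_rep1, unmatched_rep2).
    """
    by_chrom2: dict[str, list[tuple[int, Peak]]] = {}
    for j, p in enumerate(rep2):
        by_chrom2.setdefault(p.chrom, []).append((j, p))
    candidates = []
    for i, a in enumerate(rep1):
        for j, b in by_chrom2.get(a.chrom, ()):
            ov = a.interval.overlap_len(b.interval)
            if ov > 0:
                candidates.append((-ov, a.chrom, a.start, b.start, i, j))
    candidates.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    pairs: list[MatchedPeakPair] = []
    for neg_ov, _, _, _, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairs.append(MatchedPeakPair(rep1[i], rep2[j], -neg_ov))
    unmatched1 = [p for i, p in enumerate(rep1) if i not in used1]
    unmatched2 = [p for j, p in enumerate(rep2) if j not in used2]
    return pairs, unmatched1, unmatched2


def _mixture_marginal_inverse(u: np.ndarray, pi1: float, mu: float, sigma: float) -> np.ndarray:
    """Invert G(z) = pi1*Phi((z-mu)/sigma) + (1-pi1)*Phi(z) at u (vectorized).

    Grid interpolation refined by two Newton steps; G is strictly increasing.
    """
    lo = min(norm.ppf(u.min()) - 1.0, mu + sigma * norm.ppf(u.min()) - 1.0)
    hi = max(norm.ppf(u.max()) + 1.0, mu + sigma * norm.ppf(u.max()) + 1.0)
    grid = np.linspace(lo, hi, 4096)
    G = pi1 * norm.cdf((grid - mu) / sigma) + (1 - pi1) * norm.cdf(grid)
    z = np.interp(u, G, grid)
    for _ in range(2):
        g = pi1 * norm.pdf((z - mu) / sigma) / sigma + (1 - pi1) * norm.pdf(z)
        Gz = pi1 * norm.cdf((z - mu) / sigma) + (1 - pi1) * norm.cdf(z)
        z = z - (Gz - u) / np.maximum(g, 1e-12)
    return z


def _bvn_logpdf(z1, z2, mu, sigma, rho):
    q = ((z1 - mu) ** 2 - 2 * rho * (z1 - mu) * (z2 - mu) + (z2 - mu) ** 2) / (sigma**2)
    return -np.log(2 * np.pi * sigma**2 * np.sqrt(1 - rho**2)) - q / (2 * (1 - rho**2))


def fit_idr(
    pairs: Sequence[MatchedPeakPair] | tuple[np.ndarray, np.ndarray],
    score_field: str = "neglog10p",
    init: tuple[float, float, float, float] = (0.7, 2.6, 1.3, 0.8),
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int | None = None,
) -> IDRModel:
    """Fit the two-component Gaussian copula mixture to matched score pairs.

    Scores are converted to average ranks, then uniform pseudo-values
    u_i = (rank_i - 0.5)/n, then pseudo-data z_i = G^{-1}(u_i) under the
    current mixture marginal. Each outer iteration recomputes the
    pseudo-data, takes one E-step (posterior reproducibility) and one
    CM-step (posterior-weighted moments), stopping when the largest absolute
    parameter change drops below ``tol``. ``seed`` is accepted for interface
    symmetry; the fit is deterministic (average-rank ties, no jitter).
    """
    if isinstance(pairs, tuple):
        x, y = (np.asarray(v, float) for v in pairs)
    else:
        sc = np.array([p.scores(score_field) for p in pairs], float)
        if sc.size == 0:
            raise ValueError("insufficient data: need >= 50 matched pairs, got 0")
        x, y = sc[:, 0], sc[:, 1]
    n = x.size
    if n < 50:
        raise ValueError(f"insufficient data: need >= 50 matched pairs, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite scores")

    u1 = (rankdata(x, method="average") - 0.5) / n
    u2 = (rankdata(y, method="average") - 0.5) / n

    pi1, mu, sigma, rho = init
    converged = False
    it = 0
    K = np.full(n, pi1)
    for it in range(1, max_iter + 1):
        z1 = _mixture_marginal_inverse(u1, pi1, mu, sigma)
        z2 = _mixture_marginal_inverse(u2, pi1, mu, sigma)
        # E-step: posterior probability of the reproducible component
        log_f1 = np.log(pi1) + _bvn_logpdf(z1, z2, mu, sigma, rho)
        log_f0 = np.log1p(-pi1) + _bvn_logpdf(z1, z2, 0.0, 1.0, 0.0)
        m = np.maximum(log_f1, log_f0)
        K = np.exp(log_f1 - m) / (np.exp(log_f1 - m) + np.exp(log_f0 - m))
        # CM-step: posterior-weighted moments of the reproducible component
        sK = K.sum()
        new_pi1 = float(np.clip(K.mean(), _EPS, 1 - _EPS))
        if sK <= 0:
            new_mu, new_sigma, new_rho = mu, sigma, rho
        else:
            new_mu = float((K * (z1 + z2)).sum() / (2 * sK))
            var = (K * ((z1 - new_mu) ** 2 + (z2 - new_mu) ** 2)).sum() / (2 * sK)
            new_sigma = float(np.sqrt(max(var, _EPS**2)))
            new_rho = float(
                np.clip(
                    (K * (z1 - new_mu) * (z2 - new_mu)).sum() / (sK * new_sigma**2),
                    _EPS,
                    1 - _EPS,
                )
            )
        new_mu = max(new_mu, _EPS)
        delta = max(
            abs(new_pi1 - pi1), abs(new_mu - mu), abs(new_sigma - sigma), abs(new_rho - rho)
        )
        pi1, mu, sigma, rho = new_pi1, new_mu, new_sigma, new_rho
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"IDR fit did not converge in {max_iter} iterations", stacklevel=2)

    if rho <= _RHO_DEGENERATE:
        # the fitted "reproducible" component carries no dependence: the two
        # components are likelihood-equivalent relabelings (as happens on
        # independent replicates) and no pair can be certified reproducible
        warnings.warn(
            "degenerate IDR fit (rho at boundary): no reproducible component identified",
            stacklevel=2,
        )
        ones = np.ones(n)
        return IDRModel(pi1, mu, sigma, rho, ones, ones.copy(), converged, it)

    local_idr = 1.0 - K
    # global IDR: cumulative mean of sorted local IDR, constant on tie blocks
    sorted_local = np.sort(local_idr)
    cummean = np.cumsum(sorted_local) / np.arange(1, n + 1)
    pos = np.searchsorted(sorted_local, local_idr, side="right") - 1
    global_idr = cummean[pos]
    return IDRModel(
        pi1=pi1,
        mu=mu,
        sigma=sigma,
        rho=rho,
        local_idr=np.clip(local_idr, 0.0, 1.0),
        global_idr=np.clip(global_idr, 0.0, 1.0),
        converged=converged,
        n_iter=it,
    )


def simulate_idr_pairs(
    n: int,
    pi1: float = 0.7,
    mu: float = 2.5,
    sigma: float = 1.3,
    rho: float = 0.8,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (score1, score2, is_reproducible) from the copula mixture model."""
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < pi1
    z = rng.standard_normal((n, 2))
    x = np.where(labels, mu + sigma * z[:, 0], z[:, 0])
    y2 = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    y = np.where(labels, mu + sigma * y2, z[:, 1])
    return x, y, labels


def select_replicable_narrow(
    pairs: Sequence[MatchedPeakPair], model: IDRModel, threshold: float
) -> list[Peak]:
    """Consolidate pairs passing the global-IDR cutoff.

    Each consolidated peak is the union span of the matched pair with the
    mean replicate score; the global IDR is carried in the q-value slot as
    -log10(global IDR).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    if len(model.global_idr) != len(pairs):
        raise ValueError("model does not cover the given pairs")
    out = []
    for pair, gidr in zip(pairs, model.global_idr):
        if gidr > threshold:
            continue
        a, b = pair.peak1.interval, pair.peak2.interval
        union = GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end), name=a.name)
        out.append(
            Peak(
                union,
                mark=pair.peak1.mark,
                tissue=pair.peak1.tissue,
                replicate="consolidated",
                score=(pair.peak1.score + pair.peak2.score) / 2.0,
                neglog10q=float(-np.log10(max(gidr, 1e-300))),
            )
        )
    return out


def replicable_broad(
    rep1: Sequence[Peak], rep2: Sequence[Peak], min_frac: float = 0.3
) -> list[Peak]:
    """Broad domains of replicate 1 with a >= min_frac reciprocal overlap in replicate 2.

    Whole replicate-1 domains are reported (``-wa``-like), tagged
    replicate="consolidated".
    """
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac {min_frac} outside (0, 1]")
    by_chrom2: dict[str, list[Peak]] = {}
    for p in rep2:
        by_chrom2.setdefault(p.chrom, []).append(p)
    out = []
    for a in rep1:
        for b in by_chrom2.get(a.chrom, ()):
            ov = a.interval.overlap_len(b.interval)
            if ov >= min_frac * len(a.interval) and ov >= min_frac * len(b.interval):
                out.append(
                    Peak(
                        a.interval,
                        mark=a.mark,
                        tissue=a.tissue,
                        replicate="consolidated",
                        score=a.score,
                        neglog10p=a.neglog10p,
                        neglog10q=a.neglog10q,
                    )
                )
                break
    return out


def scale_track(track: SignalTrack, reference_total: float) -> SignalTrack:
    """Rescale a coverage track so its total signal equals ``reference_total``."""
    total = track.total()
    if total <= 0:
        raise ValueError("zero-total track cannot be scaled")
    bins = track.bins.copy()
    bins["value"] = bins["value"] * (reference_total / total)
    return SignalTrack(track.label, bins)
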