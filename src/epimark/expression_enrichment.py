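"""Transcriptome-side statistics.

Transcribed/untranscribed partition at a TPM cutoff, a documented Welch-test
stand-in for differential expression on log2(TPM+1), Benjamini-Hochberg
adjustment, hypergeometric over-representation, preranked GSEA
(weighted Kolmogorov-Smirnov running sum with gene-label permutations), and
cross-dataset gene-set expression correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DETable, ExpressionTable

__all__ = [
    "TermMap",
    "EnrichmentResult",
    "partition_by_expression",
    "simple_de",
    "bh_adjust",
    "filter_tissue_specific_de",
    "ora_hypergeometric",
    "gsea_preranked",
    "geneset_expression_correlation",
    "read_term_map",
    "write_term_map",
]


class TermMap:
    """term_id -> gene set, with optional descriptions."""

    def __init__(self, terms: Mapping[str, set], descriptions: Mapping[str, str] | None = None):
        for tid, genes in terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} is empty")
        self.terms = {t: set(g) for t, g in terms.items()}
        self.descriptions = dict(descriptions or {})

    def __len__(self):
        return len(self.terms)

    def items(self):
        return self.terms.items()

    def restricted_to(self, universe: set) -> "TermMap":
        kept = {t: g & universe for t, g in self.terms.items() if g & universe}
        return TermMap(kept, self.descriptions)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics."""

    term_id: str
    k: int  # overlap
    K: int  # term size in the universe
    n: int  # query size
    N: int  # universe size
    p: float
    padj: float
    fold_enrichment: float

    def __post_init__(self):
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError("overlap k outside [0, min(K, n)]")
        if not (0 < self.p <= 1 and 0 < self.padj <= 1):
            raise ValueError("p-values must lie in (0, 1]")


def read_term_map(path, description_path=None) -> TermMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"])
    terms: dict[str, set] = {}
    for tid, gid in df.itertuples(index=False):
        terms.setdefault(str(tid), set()).add(str(gid))
    desc = {}
    if description_path is not None:
        dd = pd.read_csv(description_path, sep="\t", header=None, names=["term_id", "description"])
        desc = dict(zip(dd["term_id"].astype(str), dd["description"].astype(str)))
    return TermMap(terms, desc)


def write_term_map(path, term_map: TermMap) -> None:
    with open(path, "w") as fh:
        for tid in sorted(term_map.terms):
            for gid in sorted(term_map.terms[tid]):
                fh.write(f"{tid}\t{gid}\n")


def partition_by_expression(
    expr: ExpressionTable, tissue: str, tpm_threshold: float = 1.0
) -> tuple[set, set]:
    """Split genes into transcribed (mean TPM across the tissue's replicates
    >= threshold) and untranscribed; exhaustive and disjoint."""
    sub = expr.tissue_matrix(tissue)
    means = sub.mean(axis=1)
    transcribed = set(means.index[means >= tpm_threshold])
    untranscribed = set(means.index[means < tpm_threshold])
    return transcribed, untranscribed


def simple_de(expr: ExpressionTable, tissue_a: str, tissue_b: str) -> DETable:
    """Welch two-sample t-test on log2(TPM+1), per gene, a vs b.

    A deliberately simple stand-in for a count-model DE fit: log2fc is the
    mean log2(TPM+1) difference (a - b); genes with zero variance in both
    groups get p = 1. BH adjustment is applied across all genes.
    """
    A = np.log2(expr.tissue_matrix(tissue_a).to_numpy(float) + 1.0)
    B = np.log2(expr.tissue_matrix(tissue_b).to_numpy(float) + 1.0)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("need >= 2 replicates per tissue")
    lfc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, float)
    zero_var = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    padj = bh_adjust(p)
    table = pd.DataFrame(
        {"gene_id": expr.gene_ids, "log2fc": lfc, "pvalue": p, "padj": padj}
    )
    return DETable(f"{tissue_a}_vs_{tissue_b}", table)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    # BH can only inflate: enforced as a sanity assertion, not a correction
    assert (out >= p - 1e-15).all()
    return out


def filter_tissue_specific_de(
    de_vs_stem: DETable, de_vs_leaf: DETable, min_lfc: float = 2.0, alpha: float = 0.05
) -> set:
    """Genes with log2fc > min_lfc AND padj < alpha in BOTH contrasts (strict)."""

    def passing(de: DETable) -> set:
        t = de.table
        return set(t.loc[(t["log2fc"] > min_lfc) & (t["padj"] < alpha), "gene_id"])

    return passing(de_vs_stem) & passing(de_vs_leaf)


def ora_hypergeometric(
    query_genes: set, term_map: TermMap, universe: set
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the query set.

    p = P(X >= k) with X ~ Hypergeom(N, K, n); BH across terms; sorted by
    (padj, p, term_id).
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    if not query_genes:
        raise ValueError("empty query")
    if not set(query_genes) <= universe:
        raise ValueError("query genes must be a subset of the universe")
    restricted = term_map.restricted_to(universe)
    N, n = len(universe), len(query)
    rows = []
    for tid, genes in restricted.items():
        K = len(genes)
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        fold = (k / n) / (K / N) if k else 0.0
        rows.append((tid, k, K, p, fold))
    padj = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(tid, k, K, n, N, p, float(min(max(q, np.nextafter(0, 1)), 1.0)), fold)
        for (tid, k, K, p, fold), q in zip(rows, padj)
    ]
    results.sort(key=lambda r: (r.padj, r.p, r.term_id))
    return results


def _es_running(in_set: np.ndarray, scores: np.ndarray, weight: float) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    N = in_set.size
    n_hits = int(in_set.sum())
    w = np.abs(scores) ** weight
    hit_total = w[in_set].sum()
    if hit_total <= 0:  # all hit scores zero: fall back to unweighted hits
        inc = in_set / max(n_hits, 1)
    else:
        inc = np.where(in_set, w / hit_total, 0.0)
    dec = np.where(~in_set, 1.0 / (N - n_hits), 0.0) if N > n_hits else 0.0
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(
    ranked_genes_with_scores: Sequence[tuple[str, float]],
    gene_set: set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Preranked GSEA: (ES, NES, permutation p).

    Genes are ordered by descending score; hits add |score|^weight
    (normalized by the hit total) and misses subtract 1/(N - n_hits). The
    null shuffles gene labels ``n_perm`` times; NES divides ES by the mean
    |null ES| of the same sign and p is the same-sign tail fraction with +1
    smoothing.
    """
    items = sorted(ranked_genes_with_scores, key=lambda gs: -gs[1])
    genes = [g for g, _ in items]
    scores = np.array([s for _, s in items], float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite ranking scores")
    in_set = np.array([g in gene_set for g in genes])
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene_set is disjoint from the ranked list")
    if n_hits == in_set.size:
        raise ValueError("gene_set covers the whole ranked list")
    es = _es_running(in_set, scores, weight)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(in_set.size)
    for b in range(n_perm):
        perm = np.zeros(in_set.size, bool)
        perm[rng.choice(idx, size=n_hits, replace=False)] = True
        null[b] = _es_running(perm, scores, weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
    nes = es / denom if denom > 0 else 0.0
    n_extreme = int((np.abs(same_sign) >= abs(es)).sum())
    p = (1 + n_extreme) / (1 + same_sign.size)
    return es, float(nes), float(p)


def geneset_expression_correlation(
    expression_tables: Sequence[ExpressionTable], gene_set: set
) -> tuple[np.ndarray, list[str], int]:
    """Pairwise Spearman correlation of samples restricted to a gene set.

    The gene set is intersected with every table's genes; returns
    (matrix, sample labels, n genes used).
    """
    common = set(gene_set)
    for t in expression_tables:
        common &= set(t.gene_ids)
    if not common:
        raise ValueError("gene_set intersection with the tables is empty")
    genes = sorted(common)
    cols, labels = [], []
    for t in expression_tables:
        sub = t.tpm.loc[genes]
        for s in t.samples:
            cols.append(sub[s].to_numpy(float))
            labels.append(s)
    if len(cols) < 2:
        raise ValueError("need >= 2 samples")
    ranks = np.vstack([stats.rankdata(c, method="average") for c in cols])
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    cov = rc @ rc.T
    sd = np.sqrt(np.diag(cov))
    mat = cov / np.outer(sd, sd)
    np.fill_diagonal(mat, 1.0)
    return mat, labels, len(genes)
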