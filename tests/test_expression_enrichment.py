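"""Expression partition, stand-in DE test, BH, ORA, preranked GSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from epimark.core_io import ExpressionTable
from epimark.expression_enrichment import (
    TermMap,
    bh_adjust,
    filter_tissue_specific_de,
    geneset_expression_correlation,
    gsea_preranked,
    ora_hypergeometric,
    partition_by_expression,
    simple_de,
)


def make_expr(matrix, gene_ids=None, tissues=("trichome", "stem"), n_rep=3):
    matrix = np.asarray(matrix, float)
    gene_ids = gene_ids or [f"g{i}" for i in range(matrix.shape[0])]
    cols = [f"{t}_rep{k}" for t in tissues for k in range(1, n_rep + 1)]
    df = pd.DataFrame(matrix, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    return ExpressionTable(df, {c: c.rsplit("_rep", 1)[0] for c in cols})


class TestPartition:
    def test_mean_threshold(self):
        expr = make_expr([[0.5, 1.5, 2.0, 0, 0, 0], [0, 0, 0, 0, 0, 0]])
        tx, untx = partition_by_expression(expr, "trichome", 1.0)
        assert tx == {"g0"} and untx == {"g1"}

    def test_partition_is_exhaustive_and_matches_oracle(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0, 3, (50, 6))
        expr = make_expr(m)
        tx, untx = partition_by_expression(expr, "stem", 1.0)
        assert tx | untx == set(expr.gene_ids) and not (tx & untx)
        for i, g in enumerate(expr.gene_ids):
            assert (g in tx) == (m[i, 3:].mean() >= 1.0)

    def test_unknown_tissue(self):
        with pytest.raises(KeyError):
            partition_by_expression(make_expr(np.ones((2, 6))), "root")


class TestSimpleDe:
    def test_identical_groups(self):
        m = np.tile([[4.0], [9.0]], (1, 6))
        de = simple_de(make_expr(m), "trichome", "stem")
        assert np.allclose(de.table["log2fc"], 0.0)
        assert np.allclose(de.table["pvalue"], 1.0)

    def test_swap_negates_lfc(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.uniform(0, 50, (30, 6)))
        ab = simple_de(expr, "trichome", "stem").table
        ba = simple_de(expr, "stem", "trichome").table
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])

    def test_power_on_planted_gene(self):
        # one gene with true log2FC 6 at 10% CV, 3 vs 3 replicates
        hits = 0
        n_sims = 100
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            base = np.full((100, 6), 0.0)
            means = rng.lognormal(np.log(8), 1.0, 100)
            noise = rng.lognormal(0, 0.0998, (100, 6))
            m = means[:, None] * noise
            m[0, :3] *= 2.0**6
            de = simple_de(make_expr(m), "trichome", "stem")
            row = de.table.iloc[0]
            if row["padj"] < 0.05 and row["log2fc"] > 2:
                hits += 1
        assert hits >= 95

    def test_type_one_error_near_nominal(self):
        # no planted effect: rejection rate at p < 0.05 close to nominal
        rates = []
        for s in range(20):
            rng = np.random.default_rng(2000 + s)
            m = rng.lognormal(np.log(8), 1.0, 100)[:, None] * rng.lognormal(0, 0.0998, (100, 6))
            de = simple_de(make_expr(m), "trichome", "stem")
            rates.append((de.table["pvalue"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_needs_replicates(self):
        with pytest.raises(ValueError):
            simple_de(make_expr(np.ones((3, 2)), n_rep=1), "trichome", "stem")


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_statsmodels_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(0, 1, 200)
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, atol=1e-15)

    def test_monotone_and_inflating(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDeFilter:
    def _table(self, contrast, rows):
        from epimark.core_io import DETable

        return DETable(
            contrast,
            pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue", "padj"]),
        )

    def test_both_contrasts_required_and_strict_boundary(self):
        stem = self._table(
            "t_vs_s",
            [("a", 5.0, 1e-6, 1e-5), ("b", 5.0, 1e-6, 1e-5), ("c", 2.0, 1e-6, 1e-5)],
        )
        leaf = self._table(
            "t_vs_l",
            [("a", 5.0, 1e-6, 1e-5), ("b", 0.5, 0.5, 0.9), ("c", 5.0, 1e-6, 1e-5)],
        )
        got = filter_tissue_specific_de(stem, leaf)
        assert got == {"a"}  # b fails vs leaf; c has log2fc exactly 2.0 (strict)


class TestOra:
    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        tm = TermMap({"T": {"g0", "g1"}})
        (res,) = ora_hypergeometric({"g10", "g11"}, tm, universe)
        assert res.p == pytest.approx(1.0)

    def test_exact_overlap_smallest_p(self):
        universe = {f"g{i}" for i in range(30)}
        term = {f"g{i}" for i in range(5)}
        tm = TermMap({"T": term})
        (res,) = ora_hypergeometric(term, tm, universe)
        assert res.k == res.K == res.n == 5
        assert res.p == pytest.approx(1.0 / hypergeom(30, 5, 5).pmf(5) ** -1)

    def test_pmf_summation_oracle(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3", "g10"}  # k = 4, n = 5
        (res,) = ora_hypergeometric(query, TermMap({"T": term}), universe)
        expected = hypergeom(20, 5, 5).pmf(4) + hypergeom(20, 5, 5).pmf(5)
        assert res.p == pytest.approx(expected, abs=1e-12)
        assert res.padj >= res.p

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        universe = {f"g{i}" for i in range(100)}
        term = set(rng.choice(sorted(universe), 20, replace=False))
        query = set(rng.choice(sorted(universe), 30, replace=False))
        (before,) = ora_hypergeometric(query, TermMap({"T": term}), universe)
        relabel = {g: f"x{g}" for g in universe}
        (after,) = ora_hypergeometric(
            {relabel[g] for g in query},
            TermMap({"T": {relabel[g] for g in term}}),
            set(relabel.values()),
        )
        assert after.p == pytest.approx(before.p)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric({"g"}, TermMap({"T": {"g"}}), set())


class TestGsea:
    def test_top_block_hand_computation(self):
        # 10 genes, equal scores, gene set = top 3: running sum rises by 1/3
        # per hit then falls by 1/7 per miss; maximum = 1 after the hits
        ranked = [(f"g{i}", 1.0) for i in range(10)]
        es, nes, p = gsea_preranked(ranked, {"g0", "g1", "g2"}, n_perm=200, seed=0)
        assert es == pytest.approx(1.0)
        assert es <= 1.0 and 0 < p <= 1

    def test_reversal_negates_es(self):
        rng = np.random.default_rng(5)
        scores = np.sort(rng.normal(0, 1, 50))[::-1]
        ranked = [(f"g{i}", float(s)) for i, s in enumerate(scores)]
        gene_set = {f"g{i}" for i in range(5)}
        es_fwd, _, _ = gsea_preranked(ranked, gene_set, n_perm=100, seed=1)
        reversed_ranked = [(g, -s) for g, s in ranked]
        es_rev, _, _ = gsea_preranked(reversed_ranked, gene_set, n_perm=100, seed=1)
        assert np.sign(es_rev) == -np.sign(es_fwd)

    def test_uniformly_spread_set_not_significant(self):
        ranked = [(f"g{i}", float(200 - i)) for i in range(200)]
        spread = {f"g{i}" for i in range(0, 200, 10)}
        insignificant = 0
        for seed in range(10):
            es, _, p = gsea_preranked(ranked, spread, n_perm=500, seed=seed)
            assert abs(es) <= 1.0
            if p > 0.1:
                insignificant += 1
        assert insignificant >= 9

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValueError):
            gsea_preranked([("a", 1.0)], {"zzz"}, n_perm=10, seed=0)


class TestGenesetCorrelation:
    def test_duplicate_sample_correlates_perfectly(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0, 10, (40, 6))
        m[:, 1] = m[:, 0]
        expr = make_expr(m)
        mat, labels, n = geneset_expression_correlation([expr], set(expr.gene_ids[:20]))
        assert n == 20
        assert mat[0, 1] == pytest.approx(1.0)

    def test_definitional_oracle(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(9)
        expr = make_expr(rng.uniform(0, 10, (30, 6)))
        gene_set = set(expr.gene_ids)
        mat, _, _ = geneset_expression_correlation([expr], gene_set)
        genes = sorted(gene_set)
        sub = expr.tpm.loc[genes]
        for i, a in enumerate(expr.samples):
            for j, b in enumerate(expr.samples):
                assert mat[i, j] == pytest.approx(
                    spearmanr(sub[a], sub[b]).statistic, abs=1e-12
                )

    def test_program_separates_tissue_groups(self, bundle):
        de_ids = set(bundle.manifest.de_genes["gene_id"])
        mat, labels, _ = geneset_expression_correlation([bundle.expression], de_ids)
        lab_t = [i for i, l in enumerate(labels) if l.startswith("trichome")]
        lab_o = [i for i, l in enumerate(labels) if not l.startswith("trichome")]
        within = np.mean([mat[i, j] for i in lab_t for j in lab_t if i != j])
        between = np.mean([mat[i, j] for i in lab_t for j in lab_o])
        assert within > between

    def test_empty_intersection_rejected(self):
        expr = make_expr(np.ones((3, 6)))
        with pytest.raises(ValueError):
            geneset_expression_correlation([expr], {"nope"})
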