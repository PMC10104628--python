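import itertools
import math

import numpy as np
import pytest
from scipy import stats

from scad import ExpressionMatrix
from scad.interpret import (
    ContingencyTable2x2,
    biomarker_sets,
    fisher_exact,
    gene_set_auc_compare,
    integrated_gradients,
    mean_attribution,
    rank_genes_de,
    sensitive_fraction,
    single_gene_auc,
    tail_genes,
)


# ------------------------------------------------------------- oracles
class LogisticLinear:
    """σ(w·x): closed-form gradients for validating path attribution."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def predict_proba(self, X):
        return 1 / (1 + np.exp(-(np.atleast_2d(X) @ self.w)))

    def input_gradient(self, X):
        p = self.predict_proba(X)
        return (p * (1 - p))[:, None] * self.w[None, :]

    def closed_form_ig(self, x):
        """Exact path integral from 0: ΔF split proportionally to w_i x_i."""
        s = float(self.w @ x)
        delta = self.predict_proba(x[None, :])[0] - 0.5
        return (self.w * x) / s * delta


def fisher_two_sided_oracle(a, b, c, d):
    """Full hypergeometric enumeration, probability-mass convention."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf_obs = stats.hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = stats.hypergeom.pmf(k, n, c1, r1)
        if pk <= pmf_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def bh_oracle(pvals):
    """Benjamini-Hochberg by the textbook step-up formula."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        prev = min(prev, p[idx] * n / rank)
        adj[idx] = prev
    return adj


# ------------------------------------------------------ integrated grads
class TestIntegratedGradients:
    def test_logistic_linear_closed_form(self, rng):
        model = LogisticLinear(rng.normal(size=8))
        x = rng.normal(size=8)
        ig = integrated_gradients(model, x, steps=200)
        np.testing.assert_allclose(ig, model.closed_form_ig(x), atol=1e-3)
        delta = model.predict_proba(x[None])[0] - 0.5
        assert abs(ig.sum() - delta) < 1e-3

    def test_zero_attribution_at_baseline(self, trained_small):
        model, _ = trained_small
        x = np.zeros(model.config.n_genes)
        ig = integrated_gradients(model, x, baseline=x, steps=10)
        np.testing.assert_array_equal(ig, 0.0)

    def test_completeness_on_trained_model(self, trained_small, small_sim):
        model, _ = trained_small
        X = small_sim["target"].values[:5]
        ig = integrated_gradients(model, X, steps=50)
        delta = model.predict_proba(X) - model.predict_proba(np.zeros_like(X))
        assert np.all(np.abs(ig.sum(axis=1) - delta) < 1e-2)

    def test_refinement_reduces_completeness_gap(self, trained_small, small_sim):
        model, _ = trained_small
        x = small_sim["target"].values[0]
        delta = (model.predict_proba(x[None]) - model.predict_proba(
            np.zeros((1, len(x)))))[0]

        def gap(steps):
            ig = integrated_gradients(model, x, steps=steps, check_completeness=False)
            return abs(ig.sum() - delta)

        assert gap(400) <= gap(25) + 1e-9


class TestAttributionAggregation:
    def test_single_fold_single_cell_identity(self):
        a = np.array([[1.0, -2.0, 3.0]])
        np.testing.assert_array_equal(mean_attribution([a]), a[0])

    def test_fold_permutation_invariant(self, rng):
        folds = [rng.normal(size=(4, 6)) for _ in range(3)]
        np.testing.assert_allclose(
            mean_attribution(folds), mean_attribution(folds[::-1])
        )

    def test_equal_fold_sizes_match_flat_mean(self, rng):
        folds = [rng.normal(size=(5, 6)) for _ in range(4)]
        np.testing.assert_allclose(
            mean_attribution(folds), np.vstack(folds).mean(axis=0)
        )

    def test_tail_gene_counts(self, rng):
        attr = rng.permutation(100).astype(float)
        genes = [f"g{i}" for i in range(100)]
        tails = tail_genes(attr, genes, q=0.05)
        assert len(tails) == 10
        assert tail_genes(attr, genes, q=0.5) == set(genes)
        assert tails <= tail_genes(attr, genes, q=0.10)


# ------------------------------------------------- differential expression
def _expr_two_groups(rng, n_a=5, n_b=5, n_genes=6, sep_gene=0):
    X = rng.normal(size=(n_a + n_b, n_genes))
    X[:n_a, sep_gene] += 10.0  # complete separation in one gene
    ids = [f"c{i}" for i in range(n_a + n_b)]
    genes = [f"g{j}" for j in range(n_genes)]
    m = ExpressionMatrix(X, ids, genes, "zscored")
    return m, set(ids[:n_a]), set(ids[n_a:])


class TestRankGenesDE:
    def test_separated_gene_has_positive_direction_and_minimal_p(self, rng):
        m, ga, gb = _expr_two_groups(rng)
        table = rank_genes_de(m, ga, gb)
        row = table[table["gene_id"] == "g0"].iloc[0]
        assert row["direction"] == 1.0
        assert row["pval"] == table["pval"].min()
        # exact enumeration: complete separation of 5 vs 5 has two-sided
        # probability 2 / C(10,5) under the rank-sum null
        assert 2 / math.comb(10, 5) < 0.01
        assert row["pval"] < 0.01

    def test_identical_groups_not_significant(self, rng):
        X = np.tile(rng.normal(size=(1, 5)), (8, 1)) + rng.normal(0, 1e-6, (8, 5))
        m = ExpressionMatrix(X, [f"c{i}" for i in range(8)],
                             [f"g{j}" for j in range(5)], "zscored")
        table = rank_genes_de(m, {"c0", "c1", "c2", "c3"}, {"c4", "c5", "c6", "c7"})
        assert np.all(table["pval_adj"] >= table["pval"] - 1e-12)

    def test_constant_gene_flagged_p_one(self, rng):
        m, ga, gb = _expr_two_groups(rng)
        m.values[:, 2] = 7.0
        table = rank_genes_de(m, ga, gb)
        row = table[table["gene_id"] == "g2"].iloc[0]
        assert row["constant"] and row["pval"] == 1.0

    def test_bh_adjustment_matches_stepup_oracle(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.02, 0.03, 0.5]
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], bh_oracle(p)
        )

    def test_overlapping_groups_rejected(self, rng):
        m, ga, gb = _expr_two_groups(rng)
        with pytest.raises(ValueError, match="overlap"):
            rank_genes_de(m, ga, ga)


class TestBiomarkerSets:
    def test_empty_table(self):
        import pandas as pd

        assert biomarker_sets(pd.DataFrame()) == (set(), set())

    def test_direction_partition_exclusive(self, rng):
        m, ga, gb = _expr_two_groups(rng, sep_gene=1)
        m.values[list(range(5)), 2] -= 10.0  # gene up in group b
        table = rank_genes_de(m, ga, gb)
        sens, res = biomarker_sets(table, alpha=0.05)
        assert not sens & res
        assert "g1" in sens and "g2" in res

    def test_alpha_one_partitions_all_tested(self, rng):
        m, ga, gb = _expr_two_groups(rng)
        table = rank_genes_de(m, ga, gb)
        sens, res = biomarker_sets(table, alpha=1.0)
        nonzero = set(table.loc[table["direction"] != 0, "gene_id"])
        assert sens | res == nonzero


class TestSingleGeneAUC:
    def test_perfect_and_anticorrelated(self, rng):
        X = rng.normal(size=(20, 3))
        outcome = np.array([0] * 10 + [1] * 10)
        X[:, 0] = outcome * 5 + rng.normal(0, 0.1, 20)
        X[:, 1] = -X[:, 0]
        m = ExpressionMatrix(X, [f"p{i}" for i in range(20)], ["a", "b", "c"],
                             "log_normalized")
        table = single_gene_auc(m, outcome, {"a", "b", "c"}).set_index("gene_id")
        assert table.loc["a", "auc"] == 1.0 and table.loc["a", "direction"] == 1
        assert table.loc["b", "auc"] == 1.0 and table.loc["b", "direction"] == -1

    def test_null_gene_near_half_monte_carlo(self, rng):
        n = 2000
        outcome = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 1))
        m = ExpressionMatrix(X, [f"p{i}" for i in range(n)], ["g"], "log_normalized")
        table = single_gene_auc(m, outcome, {"g"})
        assert abs(table["raw_auc"].iloc[0] - 0.5) < 0.05


class TestGeneSetAUCCompare:
    def test_identical_vectors_non_significant(self):
        v = np.array([0.5, 0.6, 0.7, 0.8])
        ma, mb, p = gene_set_auc_compare(v, v)
        assert ma == mb and p > 0.9

    def test_disjoint_ranges_minimal_exact_p(self):
        a = np.array([0.9, 0.92, 0.94, 0.96])
        b = np.array([0.5, 0.52, 0.54, 0.56])
        ma, mb, p = gene_set_auc_compare(a, b)
        # enumeration oracle: of C(8,4) equally likely rank assignments only
        # one in each direction is this extreme
        exact = 0
        ranks = range(8)
        for combo in itertools.combinations(ranks, 4):
            u = sum(combo) - 6  # sum of 0..3
            if u in (0, 16):  # both one-sided extremes
                exact += 1
        expected_p = exact / math.comb(8, 4)
        np.testing.assert_allclose(p, expected_p)
        assert ma > mb

    def test_symmetric(self, rng):
        a, b = rng.random(6), rng.random(9)
        ma, mb, p1 = gene_set_auc_compare(a, b)
        mb2, ma2, p2 = gene_set_auc_compare(b, a)
        assert (ma, mb) == (ma2, mb2)
        np.testing.assert_allclose(p1, p2)


class TestFisherExact:
    def test_vorinostat_lineage_table(self):
        t = ContingencyTable2x2(19, 661, 41, 113)
        odds, p = fisher_exact(t)
        assert p < 1e-5
        np.testing.assert_allclose(odds, (19 * 113) / (661 * 41))

    def test_sorafenib_lineage_table(self):
        _, p = fisher_exact(ContingencyTable2x2(10, 241, 21, 121))
        assert p == pytest.approx(3e-4, abs=2e-4)

    def test_balanced_table_null(self):
        odds, p = fisher_exact(ContingencyTable2x2(5, 5, 5, 5))
        assert odds == 1.0 and p == 1.0

    def test_agrees_with_enumeration_oracle_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            np.testing.assert_allclose(
                p, fisher_two_sided_oracle(int(a), int(b), int(c), int(d)),
                rtol=1e-8, atol=1e-12,
            )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestSensitiveFraction:
    @pytest.mark.parametrize(
        "table,row,expected",
        [
            ((19, 661, 41, 113), "solid", 2.79),
            ((19, 661, 41, 113), "hematopoietic", 26.62),
            ((10, 241, 21, 121), "solid", 3.98),
            ((10, 241, 21, 121), "hematopoietic", 14.79),
            ((0, 7, 1, 1), "solid", 0.0),
        ],
    )
    def test_printed_lineage_percentages(self, table, row, expected):
        t = ContingencyTable2x2(*table)
        assert round(sensitive_fraction(t, row), 2) == expected
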