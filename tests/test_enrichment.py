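import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_gsea_es, brute_ssgsea
from degsig import (GeneSet, GeneSetCollection, gsea_two_class, ssgsea_matrix,
                    ssgsea_sample, znormalize)
from degsig._utils import DegsigError
from degsig.enrichment import signal_to_noise
from degsig.io import ExpressionMatrix


def _sets(*member_lists):
    return GeneSetCollection([
        GeneSet(f"SET{i}", "", frozenset(m)) for i, m in enumerate(member_lists)
    ])


class TestSsgseaSample:
    def test_worked_four_gene_example(self):
        """A>B>C>D with set {A}, alpha=1: running diffs 1, 2/3, 1/3, 0."""
        col = pd.Series([4.0, 3.0, 2.0, 1.0], index=["A", "B", "C", "D"])
        es = ssgsea_sample(col, _sets({"A"}), alpha=1.0)
        assert es["SET0"] == pytest.approx(2.0)

    def test_top_block_is_maximal(self):
        rng = np.random.default_rng(2)
        col = pd.Series(rng.standard_normal(10), index=[f"g{i}" for i in range(10)])
        top3 = set(col.sort_values(ascending=False).index[:3])
        es_top = ssgsea_sample(col, _sets(top3), alpha=0.75)["SET0"]
        for other in itertools.combinations(col.index, 3):
            es = ssgsea_sample(col, _sets(set(other)), alpha=0.75)["SET0"]
            assert es <= es_top + 1e-12

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            G = int(rng.integers(5, 30))
            genes = [f"g{i}" for i in range(G)]
            col = pd.Series(rng.standard_normal(G), index=genes)
            m = int(rng.integers(1, G))
            members = set(rng.choice(genes, size=m, replace=False))
            alpha = float(rng.choice([0.0, 0.75, 1.0, 2.0]))
            es = ssgsea_sample(col, _sets(members), alpha=alpha)["SET0"]
            assert es == pytest.approx(brute_ssgsea(col.tolist(), genes, members, alpha), abs=1e-10)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(12)]
        col = pd.Series(rng.standard_normal(12), index=genes)
        sets = _sets({"g1", "g5", "g9"})
        es1 = ssgsea_sample(col, sets, alpha=0.75)["SET0"]
        es2 = ssgsea_sample(np.exp(col) * 3 + 1, sets, alpha=0.75)["SET0"]
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_es_bounded_by_gene_count(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(20)]
        col = pd.Series(rng.standard_normal(20), index=genes)
        es = ssgsea_sample(col, _sets({"g0", "g1"}), alpha=1.0)["SET0"]
        assert abs(es) <= 20

    def test_zero_overlap_errors(self):
        col = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(DegsigError, match="no overlap"):
            ssgsea_sample(col, _sets({"ZZZ"}), alpha=1.0)

    def test_whole_universe_errors(self):
        col = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(DegsigError, match="whole"):
            ssgsea_sample(col, _sets({"A", "B"}), alpha=1.0)


class TestZnormalize:
    def test_worked_example(self):
        np.testing.assert_allclose(znormalize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_constant_row_zeros(self):
        np.testing.assert_array_equal(znormalize([5.0, 5.0, 5.0]), np.zeros(3))

    def test_moments(self):
        rng = np.random.default_rng(6)
        z = znormalize(rng.standard_normal(40) * 3 + 7)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestSsgseaMatrix:
    def _expr(self, X, genes, samples):
        return ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))

    def test_identical_samples_give_zero_z(self):
        genes = [f"g{i}" for i in range(6)]
        col = np.arange(6, dtype=float)
        expr = self._expr(np.column_stack([col, col]), genes, ["A", "B"])
        enr = ssgsea_matrix(expr, _sets({"g4", "g5"}), alpha=1.0)
        assert enr.es.loc["SET0", "A"] == enr.es.loc["SET0", "B"]
        np.testing.assert_array_equal(enr.z.loc["SET0"], [0.0, 0.0])

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(8)]
        samples = [f"s{i}" for i in range(5)]
        X = rng.standard_normal((8, 5))
        expr = self._expr(X, genes, samples)
        perm = ["s3", "s0", "s4", "s1", "s2"]
        enr1 = ssgsea_matrix(expr, _sets({"g0", "g3"}), alpha=0.75)
        enr2 = ssgsea_matrix(expr.subset_samples(perm), _sets({"g0", "g3"}), alpha=0.75)
        np.testing.assert_allclose(enr1.es[perm], enr2.es, atol=1e-12)

    def test_planted_signature_recovery(self, base_cohort):
        """z-score of a planted signature tracks its latent activity."""
        enr = ssgsea_matrix(base_cohort.expression, base_cohort.true_signatures)
        h = base_cohort.truth.activities.loc["POS_SIG"]
        r = np.corrcoef(enr.z.loc["POS_SIG"], h)[0, 1]
        assert r > 0.6


class TestGseaTwoClass:
    def _make(self, G=60, n=24, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(G)]
        samples = [f"s{i}" for i in range(n)]
        X = rng.standard_normal((G, n))
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        return ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples)), labels, genes

    def test_top_ranked_set_has_positive_es(self):
        expr, labels, genes = self._make(seed=1)
        metric = signal_to_noise(expr.values, labels)
        top = set(np.array(genes)[np.argsort(-metric)][:8])
        res = gsea_two_class(expr, labels, _sets(top), n_perm=100, seed=0)
        assert res.table.loc["SET0", "ES"] > 0

    def test_es_matches_brute_force_running_sum(self):
        rng = np.random.default_rng(9)
        for seed in range(8):
            expr, labels, genes = self._make(G=30, n=16, seed=seed)
            m = int(rng.integers(3, 10))
            members = set(rng.choice(genes, size=m, replace=False))
            res = gsea_two_class(expr, labels, _sets(members), n_perm=100, seed=0)
            metric = signal_to_noise(expr.values, labels)
            assert res.table.loc["SET0", "ES"] == pytest.approx(
                brute_gsea_es(metric.tolist(), genes, members), abs=1e-10)

    def test_label_swap_negates_es(self):
        expr, labels, genes = self._make(seed=3)
        members = {genes[i] for i in (2, 7, 11, 20)}
        r1 = gsea_two_class(expr, labels, _sets(members), n_perm=100, seed=0)
        r2 = gsea_two_class(expr, 1 - labels, _sets(members), n_perm=100, seed=0)
        assert r1.table.loc["SET0", "ES"] == pytest.approx(-r2.table.loc["SET0", "ES"], abs=1e-10)

    def test_small_class_defaults_to_gene_set_mode(self):
        expr, _, genes = self._make(G=30, n=10, seed=4)
        labels = np.array([1] * 5 + [0] * 5)
        res = gsea_two_class(expr, labels, _sets(set(genes[:5])), n_perm=100, seed=0)
        assert res.perm_mode == "gene_set"

    def test_tiny_class_phenotype_mode_errors(self):
        expr, _, genes = self._make(G=20, n=6, seed=5)
        labels = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(DegsigError, match=">= 3"):
            gsea_two_class(expr, labels, _sets(set(genes[:4])), n_perm=100,
                           perm_mode="phenotype", seed=0)
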