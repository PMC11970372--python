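import numpy as np
import pandas as pd
import pytest

from conftest import brute_pearson
from haplotax import coexpr, synthetic
from haplotax.io_formats import GenomeInterval


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestNormalize:
    def test_log2_fixpoints(self):
        m = _matrix([[0, 1, 3, 3, 3]])
        out = coexpr.normalize_expression(m, min_expressed_samples=3)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == 1.0  # log2(1 + 1)
        assert out.iloc[0, 2] == 2.0  # log2(3 + 1)

    def test_low_expression_gene_dropped(self):
        vals = np.zeros((2, 40))
        vals[0, :2] = 5.0   # expressed in 2 of 40 -> dropped at threshold 3
        vals[1, :10] = 5.0  # kept
        out = coexpr.normalize_expression(_matrix(vals))
        assert list(out.index) == ["g1"]

    def test_all_dropped_rejected(self):
        with pytest.raises(ValueError):
            coexpr.normalize_expression(_matrix(np.zeros((3, 10))))


class TestCorrelationMatrix:
    def test_self_correlation_one(self):
        m = _matrix([[1, 2, 3, 4], [2, 1, 5, 3]])
        corr = coexpr.correlation_matrix(m)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_anticorrelated(self):
        m = _matrix([[1, 2, 3, 4], [4, 3, 2, 1]])
        corr = coexpr.correlation_matrix(m)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(20, 10)))
        corr = coexpr.correlation_matrix(m).to_numpy()
        x = m.to_numpy()
        for i in range(20):
            for j in range(20):
                assert abs(corr[i, j] - brute_pearson(x[i], x[j])) < 1e-10

    def test_constant_gene_zeroed(self):
        m = _matrix([[1, 1, 1, 1], [1, 2, 3, 4]])
        corr = coexpr.correlation_matrix(m)
        assert corr.iloc[0, 1] == 0.0
        assert corr.iloc[0, 0] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            coexpr.correlation_matrix(_matrix([[1, 2], [3, 4]]))

    def test_spearman_option(self):
        m = _matrix([[1, 2, 3, 10_000], [1, 2, 3, 4]])
        corr = coexpr.correlation_matrix(m, method="spearman")
        assert corr.iloc[0, 1] == pytest.approx(1.0)  # monotone


class TestClustering:
    def _block_corr(self):
        genes = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        c = np.full((10, 10), 0.0)
        c[:5, :5] = 0.9
        c[5:, 5:] = 0.9
        np.fill_diagonal(c, 1.0)
        return pd.DataFrame(c, index=genes, columns=genes)

    def test_block_diagonal_recovered(self):
        corr = self._block_corr()
        asg = coexpr.cluster_modules(corr, 2)
        a_labels = set(asg[[f"a{i}" for i in range(5)]])
        b_labels = set(asg[[f"b{i}" for i in range(5)]])
        assert len(a_labels) == 1 and len(b_labels) == 1
        assert a_labels != b_labels

    def test_k_equals_n_singletons(self):
        corr = self._block_corr()
        asg = coexpr.cluster_modules(corr, 10)
        assert asg.nunique() == 10

    def test_deterministic_and_row_order_invariant(self):
        corr = self._block_corr()
        shuffled = corr.iloc[::-1, ::-1]
        a = coexpr.cluster_modules(corr, 2)
        b = coexpr.cluster_modules(shuffled, 2)
        assert a.equals(b)

    def test_k_out_of_range_rejected(self):
        corr = self._block_corr()
        with pytest.raises(ValueError):
            coexpr.cluster_modules(corr, 1)
        with pytest.raises(ValueError):
            coexpr.cluster_modules(corr, 11)


class TestModuleSelection:
    def test_planted_module_recovered(self):
        matrix, label_sets, module_genes = synthetic.simulate_expression(
            synthetic.ExprSpec(), seed=3
        )
        labels = coexpr.GeneSetLabels(**label_sets)
        module, corr, asg = coexpr.mine_candidates(matrix, labels)
        truth_family = set(module_genes) & labels.family
        assert truth_family <= set(module.candidates)
        assert module.n_known == len(labels.known_pathway)

    def test_single_cluster_selected(self):
        asg = pd.Series([1, 1, 1], index=["a", "b", "c"])
        labels = coexpr.GeneSetLabels({"a"}, {"b", "c"})
        module = coexpr.select_candidate_module(asg, labels)
        assert module.candidates == ["b", "c"]

    def test_tie_broken_by_family_known_correlation(self):
        genes = ["k1", "f1", "k2", "f2"]
        asg = pd.Series([1, 1, 2, 2], index=genes)
        corr = pd.DataFrame(
            np.eye(4), index=genes, columns=genes
        )
        corr.loc["k1", "f1"] = corr.loc["f1", "k1"] = 0.2
        corr.loc["k2", "f2"] = corr.loc["f2", "k2"] = 0.9
        labels = coexpr.GeneSetLabels({"k1", "k2"}, {"f1", "f2"})
        module = coexpr.select_candidate_module(asg, labels, corr)
        assert module.candidates == ["f2"]

    def test_no_known_gene_rejected(self):
        asg = pd.Series([1, 1], index=["a", "b"])
        labels = coexpr.GeneSetLabels({"zz"}, {"a"})
        with pytest.raises(ValueError):
            coexpr.select_candidate_module(asg, labels)


class TestShortlist:
    def _world(self):
        candidates = [f"g{i}" for i in range(9)]
        clade_of = {g: f"clade{i % 3 + 1}" for i, g in enumerate(candidates)}
        position_of = {
            g: (f"chr{i % 2 + 1}", 1_000_000 * i) for i, g in enumerate(candidates)
        }
        return candidates, clade_of, position_of

    def test_one_per_clade_at_n3(self):
        candidates, clade_of, position_of = self._world()
        picked = coexpr.shortlist_candidates(candidates, clade_of, position_of, 3)
        assert len(picked) == 3
        assert len({clade_of[g] for g in picked}) == 3

    def test_all_returned_at_full_target(self):
        candidates, clade_of, position_of = self._world()
        picked = coexpr.shortlist_candidates(candidates, clade_of, position_of, 9)
        assert sorted(picked) == sorted(candidates)

    def test_overshoot_warns_and_returns_all(self):
        candidates, clade_of, position_of = self._world()
        with pytest.warns(UserWarning):
            picked = coexpr.shortlist_candidates(
                candidates, clade_of, position_of, 50
            )
        assert sorted(picked) == sorted(candidates)

    def test_deterministic(self):
        candidates, clade_of, position_of = self._world()
        a = coexpr.shortlist_candidates(candidates, clade_of, position_of, 5)
        b = coexpr.shortlist_candidates(candidates, clade_of, position_of, 5)
        assert a == b

    def test_missing_metadata_rejected(self):
        candidates, clade_of, position_of = self._world()
        del clade_of["g0"]
        with pytest.raises(ValueError):
            coexpr.shortlist_candidates(candidates, clade_of, position_of, 3)


class TestClusterFraction:
    def test_54_of_64(self):
        region = GenomeInterval("chr9", 19_760_000, 27_160_000)
        positions = {
            f"cyp{i}": ("chr9", 20_000_000 + i * 1000) for i in range(54)
        }
        positions.update(
            {f"cypx{i}": ("chr2", 5_000_000 + i) for i in range(10)}
        )
        inside, total, pct = coexpr.gene_cluster_fraction(positions, region)
        assert (inside, total, pct) == (54, 64, 84)

    def test_none_inside(self):
        region = GenomeInterval("chr9", 0, 100)
        positions = {"a": ("chr1", 5)}
        assert coexpr.gene_cluster_fraction(positions, region) == (0, 1, 0)

    def test_all_inside(self):
        region = GenomeInterval("chr9", 0, 100)
        positions = {"a": ("chr9", 5), "b": ("chr9", 50)}
        assert coexpr.gene_cluster_fraction(positions, region) == (2, 2, 100)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            coexpr.gene_cluster_fraction({}, GenomeInterval("c", 0, 1))


def test_pipeline_invariant_to_gene_row_order():
    matrix, label_sets, module_genes = synthetic.simulate_expression(
        synthetic.ExprSpec(n_genes=120, k_known=6, m_family=20,
                           n_family_extra=20),
        seed=5,
    )
    labels = coexpr.GeneSetLabels(**label_sets)
    module_a, _, _ = coexpr.mine_candidates(matrix, labels, k=8)
    module_b, _, _ = coexpr.mine_candidates(matrix.iloc[::-1], labels, k=8)
    assert module_a.candidates == module_b.candidates
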