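import io
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from culicinet.beta_diversity import (
    pairwise_permanova,
    pcoa,
    permanova,
    unifrac,
)
from culicinet.io_formats import CountTable
from oracles import permanova_exact_p, permanova_f, random_binary_tree, unifrac_brute


def _tree(newick):
    return TreeNode.read(io.StringIO(newick))


def _table(rows, samples, taxa):
    return CountTable(pd.DataFrame(rows, index=samples, columns=taxa))


class TestUnifrac:
    def test_identical_samples_distance_zero(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        table = _table([[1, 2, 0, 3], [1, 2, 0, 3]], ["s1", "s2"], list("ABCD"))
        for weighted in (False, True):
            dm = unifrac(tree, table, weighted=weighted)
            assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_leaf_sets_on_star_tree_unweighted_one(self):
        tree = _tree("((A:1,B:1,C:1,D:1):0);")
        table = _table([[1, 1, 0, 0], [0, 0, 1, 1]], ["s1", "s2"], list("ABCD"))
        dm = unifrac(tree, table, weighted=False)
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_four_leaf_disjoint_pair(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        table = _table([[1, 0, 0, 0], [0, 0, 1, 0]], ["s1", "s2"], list("ABCD"))
        dm = unifrac(tree, table, weighted=False)
        assert dm["s1", "s2"] == pytest.approx(1.0)  # (1+1+1+1)/(1+1+1+1)

    def test_nested_leaf_sets_match_branch_enumeration(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        table = _table([[1, 1, 0, 0], [1, 0, 0, 0]], ["s1", "s2"], list("ABCD"))
        dm = unifrac(tree, table, weighted=False)
        oracle = unifrac_brute(tree, {"A": 1, "B": 1}, {"A": 1}, weighted=False)
        assert dm["s1", "s2"] == pytest.approx(oracle, abs=1e-12)

    def test_weighted_star_tree_equals_l1_of_proportions(self):
        tree = _tree("((A:1,B:1,C:1):0);")
        table = _table([[2, 2, 0], [0, 1, 3]], ["s1", "s2"], list("ABC"))
        dm = unifrac(tree, table, weighted=True)
        pa = np.array([0.5, 0.5, 0.0])
        pb = np.array([0.0, 0.25, 0.75])
        assert dm["s1", "s2"] == pytest.approx(np.abs(pa - pb).sum())

    def test_missing_taxon_error_lists_taxa(self):
        tree = _tree("((A:1,B:1):1,C:1);")
        table = _table([[1, 2], [3, 1]], ["s1", "s2"], ["A", "Zmissing"])
        with pytest.raises(KeyError, match="Zmissing"):
            unifrac(tree, table, weighted=False)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_random_trees_match_brute_force(self, weighted):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(3, 11))
            newick, names = random_binary_tree(rng, n)
            tree = _tree(newick)
            counts = rng.integers(0, 8, size=(2, n))
            counts[:, 0] += 1  # non-empty samples
            table = _table(counts, ["s1", "s2"], names)
            dm = unifrac(tree, table, weighted=weighted)
            oracle = unifrac_brute(
                tree,
                dict(zip(names, counts[0])),
                dict(zip(names, counts[1])),
                weighted=weighted,
            )
            assert dm["s1", "s2"] == pytest.approx(oracle, abs=1e-10)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(5)
        newick, names = random_binary_tree(rng, 8)
        tree = _tree(newick)
        counts = rng.integers(0, 10, size=(5, 8))
        counts[:, 0] += 1
        table = _table(counts, [f"s{i}" for i in range(5)], names)
        for weighted in (False, True):
            d = unifrac(tree, table, weighted=weighted).data
            np.testing.assert_allclose(d, d.T, atol=1e-12)
            for i, j, k in itertools.permutations(range(5), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-10


class TestPcoa:
    def test_collinear_points_single_positive_axis(self):
        d = squareform(pdist(np.array([[0.0], [1.0], [2.0]])))
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert res.coordinates.shape[1] == 1
        emb = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(emb, d, atol=1e-9)

    def test_equilateral_triangle_equal_leading_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)

    def test_embedding_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(12)]))
        emb = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(emb, d, atol=1e-9)
        assert res.proportion_explained.sum() <= 1.0 + 1e-12

    def test_matches_skbio_reference(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(23)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(8)])
        mine = pcoa(dm)
        ref = skbio_pcoa(dm)
        k = mine.coordinates.shape[1]
        np.testing.assert_allclose(
            np.abs(mine.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :k]),
            atol=1e-8,
        )


class TestPermanova:
    def _clustered_dm(self, rng, sep, n_per=4):
        pts = np.vstack([
            rng.normal(0, 1, size=(n_per, 2)),
            rng.normal(sep, 1, size=(n_per, 2)),
        ])
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(2 * n_per)]
        return DistanceMatrix(d, ids=ids), ["a"] * n_per + ["b"] * n_per

    def test_pseudo_f_matches_longhand_and_skbio(self):
        rng = np.random.default_rng(31)
        dm, groups = self._clustered_dm(rng, sep=2.0)
        res = permanova(dm, groups, n_perm=99, seed=0)
        codes = [0] * 4 + [1] * 4
        assert res.pseudo_f == pytest.approx(
            permanova_f(dm.data, codes, 2), abs=1e-10
        )
        from skbio.stats.distance import permanova as skbio_permanova

        ref = skbio_permanova(dm, groups, permutations=99)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-8)

    def test_null_p_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        dm, groups = self._clustered_dm(rng, sep=0.0)
        p_exact = permanova_exact_p(dm.data, [0] * 4 + [1] * 4, 2)
        res = permanova(dm, groups, n_perm=999, seed=1)
        assert p_exact > 0.05
        assert abs(res.p - p_exact) < 0.08  # Monte-Carlo tolerance

    def test_separated_clusters_reach_minimum_p(self):
        rng = np.random.default_rng(13)
        dm, groups = self._clustered_dm(rng, sep=50.0, n_per=8)
        res = permanova(dm, groups, n_perm=199, seed=2)
        assert res.p == pytest.approx(1 / 200)

    def test_p_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(19)
        dm, groups = self._clustered_dm(rng, sep=1.0)
        renamed = ["x" if g == "a" else "y" for g in groups]
        a = permanova(dm, groups, n_perm=199, seed=3)
        b = permanova(dm, renamed, n_perm=199, seed=3)
        assert a.p == b.p and a.pseudo_f == pytest.approx(b.pseudo_f)

    def test_group_of_one_is_error(self):
        rng = np.random.default_rng(2)
        dm, _ = self._clustered_dm(rng, sep=1.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["a"] * 7 + ["b"], n_perm=9, seed=0)

    def test_pairwise_runs_each_pair_with_bonferroni(self):
        rng = np.random.default_rng(41)
        pts = np.vstack([rng.normal(i * 10, 1, size=(4, 2)) for i in range(3)])
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(12)])
        groups = np.repeat(["a", "b", "c"], 4)
        results = pairwise_permanova(dm, groups, n_perm=99, seed=5)
        assert {r.groups for r in results} == {("a", "b"), ("a", "c"), ("b", "c")}
        for r in results:
            assert r.n_samples == 8
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 3))
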