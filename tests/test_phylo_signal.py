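"""Blomberg's K, distance matrices and Mantel tests against independent oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import thermotrait as tt
from thermotrait.phylo_signal import (blomberg_k, k_permutation_test, mantel,
                                      patristic_distances,
                                      trait_distance_matrix, vcv_from_tree)

# picante::Kcalc on ((A:1,B:1):1,C:2) with x=(1,2,4) -- frozen external oracle
PICANTE_K_3TIP = 1.234375


class TestVcv:
    def test_star_tree_is_diagonal(self, star_tree):
        V = vcv_from_tree(star_tree)
        assert np.allclose(V.to_numpy(), 2.0 * np.eye(5))

    def test_three_tip_by_inspection(self, three_tip_tree):
        V = vcv_from_tree(three_tip_tree)
        assert np.allclose(np.diag(V), [2.0, 2.0, 2.0])
        assert V.loc["A", "B"] == pytest.approx(1.0)
        assert V.loc["A", "C"] == 0.0

    def test_matches_mrca_path_sum_oracle(self):
        """Brute-force oracle: walk each leaf's ancestor chain, intersect paths."""
        tree = tt.simulate_tree(10, 1.0, seed=17)
        V = vcv_from_tree(tree)

        chains = {}
        for leaf in tree.leaf_node_iter():
            chain, node = [], leaf
            while node is not None:
                chain.append(node)
                node = node.parent_node
            chains[leaf.taxon.label] = chain

        def shared_depth(a, b):
            mrca = next(n for n in chains[a] if n in chains[b])
            d, node = 0.0, mrca
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            return d

        for a in V.index:
            for b in V.index:
                if a != b:
                    assert V.loc[a, b] == pytest.approx(shared_depth(a, b), abs=1e-12)

    def test_zero_depth_tree_rejected(self):
        from conftest import newick_tree
        with pytest.raises(ValueError, match="depth"):
            vcv_from_tree(newick_tree("(A:0,B:0,C:0);"))


class TestPatristic:
    def test_three_tip_path_sums(self, three_tip_tree):
        D = patristic_distances(three_tip_tree)
        assert D.loc["A", "B"] == pytest.approx(2.0)
        assert D.loc["A", "C"] == pytest.approx(4.0)
        assert D.loc["B", "C"] == pytest.approx(4.0)
        assert np.all(np.diag(D) == 0.0)

    def test_matches_dendropy_distance_matrix(self):
        tree = tt.simulate_tree(8, 1.0, seed=23)
        D = patristic_distances(tree)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for a in D.index:
            for b in D.columns:
                assert D.loc[a, b] == pytest.approx(
                    pdm.patristic_distance(taxa[a], taxa[b]), abs=1e-9)


class TestBlombergK:
    def test_star_tree_k_is_one_for_any_trait(self, star_tree):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = pd.Series(rng.normal(size=5), index=list("ABCDE"))
            assert blomberg_k(star_tree, x).k == pytest.approx(1.0, abs=1e-10)

    def test_three_tip_matches_hand_inverted_algebra(self, three_tip_tree):
        """Explicit 3x3 inversion oracle, plus the frozen picante value."""
        V = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        x = np.array([1.0, 2.0, 4.0])
        Vinv = np.linalg.inv(V)
        one = np.ones(3)
        a = (one @ Vinv @ x) / (one @ Vinv @ one)
        r = x - a
        expected = ((r @ r) / (r @ Vinv @ r)) / (
            (np.trace(V) - 3 / (one @ Vinv @ one)) / 2)
        res = blomberg_k(three_tip_tree, pd.Series(x, index=list("ABC")))
        assert res.k == pytest.approx(expected, abs=1e-10)
        assert res.k == pytest.approx(PICANTE_K_3TIP, abs=1e-9)

    def test_bm_expectation_near_one(self, yule16):
        ks = [blomberg_k(yule16, tt.simulate_bm_traits(yule16, 1.0, seed=s)).k
              for s in range(1000)]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_affine_invariance(self, yule16):
        x = tt.simulate_bm_traits(yule16, 1.0, seed=3)
        k0 = blomberg_k(yule16, x).k
        assert blomberg_k(yule16, 7.5 * x - 3.0).k == pytest.approx(k0, abs=1e-10)

    def test_branch_rescaling_invariance(self, yule16):
        x = tt.simulate_bm_traits(yule16, 1.0, seed=4)
        k0 = blomberg_k(yule16, x).k
        scaled = yule16.clone(depth=1)
        for edge in scaled.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 13.7
        assert blomberg_k(scaled, x).k == pytest.approx(k0, abs=1e-10)

    def test_missing_tips_pruned(self, yule16):
        x = tt.simulate_bm_traits(yule16, 1.0, seed=5)
        x.iloc[0] = np.nan
        res = blomberg_k(yule16, x)
        assert res.n_tips_used == 15

    def test_constant_trait_rejected(self, yule16):
        labels = [l.taxon.label for l in yule16.leaf_node_iter()]
        with pytest.raises(ValueError, match="zero variance"):
            blomberg_k(yule16, pd.Series(1.0, index=labels))


class TestKPermutation:
    def test_seed_reproducibility(self, yule16):
        x = tt.simulate_bm_traits(yule16, 1.0, seed=8)
        p1 = k_permutation_test(yule16, x, 999, seed=99).p
        p2 = k_permutation_test(yule16, x, 999, seed=99).p
        assert p1 == p2
        assert p1 > 0.0  # add-one rule

    def test_type_one_error_calibrated(self, imbalanced_tree):
        labels = [l.taxon.label for l in imbalanced_tree.leaf_node_iter()]
        rej = sum(
            k_permutation_test(imbalanced_tree,
                               tt.simulate_white_noise_traits(labels, 0, 1, seed=s),
                               999, seed=s).p <= 0.05
            for s in range(500))
        assert 0.02 <= rej / 500 <= 0.08

    def test_power_on_bm_traits(self, yule16):
        """BM traits on the birth-death tree model the generator itself uses."""
        rej = sum(
            k_permutation_test(yule16,
                               tt.simulate_bm_traits(yule16, 1.0, seed=s),
                               999, seed=s).p <= 0.05
            for s in range(500))
        assert rej / 500 >= 0.8

    def test_rejects_zero_permutations(self, yule16):
        x = tt.simulate_bm_traits(yule16, 1.0, seed=1)
        with pytest.raises(ValueError):
            k_permutation_test(yule16, x, n_perm=0, seed=1)


class TestTraitDistance:
    def test_three_four_five(self):
        table = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        assert trait_distance_matrix(table).loc["a", "b"] == pytest.approx(5.0)

    def test_identical_profiles_distance_zero(self):
        table = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]],
                             index=["a", "b", "c"])
        assert trait_distance_matrix(table).loc["a", "b"] == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.normal(size=(6, 4)),
                             index=[f"i{k}" for k in range(6)])
        D = trait_distance_matrix(table)
        for a in table.index:
            for b in table.index:
                expected = np.sqrt(sum((table.loc[a, c] - table.loc[b, c]) ** 2
                                       for c in table.columns))
                assert D.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_all_missing_row_dropped_with_warning(self):
        table = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan], [0.0, 1.0]],
                             index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="all-missing"):
            D = trait_distance_matrix(table)
        assert list(D.index) == ["a", "c"]

    def test_pairwise_deletion_uses_shared_columns(self):
        table = pd.DataFrame([[0.0, 0.0, 5.0], [3.0, 4.0, np.nan]],
                             index=["a", "b"])
        assert trait_distance_matrix(table).loc["a", "b"] == pytest.approx(5.0)


class TestMantel:
    @staticmethod
    def _random_dist(rng, n, labels=None):
        M = rng.random((n, n))
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 0.0)
        labels = labels or [f"l{i}" for i in range(n)]
        return pd.DataFrame(M, index=labels, columns=labels)

    def test_self_correlation_is_one(self):
        D = self._random_dist(np.random.default_rng(1), 6)
        res = mantel(D, D.copy(), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_enumeration_n4(self):
        """Exhaustive p at n=4 equals the exact fraction over all 24 relabelings."""
        rng = np.random.default_rng(5)
        A = self._random_dist(rng, 4)
        B = self._random_dist(rng, 4, labels=list(A.index))
        tri = np.tril_indices(4, -1)
        a = A.to_numpy()[tri]
        observed = np.corrcoef(a, B.to_numpy()[tri])[0, 1]
        exact = np.mean([
            np.corrcoef(a, B.to_numpy()[np.ix_(p, p)][tri])[0, 1] >= observed
            for p in map(list, permutations(range(4)))])
        res = mantel(A, B, exhaustive=True)
        assert res.p == pytest.approx(exact, abs=1e-12)
        assert res.n_perm == 24

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as sk_mantel
        rng = np.random.default_rng(9)
        A = self._random_dist(rng, 10)
        B = self._random_dist(rng, 10, labels=list(A.index))
        ours = mantel(A, B, n_perm=9, seed=0)
        r, _, _ = sk_mantel(DistanceMatrix(A.to_numpy(), list(A.index)),
                            DistanceMatrix(B.to_numpy(), list(B.index)),
                            permutations=0, alternative="greater")
        assert ours.r == pytest.approx(float(r), abs=1e-12)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(11)
        rs = [mantel(self._random_dist(rng, 20), self._random_dist(rng, 20),
                     n_perm=1, seed=i).r for i in range(500)]
        assert abs(np.mean(rs)) <= 0.05

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        A = self._random_dist(rng, 7)
        B = self._random_dist(rng, 7, labels=list(A.index))
        r0 = mantel(A, B, n_perm=9, seed=1).r
        perm = rng.permutation(7)
        newlab = [A.index[i] for i in perm]
        A2 = pd.DataFrame(A.to_numpy()[np.ix_(perm, perm)], index=newlab, columns=newlab)
        B2 = pd.DataFrame(B.to_numpy()[np.ix_(perm, perm)], index=newlab, columns=newlab)
        assert mantel(A2, B2, n_perm=9, seed=1).r == pytest.approx(r0, abs=1e-12)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        A = self._random_dist(rng, 5)
        B = self._random_dist(rng, 5, labels=list("vwxyz"))
        with pytest.raises(ValueError, match="label"):
            mantel(A, B, n_perm=9, seed=0)

    def test_seeded_p_reproducible_and_positive(self):
        rng = np.random.default_rng(21)
        A = self._random_dist(rng, 8)
        B = self._random_dist(rng, 8, labels=list(A.index))
        p1 = mantel(A, B, n_perm=99, seed=5).p
        p2 = mantel(A, B, n_perm=99, seed=5).p
        assert p1 == p2 > 0.0
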