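"""Jaccard similarity, UPGMA, cophenetic correlation, PCA and PCoA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average as scipy_average
from scipy.cluster.hierarchy import cophenet as scipy_cophenet
from scipy.spatial.distance import pdist, squareform

import indelpop as ip
from indelpop.io import BandMatrix, ComputationError, ValidationError

import skbio

from test_popgen import random_band_matrix


def dm(matrix, ids=None) -> ip.DistanceMatrix:
    matrix = np.asarray(matrix, dtype=float)
    ids = ids or [chr(ord("A") + i) for i in range(matrix.shape[0])]
    return ip.DistanceMatrix(ids=list(ids), data=matrix, metric="test")


class TestJaccard:
    def test_identical_disjoint_and_partial(self):
        values = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 1]], np.int8)
        bm = BandMatrix([f"s{i}" for i in range(4)], ["a", "b", "c"],
                        values, np.zeros((4, 3), bool), ["m"] * 3)
        sim = ip.jaccard_similarity(bm)
        assert sim.iloc[0, 1] == 1.0
        assert sim.iloc[0, 2] == 0.0
        assert sim.iloc[0, 3] == pytest.approx(1 / 3)

    def test_masked_columns_excluded(self):
        values = np.array([[1, 1], [1, 0]], np.int8)
        mask = np.array([[False, True], [False, False]])
        bm = BandMatrix(["a", "b"], ["x", "y"], values, mask, ["m1", "m2"])
        assert ip.jaccard_similarity(bm).iloc[0, 1] == 1.0

    def test_empty_union_is_an_error(self):
        values = np.zeros((2, 2), np.int8)
        bm = BandMatrix(["a", "b"], ["x", "y"], values,
                        np.zeros((2, 2), bool), ["m1", "m2"])
        with pytest.raises(ComputationError, match="union"):
            ip.jaccard_similarity(bm)

    def test_distance_satisfies_triangle_inequality(self, rng):
        bm = random_band_matrix(rng, 8, 20)
        bm.values[:, 0] = 1  # avoid empty unions
        d = ip.jaccard_distance(bm).data
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestUpgma:
    def test_two_leaves_merge_at_half_distance(self):
        tree = ip.upgma(dm([[0, 0.4], [0.4, 0]]))
        assert tree.height == pytest.approx(0.2)
        assert tree.cophenetic_matrix().loc["A", "B"] == pytest.approx(0.4)

    def test_three_leaf_hand_computation(self):
        d = dm([[0, 2, 8], [2, 0, 8], [8, 8, 0]])
        tree = ip.upgma(d)
        assert tree.merges[0][2] == pytest.approx(1.0)  # (A,B) at height 1
        assert tree.merges[1][2] == pytest.approx(4.0)  # C joins at height 4
        coph = tree.cophenetic_matrix()
        assert coph.loc["A", "B"] == pytest.approx(2.0)
        assert coph.loc["A", "C"] == pytest.approx(8.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_average_linkage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        condensed = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
        d = dm(squareform(condensed))
        tree = ip.upgma(d)
        ours = squareform(tree.cophenetic_matrix().to_numpy(), checks=False)
        z = scipy_average(condensed)
        theirs = scipy_cophenet(z)
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_ultrametric_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        d = dm(squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)))
        tree = ip.upgma(d)
        heights = [m[2] for m in tree.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
        # every leaf pair's cophenetic distance obeys the ultrametric
        # three-point condition
        coph = tree.cophenetic_matrix().to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(n):
                    if k in (i, j):
                        continue
                    assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-12

    def test_newick_round_trip_preserves_cophenetic_distances(self):
        rng = np.random.default_rng(9)
        n = 6
        d = dm(squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)))
        tree = ip.upgma(d)
        newick = tree.to_newick()
        sk = skbio.TreeNode.read([newick])
        coph = tree.cophenetic_matrix()
        tip_dists = sk.tip_tip_distances()
        for a in d.ids:
            for b in d.ids:
                if a == b:
                    continue
                assert tip_dists[a, b] == pytest.approx(coph.loc[a, b], abs=1e-9)

    def test_tie_break_prefers_lowest_leaf_indices(self):
        # A-B and C-D tie at distance 2; A-B must merge first
        mat = np.full((4, 4), 8.0)
        np.fill_diagonal(mat, 0.0)
        mat[0, 1] = mat[1, 0] = 2.0
        mat[2, 3] = mat[3, 2] = 2.0
        tree = ip.upgma(dm(mat))
        assert tree.merges[0][0] == (0,) and tree.merges[0][1] == (1,)

    def test_cut_at_similarity_recovers_two_groups(self):
        values = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], np.int8
        )
        bm = BandMatrix([f"s{i}" for i in range(4)], list("abcd"),
                        values, np.zeros((4, 4), bool), ["m"] * 4)
        tree = ip.upgma(ip.jaccard_distance(bm))
        clusters = tree.cut_at_similarity(0.30)
        assert clusters.nunique() == 2
        assert clusters["s0"] == clusters["s1"]
        assert clusters["s2"] == clusters["s3"]
        assert clusters["s0"] != clusters["s2"]


class TestCophenetic:
    def test_ultrametric_input_gives_perfect_correlation(self):
        d = dm([[0, 2, 8], [2, 0, 8], [8, 8, 0]])
        tree = ip.upgma(d)
        assert ip.cophenetic_correlation(tree, d) == pytest.approx(1.0)

    def test_distorted_input_gives_less_than_one(self):
        # 4-leaf additive but non-ultrametric distances
        mat = np.array(
            [[0, 3, 9, 9], [3, 0, 9, 9], [9, 9, 0, 2], [9, 9, 2, 0]], float
        )
        mat[0, 2] = mat[2, 0] = 11.0  # break exchangeability
        tree = ip.upgma(dm(mat))
        r = ip.cophenetic_correlation(tree, dm(mat))
        assert r < 1.0

    def test_two_leaves_undefined(self):
        d = dm([[0, 1], [1, 0]])
        tree = ip.upgma(d)
        with pytest.raises(ComputationError):
            ip.cophenetic_correlation(tree, d)


class TestPca:
    def test_separated_clusters_on_disjoint_bands(self):
        values = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 0, 0],
             [0, 0, 1, 1], [0, 0, 1, 1], [0, 0, 1, 0]],
            np.int8,
        )
        bm = BandMatrix([f"s{i}" for i in range(6)], list("abcd"),
                        values, np.zeros((6, 4), bool), ["m"] * 4)
        res = ip.pca_band(bm)
        pc1 = res.scores["PC1"]
        assert res.percent_variance[0] == max(res.percent_variance)
        assert set(np.sign(pc1[:3])) != set(np.sign(pc1[3:]))

    def test_duplicate_samples_identical_scores(self, rng):
        bm = random_band_matrix(rng, 5, 8)
        bm.values[1] = bm.values[0]
        res = ip.pca_band(bm)
        np.testing.assert_allclose(
            res.scores.iloc[0], res.scores.iloc[1], atol=1e-9
        )

    def test_percent_variance_sums_to_100(self, rng):
        bm = random_band_matrix(rng, 7, 9)
        res = ip.pca_band(bm)
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_scores_invariant_to_sample_order_up_to_sign(self, rng):
        bm = random_band_matrix(rng, 6, 8)
        res1 = ip.pca_band(bm)
        perm = rng.permutation(6)
        bm2 = BandMatrix(
            [bm.sample_ids[i] for i in perm], bm.band_ids,
            bm.values[perm], bm.mask[perm], bm.band_marker,
        )
        res2 = ip.pca_band(bm2)
        s1 = res1.scores.loc[bm.sample_ids, "PC1"].to_numpy()
        s2 = res2.scores.loc[bm.sample_ids, "PC1"].to_numpy()
        assert np.allclose(s1, s2, atol=1e-9) or np.allclose(s1, -s2, atol=1e-9)


class TestPcoa:
    def _coords(self, rows):
        return pd.DataFrame(
            rows, columns=["latitude", "longitude", "altitude_m"],
            index=[f"s{i}" for i in range(len(rows))],
        )

    def test_collinear_sites_have_one_positive_eigenvalue(self):
        coords = self._coords([[20, 80, 100], [21, 81, 200], [22, 82, 300],
                               [23, 83, 400]])
        res = ip.pcoa_geographic(coords)
        assert (res.eigenvalues > 1e-9).sum() == 1

    def test_recovered_coordinates_reproduce_distances(self):
        rng = np.random.default_rng(4)
        coords = self._coords(rng.uniform(0, 10, size=(6, 3)))
        res = ip.pcoa_geographic(coords)
        z = coords.to_numpy()
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        expected = squareform(pdist(z))
        recovered = squareform(pdist(res.scores.to_numpy()))
        np.testing.assert_allclose(recovered, expected, atol=1e-8)

    def test_identical_sites_identical_scores(self):
        coords = self._coords([[20, 80, 100], [20, 80, 100], [25, 85, 300],
                               [22, 83, 250]])
        res = ip.pcoa_geographic(coords)
        np.testing.assert_allclose(
            res.scores.loc["s0"], res.scores.loc["s1"], atol=1e-9
        )

    def test_missing_coordinates_dropped_with_warning(self, caplog):
        coords = self._coords([[20, 80, 100], [21, 81, 200], [22, 82, 300],
                               [23, 83, 400]])
        coords.loc["s3", "altitude_m"] = np.nan
        res = ip.pcoa_geographic(coords)
        assert "s3" not in res.scores.index
        assert len(res.scores) == 3
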