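import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import skincorrect as sc

from conftest import random_distance_matrix


class TestPCoA:
    def test_collinear_points_single_axis(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.warns(UserWarning):
            result = sc.pcoa(d, n_axes=2)
        assert result.explained_fraction[0] == pytest.approx(1.0)

    def test_euclidean_distances_recovered(self):
        rng = np.random.default_rng(0)
        points = rng.standard_normal((9, 2))
        ids = [f"s{i}" for i in range(9)]
        d = pd.DataFrame(squareform(pdist(points)), index=ids, columns=ids)
        coords = sc.pcoa(d, n_axes=2).coordinates.to_numpy()
        recovered = squareform(pdist(coords))
        assert np.abs(recovered - d.to_numpy()).max() < 1e-9

    def test_procrustes_recovery_of_configuration(self):
        from scipy.spatial import procrustes

        rng = np.random.default_rng(1)
        points = rng.standard_normal((12, 2))
        ids = [f"s{i}" for i in range(12)]
        d = pd.DataFrame(squareform(pdist(points)), index=ids, columns=ids)
        coords = sc.pcoa(d, n_axes=2).coordinates.to_numpy()
        _, _, disparity = procrustes(points, coords)
        assert disparity < 1e-6

    def test_all_zero_matrix_degenerates_cleanly(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"),
                         columns=list("abcd"))
        with pytest.warns(UserWarning):
            result = sc.pcoa(d, n_axes=2)
        assert result.coordinates.shape[1] == 0
        assert result.explained_fraction.size == 0

    def test_coordinates_centred_and_fractions_bounded(self):
        d = random_distance_matrix(10, np.random.default_rng(5))
        result = sc.pcoa(d, n_axes=3)
        assert np.allclose(result.coordinates.mean(axis=0), 0, atol=1e-9)
        assert result.explained_fraction.sum() <= 1 + 1e-12
        assert (np.diff(result.eigenvalues) <= 1e-9).all()

    def test_matches_scikit_bio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        d = random_distance_matrix(8, np.random.default_rng(6))
        ours = sc.pcoa(d, n_axes=3)
        ref = skbio_pcoa(d.to_numpy(), number_of_dimensions=3)
        assert np.allclose(np.abs(ours.coordinates.to_numpy()),
                           np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-8)
        assert np.allclose(ours.explained_fraction,
                           ref.proportion_explained[:3], atol=1e-10)


class TestBiplot:
    def test_feature_in_one_sample_points_at_it(self):
        counts = pd.DataFrame(
            [[10, 1], [0, 1], [0, 1], [0, 1]],
            index=list("abcd"), columns=["solo", "everywhere"])
        d = pd.DataFrame(
            squareform(pdist(np.array([[0.], [1.], [2.], [3.]]))),
            index=list("abcd"), columns=list("abcd"))
        ordn = sc.pcoa(d, n_axes=1)
        arrows = sc.biplot(ordn, counts, k=2)
        solo_arrow = arrows.loc["solo", "PC1"]
        assert solo_arrow == pytest.approx(ordn.coordinates.loc["a", "PC1"],
                                           abs=1e-9)

    def test_uniform_feature_sits_at_origin(self):
        counts = pd.DataFrame(
            [[5, 3], [5, 1], [5, 7], [5, 2]],
            index=list("abcd"), columns=["flat", "other"])
        d = random_distance_matrix(4, np.random.default_rng(2))
        d.index = d.columns = list("abcd")
        ordn = sc.pcoa(d, n_axes=2)
        # "flat" has equal proportions only if row totals are equal; build so
        counts["other"] = 5
        arrows = sc.biplot(ordn, counts, k=2)
        assert np.allclose(arrows.loc["flat", ["PC1", "PC2"]], 0, atol=1e-9)

    def test_hand_computed_weighted_means(self):
        counts = pd.DataFrame(
            [[4, 0, 4], [0, 4, 4], [4, 4, 0], [4, 4, 8]],
            index=list("abcd"), columns=["f1", "f2", "f3"])
        d = pd.DataFrame(
            squareform(pdist(np.array([[0., 0], [1, 0], [0, 1], [1, 1]]))),
            index=list("abcd"), columns=list("abcd"))
        ordn = sc.pcoa(d, n_axes=2)
        coords = ordn.coordinates
        rel = counts.div(counts.sum(axis=1), axis=0)
        weights = rel / rel.sum(axis=0)
        expected = weights.T @ coords
        arrows = sc.biplot(ordn, counts, k=3)
        for f in ["f1", "f2", "f3"]:
            assert np.allclose(arrows.loc[f, ["PC1", "PC2"]],
                               expected.loc[f], atol=1e-12)

    def test_k_larger_than_feature_count_returns_all(self):
        counts = pd.DataFrame([[1, 2], [2, 1]], index=["a", "b"],
                              columns=["f1", "f2"])
        d = pd.DataFrame([[0, 1.], [1., 0]], index=["a", "b"],
                         columns=["a", "b"])
        ordn = sc.pcoa(d, n_axes=1)
        assert len(sc.biplot(ordn, counts, k=10)) == 2


class TestPermanova:
    def test_extreme_separation_minimal_p(self):
        # two blocks of identical samples, maximally distant between blocks;
        # 12+12 so a random permutation essentially never reproduces the
        # partition (probability ~7e-7) and the minimal attainable p is
        # reached
        n_half = 12
        d = np.ones((2 * n_half, 2 * n_half)) * 10
        d[:n_half, :n_half] = 0
        d[n_half:, n_half:] = 0
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(2 * n_half)]
        dm = pd.DataFrame(d, index=ids, columns=ids)
        f, p = sc.permanova(dm, ["a"] * n_half + ["b"] * n_half,
                            n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_two_plus_two_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        dm = random_distance_matrix(4, rng)
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        from skincorrect.ordination import _permanova_f

        d2 = dm.to_numpy() ** 2
        f_obs = _permanova_f(d2, labels, np.array(["a", "b"], dtype=object))
        # enumerate all 6 ways to choose which two samples form group "a"
        fs = []
        for pair in itertools.combinations(range(4), 2):
            lab = np.array(["b"] * 4, dtype=object)
            lab[list(pair)] = "a"
            fs.append(_permanova_f(d2, lab, np.array(["a", "b"], object)))
        exact_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        _, p = sc.permanova(dm, labels, n_perm=5999, seed=1)
        assert p == pytest.approx(exact_p, abs=0.02)

    def test_single_group_errors(self):
        dm = random_distance_matrix(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            sc.permanova(dm, ["a"] * 4)

    def test_statistic_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        dm = random_distance_matrix(12, np.random.default_rng(7))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        f, _ = sc.permanova(dm, groups, n_perm=9, seed=0)
        ref = skbio_permanova(DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
                              grouping=groups, permutations=9)
        assert f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_pairwise_two_groups_q_equals_p(self):
        dm = random_distance_matrix(8, np.random.default_rng(8))
        out = sc.pairwise_permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=99,
                                    seed=0)
        assert len(out) == 1
        assert out.loc[0, "q_value"] == pytest.approx(out.loc[0, "p_value"])


class TestKruskalWallisAndPearson:
    def test_hand_ranked_h(self):
        h, _ = sc.kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9],
                                 ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert h == pytest.approx(7.2)

    def test_identical_groups_h_zero(self):
        h, p = sc.kruskal_wallis([1, 1, 1, 1], ["a", "a", "b", "b"])
        assert h == 0.0 and p == 1.0

    def test_pairwise_bh_columns(self):
        out = sc.pairwise_kruskal_wallis(
            [1, 2, 3, 7, 8, 9, 4, 5, 6], ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert len(out) == 3
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_pearson_exact_linearity(self):
        x = np.arange(10, dtype=float)
        r, r2 = sc.pearson_r2(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_pearson_hand_value(self):
        r, r2 = sc.pearson_r2([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert r2 == pytest.approx(0.36)

    def test_pearson_missing_drops_pair(self):
        x = np.array([1, 2, 3, 4, np.nan])
        y = np.array([2, 1, 4, 3, 100.0])
        r, _ = sc.pearson_r2(x, y)
        assert r == pytest.approx(0.6)

    def test_pearson_null_is_small_at_large_n(self):
        rng = np.random.default_rng(9)
        r, _ = sc.pearson_r2(rng.standard_normal(10_000),
                             rng.standard_normal(10_000))
        assert abs(r) < 0.05

    def test_pearson_zero_variance_undefined(self):
        r, r2 = sc.pearson_r2([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(r2)
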