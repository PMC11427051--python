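"""Clustering algorithms against hand computations and scipy/sklearn oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans as SKKMeans
from sklearn.metrics import silhouette_samples as sk_silhouette_samples

from spikemodes import (
    AgglomerativeGower,
    GowerTransformer,
    MixedKMeans,
    PAMClustering,
    agglomerative_coefficient,
    cut_tree,
    dunn_index,
    encode_features,
    gower_matrix,
    hierarchical_cluster,
    kmeans,
    pam,
    silhouette,
    validation_scan,
)


def feature_frame(rows):
    return pd.DataFrame(rows, columns=["bursting", "rate_hz", "cv"])


def brute_gower(df):
    n = len(df)
    rngs = {c: df[c].max() - df[c].min() for c in ("rate_hz", "cv")}
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            parts = [float(df.bursting.iat[i] != df.bursting.iat[j])]
            for c in ("rate_hz", "cv"):
                parts.append(abs(df[c].iat[i] - df[c].iat[j]) / rngs[c] if rngs[c] else 0.0)
            out[i, j] = np.mean(parts)
    return out


def random_dissimilarity(rng, n):
    pts = rng.uniform(0, 1, size=(n, 2))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return d


class TestGower:
    def test_identical_vectors_have_zero_dissimilarity(self):
        df = feature_frame([(0, 2.0, 0.3), (0, 2.0, 0.3), (1, 4.0, 0.8)])
        d = gower_matrix(df)
        assert d[0, 1] == 0.0

    def test_bursting_flag_alone_contributes_one_third(self):
        df = feature_frame([(0, 2.0, 0.3), (1, 2.0, 0.3), (0, 4.0, 0.5)])
        d = gower_matrix(df)
        assert d[0, 1] == pytest.approx(1 / 3)

    def test_matches_brute_force(self):
        df = feature_frame([(0, 1.5, 0.2), (1, 3.0, 0.8), (0, 4.0, 0.5)])
        np.testing.assert_allclose(gower_matrix(df), brute_gower(df), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 12))
    def test_bounded_and_symmetric(self, seed, n):
        rng = np.random.default_rng(seed)
        df = feature_frame(
            [(int(rng.integers(2)), rng.uniform(0.5, 6), rng.uniform(0.05, 1.1)) for _ in range(n)]
        )
        d = gower_matrix(df)
        assert np.all(d >= 0) and np.all(d <= 1 + 1e-12)
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.all(np.diag(d) == 0)

    def test_zero_range_variable_warns_and_contributes_zero(self):
        df = feature_frame([(0, 2.0, 0.3), (1, 2.0, 0.5)])
        with pytest.warns(UserWarning, match="zero range"):
            d = gower_matrix(df)
        assert d[0, 1] == pytest.approx((1 + 0 + 1) / 3)

    def test_transformer_freezes_ranges(self):
        full = feature_frame([(0, 1.0, 0.1), (0, 5.0, 0.9), (1, 3.0, 0.5)])
        sub = full.iloc[:2]
        t = GowerTransformer().fit(full)
        d_sub = t.transform(sub)
        # the continuous parts use the full-table ranges, not the sub-table's
        assert d_sub[0, 1] == pytest.approx((0 + 4 / 4 + 0.8 / 0.8) / 3)


class TestHierarchical:
    def test_separated_pairs_merge_first(self):
        d = np.array(
            [
                [0.0, 0.1, 5.0, 5.0],
                [0.1, 0.0, 5.0, 5.0],
                [5.0, 5.0, 0.0, 0.1],
                [5.0, 5.0, 0.1, 0.0],
            ]
        )
        for link in ("ward", "ward_d", "average", "complete", "single"):
            dend = hierarchical_cluster(d, link)
            labels = cut_tree(dend, 2)
            assert labels[0] == labels[1] and labels[2] == labels[3]
            assert labels[0] != labels[2]

    def test_average_linkage_hand_computation(self):
        # 4 points on a line at 0, 1, 5, 7 with Euclidean dissimilarity
        x = np.array([0.0, 1.0, 5.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        dend = hierarchical_cluster(d, "average")
        # merges: (0,1)@1, (2,3)@2, then average of {0,1}x{2,3} = (5+7+4+6)/4
        np.testing.assert_allclose(dend.heights, [1.0, 2.0, 5.5])

    @pytest.mark.parametrize("link", ["ward", "average", "complete", "single"])
    def test_partitions_match_scipy(self, link):
        rng = np.random.default_rng(21)
        for _ in range(10):
            d = random_dissimilarity(rng, 9)
            dend = hierarchical_cluster(d, link)
            ours = cut_tree(dend, 2)
            Z = linkage(squareform(d, checks=False), method=link)
            theirs = fcluster(Z, t=2, criterion="maxclust")
            assert (
                adjusted_equal(ours, theirs)
            ), f"partition mismatch for {link}"

    @pytest.mark.parametrize("link", ["ward", "average", "complete", "single"])
    def test_heights_monotone(self, link):
        rng = np.random.default_rng(22)
        d = random_dissimilarity(rng, 12)
        dend = hierarchical_cluster(d, link)
        assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_heights_match_scipy_exactly(self):
        rng = np.random.default_rng(23)
        d = random_dissimilarity(rng, 10)
        for link in ("ward", "average", "complete", "single"):
            dend = hierarchical_cluster(d, link)
            Z = linkage(squareform(d, checks=False), method=link)
            np.testing.assert_allclose(np.sort(dend.heights), np.sort(Z[:, 2]), rtol=1e-10)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.zeros((1, 1)))

    def test_newick_export_parses(self):
        rng = np.random.default_rng(24)
        dend = hierarchical_cluster(random_dissimilarity(rng, 5))
        s = dend.to_newick()
        assert s.endswith(";") and s.count("(") == 4
        for i in range(5):
            assert f"L{i}:" in s


def adjusted_equal(a, b):
    """Same partition up to label renaming."""
    a, b = np.asarray(a), np.asarray(b)
    mapping = {}
    for x, y in zip(a, b):
        if x in mapping and mapping[x] != y:
            return False
        mapping[x] = y
    return len(set(mapping.values())) == len(mapping)


class TestAgglomerativeCoefficient:
    def test_two_leaves_give_zero(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert agglomerative_coefficient(hierarchical_cluster(d, "single")) == 0.0

    def test_three_leaf_hand_value(self):
        # single linkage: (a,b) merge at 1, then c joins at 4
        d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dend = hierarchical_cluster(d, "single")
        assert agglomerative_coefficient(dend) == pytest.approx((0.75 + 0.75 + 0.0) / 3)

    def test_tight_classes_approach_one(self):
        rng = np.random.default_rng(25)
        pts = np.concatenate([rng.normal(0, 0.01, (20, 2)), rng.normal(10, 0.01, (20, 2))])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ac = agglomerative_coefficient(hierarchical_cluster(d, "average"))
        assert ac > 0.99

    def test_scale_invariance(self):
        rng = np.random.default_rng(26)
        d = random_dissimilarity(rng, 8)
        ac1 = agglomerative_coefficient(hierarchical_cluster(d, "average"))
        ac2 = agglomerative_coefficient(hierarchical_cluster(17.3 * d, "average"))
        assert ac1 == pytest.approx(ac2, abs=1e-12)

    def test_identical_points_defined_as_zero(self):
        d = np.zeros((3, 3))
        with pytest.warns(UserWarning):
            assert agglomerative_coefficient(hierarchical_cluster(d, "single")) == 0.0


class TestCutTree:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(27)
        d = random_dissimilarity(rng, 6)
        dend = hierarchical_cluster(d)
        assert len(np.unique(cut_tree(dend, 6))) == 6
        assert len(np.unique(cut_tree(dend, 1))) == 1
        with pytest.raises(ValueError):
            cut_tree(dend, 0)
        with pytest.raises(ValueError):
            cut_tree(dend, 7)


class TestPAM:
    def brute_force_k2(self, d):
        n = d.shape[0]
        best = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                obj = np.minimum(d[:, i], d[:, j]).sum()
                best = min(best, obj)
        return best

    def test_matches_exhaustive_search_k2(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            d = random_dissimilarity(rng, 8)
            labels, medoids = pam(d, 2)
            obj = d[np.arange(8), medoids[labels]].sum()
            assert obj == pytest.approx(self.brute_force_k2(d), abs=1e-12)

    def test_k_equals_n_zero_objective(self):
        rng = np.random.default_rng(32)
        d = random_dissimilarity(rng, 5)
        labels, medoids = pam(d, 5)
        assert d[np.arange(5), medoids[labels]].sum() == 0.0

    def test_duplicates_cluster_together(self):
        base = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        d = np.sqrt(((base[:, None] - base[None, :]) ** 2).sum(-1))
        labels, _ = pam(d, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]

    def test_estimator_interface(self):
        df = feature_frame([(0, 2.0, 0.2), (0, 2.1, 0.25), (1, 3.0, 0.8), (1, 3.1, 0.85)])
        est = PAMClustering(n_clusters=2).fit(df)
        assert len(np.unique(est.labels_)) == 2
        assert est.labels_[0] == est.labels_[1]


class TestKMeans:
    def test_two_point_masses_recovered(self):
        x = np.array([[0, 0], [0, 0], [5, 5], [5, 5]], dtype=float)
        labels, centroids, inertia = kmeans(x, 2, seed=0)
        assert labels[0] == labels[1] != labels[2]
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_k1_centroid_is_mean(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=(20, 3))
        _, centroids, _ = kmeans(x, 1, seed=0)
        np.testing.assert_allclose(centroids[0], x.mean(axis=0), atol=1e-12)

    def test_matches_sklearn_objective_on_separable_data(self):
        rng = np.random.default_rng(34)
        x = np.concatenate([rng.normal(0, 0.1, (15, 2)), rng.normal(5, 0.1, (15, 2))])
        _, _, ours = kmeans(x, 2, seed=0, n_restarts=5)
        sk = SKKMeans(n_clusters=2, n_init=5, random_state=0).fit(x)
        assert ours == pytest.approx(sk.inertia_, rel=1e-9)

    def test_mixed_estimator_encoding_parallels_gower(self):
        df = feature_frame([(0, 1.0, 0.1), (0, 1.2, 0.15), (1, 4.0, 0.9), (1, 4.1, 0.95)])
        enc = encode_features(df)
        assert enc[:, 0].tolist() == [0, 0, 1, 1]
        assert enc[:, 1].min() == 0.0 and enc[:, 1].max() == 1.0
        est = MixedKMeans(n_clusters=2, random_state=0).fit(df)
        assert est.labels_[0] == est.labels_[1] != est.labels_[2]


def brute_silhouette(d, labels):
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = np.mean([d[i, j] for j in same])
        bs = []
        for c in set(labels) - {labels[i]}:
            bs.append(np.mean([d[i, j] for j in range(n) if labels[j] == c]))
        b = min(bs)
        out[i] = (b - a) / max(a, b)
    return out


def brute_dunn(d, labels):
    labs = sorted(set(labels))
    between = min(
        d[i, j]
        for i in range(len(labels))
        for j in range(len(labels))
        if labels[i] != labels[j]
    )
    diam = max(
        (
            max(
                (d[i, j] for i in range(len(labels)) for j in range(len(labels))
                 if labels[i] == c and labels[j] == c),
                default=0.0,
            )
            for c in labs
        )
    )
    return between / diam


class TestValidationIndices:
    def test_ideal_clusters_have_unit_silhouette(self):
        d = np.zeros((4, 4))
        d[:2, 2:] = 1.0
        d[2:, :2] = 1.0
        mean_s, s = silhouette(d, np.array([0, 0, 1, 1]))
        assert mean_s == pytest.approx(1.0)

    def test_equidistant_point_scores_zero(self):
        # point 0 at distance 1 from its own cluster-mate and from the other cluster
        d = np.array(
            [
                [0.0, 1.0, 1.0, 1.0],
                [1.0, 0.0, 2.0, 2.0],
                [1.0, 2.0, 0.0, 0.5],
                [1.0, 2.0, 0.5, 0.0],
            ]
        )
        _, s = silhouette(d, np.array([0, 0, 1, 1]))
        assert s[0] == pytest.approx(0.0)

    def test_five_point_hand_instance_matches_brute_force(self):
        rng = np.random.default_rng(41)
        d = random_dissimilarity(rng, 5)
        labels = np.array([0, 0, 1, 1, 1])
        mean_s, s = silhouette(d, labels)
        np.testing.assert_allclose(s, brute_silhouette(d, labels), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 100_000), n=st.integers(4, 8))
    def test_silhouette_and_dunn_match_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        d = random_dissimilarity(rng, n)
        labels = rng.integers(0, 2, size=n)
        if len(set(labels.tolist())) < 2:
            labels[0] = 1 - labels[0]
        mean_s, s = silhouette(d, labels)
        np.testing.assert_allclose(s, brute_silhouette(d, labels), atol=1e-12)
        if all(np.sum(labels == c) > 1 for c in (0, 1)):
            assert dunn_index(d, labels) == pytest.approx(brute_dunn(d, labels), abs=1e-12)

    def test_silhouette_matches_sklearn(self):
        rng = np.random.default_rng(42)
        d = random_dissimilarity(rng, 12)
        labels = rng.integers(0, 3, size=12)
        while len(set(labels.tolist())) < 3:
            labels = rng.integers(0, 3, size=12)
        _, s = silhouette(d, labels)
        np.testing.assert_allclose(
            s, sk_silhouette_samples(d, labels, metric="precomputed"), atol=1e-10
        )

    def test_dunn_hand_value(self):
        d = np.array(
            [
                [0.0, 1.0, 2.0, 2.5],
                [1.0, 0.0, 2.2, 2.0],
                [2.0, 2.2, 0.0, 0.8],
                [2.5, 2.0, 0.8, 0.0],
            ]
        )
        assert dunn_index(d, np.array([0, 0, 1, 1])) == pytest.approx(2.0)

    def test_touching_clusters_give_zero(self):
        d = np.array(
            [
                [0.0, 0.5, 0.0, 1.0],
                [0.5, 0.0, 1.0, 1.0],
                [0.0, 1.0, 0.0, 0.5],
                [1.0, 1.0, 0.5, 0.0],
            ]
        )
        assert dunn_index(d, np.array([0, 0, 1, 1])) == 0.0

    def test_all_singletons_undefined(self):
        rng = np.random.default_rng(43)
        d = random_dissimilarity(rng, 3)
        with pytest.raises(ValueError, match="singleton"):
            dunn_index(d, np.array([0, 1, 2]))

    def test_k1_silhouette_rejected(self):
        rng = np.random.default_rng(44)
        with pytest.raises(ValueError):
            silhouette(random_dissimilarity(rng, 4), np.zeros(4, dtype=int))


class TestValidationScan:
    def test_full_grid_size(self):
        rng = np.random.default_rng(51)
        df = feature_frame(
            [(int(rng.integers(2)), rng.uniform(1, 4), rng.uniform(0.1, 1.0)) for _ in range(20)]
        )
        report = validation_scan(df)
        assert len(report.entries) == 15  # 3 methods x k in 2..6

    def test_structureless_cloud_scores_poorly_at_every_k(self):
        # Gower range-normalises each variable, so silhouette is scale-free:
        # a "tight" blob behaves like any structureless cloud. No cut of an
        # unstructured cloud should approach the separation of real clusters.
        rng = np.random.default_rng(52)
        df = feature_frame(
            [(0, rng.uniform(1, 4), rng.uniform(0.1, 1.0)) for _ in range(100)]
        )
        report = validation_scan(df, methods=("hierarchical",))
        for e in report.entries:
            if not e.degenerate:
                assert e.mean_silhouette < 0.5

    def test_two_ideal_blobs_best_at_k2(self):
        df = feature_frame([(0, 1.0, 0.2)] * 10 + [(1, 4.0, 0.9)] * 10)
        report = validation_scan(df)
        best = report.best("mean_silhouette")
        assert best.k == 2
        assert best.mean_silhouette > 0.95

    def test_agglomerative_estimator(self):
        df = feature_frame([(0, 1.0, 0.2)] * 5 + [(1, 4.0, 0.9)] * 5)
        est = AgglomerativeGower(n_clusters=2).fit(df)
        assert est.agglomerative_coefficient_ > 0.9
        assert len(np.unique(est.labels_)) == 2
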