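import itertools

import numpy as np
import pandas as pd
import pytest

import milkbiome as mb
from milkbiome.tableio import CountTableError


def dist_from_array(a, ids=None):
    ids = ids or [f"S{i}" for i in range(len(a))]
    return mb.DistanceMatrix(pd.DataFrame(a, index=ids, columns=ids))


def brute_force_complete_linkage(d):
    """Naive agglomeration oracle: repeatedly merge the pair of clusters
    with the smallest maximum pairwise distance."""
    n = len(d)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(d[i][j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), h))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = mb.CountTable(pd.DataFrame({"A": [3, 1], "B": [3, 1]},
                                       index=["x", "y"]))
        d = mb.bray_curtis(mb.to_relative(t))
        assert d.values.loc["A", "B"] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        t = mb.CountTable(pd.DataFrame({"A": [1, 0], "B": [0, 1]},
                                       index=["x", "y"]))
        d = mb.bray_curtis(mb.to_relative(t))
        assert d.values.loc["A", "B"] == pytest.approx(1.0)

    def test_direct_formula(self):
        t = mb.CountTable(pd.DataFrame({"A": [6, 4], "B": [4, 6]},
                                       index=["x", "y"]))
        d = mb.bray_curtis(mb.to_relative(t))
        assert d.values.loc["A", "B"] == pytest.approx(0.2)

    def test_bounded_unit_interval(self, cohort):
        comp = mb.to_relative(cohort[0].subset_samples(
            cohort[0].biological_samples))
        d = mb.bray_curtis(comp).values.to_numpy()
        assert d.min() >= 0 and d.max() <= 1 + 1e-12


class TestHierarchicalCluster:
    def test_two_point_cut(self):
        d = dist_from_array([[0, 0.9], [0.9, 0]])
        m1 = mb.hierarchical_cluster(d, cut_height=0.8, min_size=1)
        assert m1.labels.nunique() == 2
        m2 = mb.hierarchical_cluster(d, cut_height=0.95, min_size=1)
        assert m2.labels.nunique() == 1

    def test_three_point_hand_agglomeration(self):
        d = dist_from_array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        m = mb.hierarchical_cluster(d, cut_height=0.5, min_size=1)
        # first merge {A,B} at 0.1; final merge at 0.9 (complete = max)
        assert m.linkage[0, 2] == pytest.approx(0.1)
        assert m.linkage[1, 2] == pytest.approx(0.9)
        assert m.labels["S0"] == m.labels["S1"] != m.labels["S2"]

    def test_matches_brute_force_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pts = rng.random((8, 3))
            a = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            merges = brute_force_complete_linkage(a.tolist())
            m = mb.hierarchical_cluster(dist_from_array(a), 0.5, min_size=1)
            np.testing.assert_allclose(
                sorted(m.linkage[:, 2]), sorted(h for _, h in merges),
                atol=1e-12)

    def test_cut_extremes(self):
        rng = np.random.default_rng(1)
        pts = rng.random((6, 2))
        a = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = dist_from_array(a)
        m0 = mb.hierarchical_cluster(d, cut_height=0.0, min_size=1)
        assert m0.labels.nunique() == 6        # all singletons
        mmax = mb.hierarchical_cluster(d, cut_height=a.max() + 1, min_size=1)
        assert mmax.labels.nunique() == 1

    def test_small_clusters_set_aside(self):
        # 2 tight groups of 5 + 1 outlier; min_size 3 sets outlier aside
        a = np.full((11, 11), 0.9)
        np.fill_diagonal(a, 0)
        a[:5, :5] = 0.05
        a[5:10, 5:10] = 0.05
        np.fill_diagonal(a, 0)
        m = mb.hierarchical_cluster(dist_from_array(a), 0.5, min_size=3)
        assert m.labels["S10"] == 0
        assert sorted(m.labels.unique()) == [0, 1, 2]
        assert m.small_clusters

    def test_asymmetric_rejected(self):
        with pytest.raises(CountTableError, match="symmetric"):
            dist_from_array([[0, 0.2], [0.5, 0]])

    def test_newick_export_parses(self):
        d = dist_from_array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        m = mb.hierarchical_cluster(d, 0.5, min_size=1)
        nwk = mb.to_newick(m)
        assert nwk.endswith(";")
        import io
        import skbio
        tree = skbio.TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"S0", "S1", "S2"}


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(2)
        pts = rng.random((7, 2))
        a = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = mb.pcoa(dist_from_array(a))
        emb = res.coordinates.to_numpy()
        back = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
        np.testing.assert_allclose(back, a, atol=1e-9)

    def test_axes_orthogonal_and_ordered(self):
        rng = np.random.default_rng(3)
        pts = rng.random((10, 4))
        a = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = mb.pcoa(dist_from_array(a))
        emb = res.coordinates.to_numpy()
        gram = emb.T @ emb
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-8)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_negative_eigenvalues_reported_for_bray(self, cohort):
        comp = mb.to_relative(cohort[0].subset_samples(
            cohort[0].biological_samples))
        res = mb.pcoa(mb.bray_curtis(comp))
        # Bray-Curtis is non-Euclidean: some negative eigenvalues expected
        assert res.negative_eigenvalues.size > 0
        assert (res.eigenvalues > 0).all()

    def test_cluster_separation_on_first_axes(self, cohort, spike_id):
        table, _, _, truth = cohort
        clean = mb.subtract_background(
            table, mb.identify_background(table, spike_id))
        comp = mb.to_relative(clean.subset_samples(clean.biological_samples))
        res = mb.pcoa(mb.bray_curtis(comp), n_axes=2)
        labels = pd.Series(truth.true_cluster)
        cents = {c: res.coordinates.loc[labels[labels == c].index].mean()
                 for c in labels.unique()}
        within = np.mean([
            np.linalg.norm(res.coordinates.loc[s] - cents[labels[s]])
            for s in res.coordinates.index])
        between = np.mean([
            np.linalg.norm(cents[a] - cents[b])
            for a, b in itertools.combinations(cents, 2)])
        assert between > within


class TestSelectK:
    def two_blob_distance(self):
        a = np.full((10, 10), 0.9)
        a[:5, :5] = 0.01
        a[5:, 5:] = 0.01
        np.fill_diagonal(a, 0)
        return dist_from_array(a)

    def test_two_separated_blobs(self):
        d = self.two_blob_distance()
        m = mb.hierarchical_cluster(d, 0.5, min_size=1)
        m = mb.select_k(d, m, range(2, 6))
        assert m.selected_k == 2
        assert m.scores.loc[2, "silhouette"] > 0.9

    def test_identical_points_flagged_degenerate(self):
        a = np.zeros((5, 5))
        d = dist_from_array(a)
        m = mb.hierarchical_cluster(d, 0.5, min_size=1)
        m = mb.select_k(d, m, range(2, 4))
        assert m.scores["calinski_harabasz"].isna().all()
        assert m.selected_k is None

    def test_k_range_bounds_enforced(self):
        d = self.two_blob_distance()
        m = mb.hierarchical_cluster(d, 0.5, min_size=1)
        with pytest.raises(CountTableError):
            mb.select_k(d, m, range(2, 12))

    def test_recovers_three_synthetic_clusters(self, cohort, spike_id):
        from sklearn.metrics import adjusted_rand_score
        table, _, _, truth = cohort
        clean = mb.subtract_background(
            table, mb.identify_background(table, spike_id))
        comp = mb.to_relative(clean.subset_samples(clean.biological_samples))
        d = mb.bray_curtis(comp)
        m = mb.hierarchical_cluster(d, 0.8)
        m = mb.select_k(d, m, range(2, 8))
        assert m.selected_k == 3
        lab = mb.cut_into_k(m, 3)
        true = pd.Series(truth.true_cluster).loc[lab.index]
        assert adjusted_rand_score(true, lab) > 0.9
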