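import numpy as np
import pytest

import chemomodes as cm
from chemomodes.errors import DegenerateDensityError, ParameterError
from chemomodes.geometry import PairwiseMatrix


def brute_force_density_delta(points, dc, kernel):
    m = len(points)
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    rho = np.zeros(m)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            if kernel == "cutoff":
                rho[i] += 1.0 if dist[i, j] < dc else 0.0
            else:
                rho[i] += np.exp(-((dist[i, j] / dc) ** 2))
    delta = np.zeros(m)
    for i in range(m):
        higher = [j for j in range(m)
                  if rho[j] > rho[i] or (rho[j] == rho[i] and j < i)]
        if not higher:
            delta[i] = dist.max()
        else:
            delta[i] = min(dist[i, j] for j in higher)
    return rho, delta


class TestDrmsCluster:
    def test_single_cluster_when_all_close(self):
        values = np.full((5, 5), 0.05)
        np.fill_diagonal(values, 0.0)
        res = cm.drms_cluster(PairwiseMatrix(values, "drms"), cutoff=0.2)
        assert res.n_clusters == 1
        assert res.probabilities[0] == 1.0

    def test_two_group_fixture_splits_exactly(self):
        # 6 frames: indices 0-3 mutually close, 4-5 close, groups far apart
        values = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                same = (i < 4) == (j < 4)
                values[i, j] = 0.1 if same else 0.8
        res = cm.drms_cluster(PairwiseMatrix(values, "drms"), cutoff=0.2)
        assert res.n_clusters == 2
        assert set(res.labels[:4]) == {0} and set(res.labels[4:]) == {1}
        np.testing.assert_allclose(sorted(res.probabilities), [2 / 6, 4 / 6])

    def test_deterministic_partition(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, size=(30, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        m = PairwiseMatrix(d, "drms")
        a = cm.drms_cluster(m, cutoff=0.3)
        b = cm.drms_cluster(m, cutoff=0.3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ParameterError):
            cm.drms_cluster(PairwiseMatrix(np.zeros((2, 2)), "drms"), cutoff=0.0)


class TestDensityDelta:
    def test_three_collinear_points_hand_values(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        dd = cm.density_delta(pts, dc=1.5, kernel="cutoff")
        np.testing.assert_array_equal(dd.rho, [1.0, 2.0, 1.0])
        assert dd.delta[1] == 2.0  # global peak: max pairwise distance
        assert dd.delta[0] == 1.0 and dd.delta[2] == 1.0
        assert dd.nearest_higher[1] == -1

    def test_identical_points_raise(self):
        pts = np.zeros((4, 2))
        with pytest.raises(DegenerateDensityError):
            cm.density_delta(pts, dc=1.0)

    @pytest.mark.parametrize("kernel", ["cutoff", "gaussian"])
    def test_matches_brute_force_on_random_points(self, kernel):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 3, size=(500, 2))
        dc = 0.3
        dd = cm.density_delta(pts, dc, kernel=kernel)
        rho, delta = brute_force_density_delta(pts, dc, kernel)
        np.testing.assert_allclose(dd.rho, rho, atol=1e-12)
        np.testing.assert_allclose(dd.delta, delta, atol=1e-12)


class TestDensityPeakCluster:
    def test_three_blob_fixture_recovers_partition(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2014)
        means = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
        pts = np.vstack([m + rng.normal(scale=0.3, size=(300, 2)) for m in means])
        labels_true = np.repeat([0, 1, 2], 300)
        res = cm.density_peak_cluster(pts, n_centers=3)
        ari = sklearn_metrics.adjusted_rand_score(labels_true, res.labels)
        assert ari > 0.95

    def test_single_blob_single_cluster(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(200, 2))
        res = cm.density_peak_cluster(pts, n_centers=1)
        assert res.n_clusters == 1
        assert res.probabilities[0] == 1.0
        assert set(res.labels) == {0}

    def test_two_basin_fixture_recovers_weights_and_centers(self, two_basin_run):
        pts = two_basin_run["points"]
        res = cm.density_peak_cluster(pts, n_centers=2)
        order = np.argsort(res.center_points[:, 0])
        centers = res.center_points[order]
        probs = res.probabilities[order]
        planted = np.array(cm.synthetic_data.TWO_BASIN_CENTERS)
        assert np.abs(centers - planted).max() < 0.2
        np.testing.assert_allclose(probs, [0.7, 0.3], atol=0.03)

    def test_unequal_weights_recovered(self):
        ensemble, truth = cm.two_basin_fixture(n_frames=3000, weights=(0.8, 0.2), seed=11)
        basis = cm.ModeBasis(mean=truth.template.coords, eigenvalues=np.ones(2),
                             eigenvectors=truth.mode_vectors, kind="pca",
                             labels=list(ensemble.labels))
        pts = cm.project(ensemble, basis, k=2).values
        res = cm.density_peak_cluster(pts, n_centers=2)
        order = np.argsort(res.center_points[:, 0])
        np.testing.assert_allclose(res.probabilities[order], [0.8, 0.2], atol=0.03)

    def test_threshold_center_selection(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(scale=0.2, size=(150, 2)),
                         np.array([2.5, 2.5]) + rng.normal(scale=0.2, size=(150, 2))])
        dd = cm.density_delta(pts, dc=cm.choose_dc(pts))
        res = cm.density_peak_cluster(pts, rho_min=np.median(dd.rho),
                                      delta_min=1.0)
        assert res.n_clusters == 2

    def test_too_many_centers_rejected(self):
        with pytest.raises(ParameterError):
            cm.density_peak_cluster(np.random.default_rng(0).normal(size=(10, 2)),
                                    n_centers=11)


class TestClusterProbabilities:
    def test_fraction_and_conservation(self):
        res = cm.ClusterResult(labels=np.array([0, 0, 0, 1]), centers=np.array([0, 3]),
                               probabilities=np.array([0.75, 0.25]))
        probs, totals = cm.cluster_probabilities(res, grouping=[[0, 1]])
        np.testing.assert_allclose(probs, [0.75, 0.25])
        assert totals[0] == pytest.approx(1.0, abs=1e-12)

    def test_group_by_negative_pe2_center(self, two_basin_run):
        pts = two_basin_run["points"]
        res = cm.density_peak_cluster(pts, n_centers=2)
        neg = [i for i in range(2) if res.center_points[i, 1] < 0]
        _, totals = cm.cluster_probabilities(res, grouping=[neg])
        assert totals[0] == pytest.approx(0.3, abs=0.03)

    def test_unknown_cluster_id_rejected(self):
        res = cm.ClusterResult(labels=np.array([0, 1]), centers=np.array([0, 1]),
                               probabilities=np.array([0.5, 0.5]))
        with pytest.raises(ParameterError):
            cm.cluster_probabilities(res, grouping=[[2]])
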