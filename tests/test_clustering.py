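import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cilgibbs.clustering import (GROUP_GIBBS, GROUP_INVASION,
                                 incremental_centroids, index_battery,
                                 kmeans_cluster, name_groups_by_interaction,
                                 optimal_k, zscore_metrics)


class TestZScore:
    def test_closed_form_one_two_three(self):
        df = pd.DataFrame({"L_r": [1.0, 2.0, 3.0], "G_r": [3.0, 2.0, 1.0]})
        out = zscore_metrics(df)
        np.testing.assert_allclose(out["z_L_r"], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(out["z_G_r"], [1.0, 0.0, -1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"L_r": rng.normal(10, 3, 40),
                           "G_r": rng.normal(5, 2, 40)})
        out = zscore_metrics(df)
        for c in ("z_L_r", "z_G_r"):
            assert abs(out[c].mean()) < 1e-9
            assert out[c].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            zscore_metrics(pd.DataFrame({"L_r": [1.0], "G_r": [1.0]}))
        with pytest.raises(ValueError, match="zero variance"):
            zscore_metrics(pd.DataFrame({"L_r": [1.0, 1.0],
                                         "G_r": [1.0, 2.0]}))


class TestKMeans:
    def test_two_blobs_perfect_recovery(self, two_blobs):
        X, truth = two_blobs
        res = kmeans_cluster(X, 2, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert set(res.group_of_cluster.values()) == {GROUP_GIBBS,
                                                      GROUP_INVASION}

    def test_k_one_centroid_is_mean(self, two_blobs):
        X, _ = two_blobs
        res = kmeans_cluster(X, 1, seed=0)
        np.testing.assert_allclose(res.centroids[0], X.mean(axis=0),
                                   atol=1e-8)

    def test_k_equals_n_zero_inertia(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        res = kmeans_cluster(X, 8, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_group_naming_by_dispersion(self):
        """The more dispersed cluster gets the Invasion label regardless
        of its size or position."""
        rng = np.random.default_rng(5)
        tight = rng.normal([5.0, 5.0], 0.05, (30, 2))
        loose = rng.normal([0.0, 0.0], 1.0, (20, 2))
        res = kmeans_cluster(np.vstack([tight, loose]), 2, seed=0)
        groups = res.group_labels
        assert (groups[:30] == GROUP_GIBBS).all()
        assert (groups[30:] == GROUP_INVASION).all()
        # accounting: every point assigned to one of the two groups
        assert (groups == GROUP_GIBBS).sum() + \
            (groups == GROUP_INVASION).sum() == 50

    def test_label_stability_across_seeds(self, two_blobs):
        X, _ = two_blobs
        base = kmeans_cluster(X, 2, seed=0)
        for s in range(1, 10):
            res = kmeans_cluster(X, 2, seed=s)
            assert adjusted_rand_score(base.labels, res.labels) == 1.0

    def test_interaction_naming(self):
        """The cluster with smaller mean log gamma is the Gibbs group,
        independent of cluster dispersion."""
        labels = np.array([0, 0, 0, 1, 1])
        gamma = np.array([2.1, 1.8, 2.5, 0.3, 0.5])
        names = name_groups_by_interaction(labels, gamma)
        assert names == {1: GROUP_GIBBS, 0: GROUP_INVASION}
        with pytest.raises(ValueError):
            name_groups_by_interaction(np.zeros(4), gamma[:4])

    def test_invalid_k(self, two_blobs):
        X, _ = two_blobs
        with pytest.raises(ValueError):
            kmeans_cluster(X, 0)
        with pytest.raises(ValueError):
            kmeans_cluster(X, len(X) + 1)


def _toy_six_points():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0],
                  [5.0, 5.0], [5.0, 6.0], [6.0, 5.0]])
    labels = np.array([0, 0, 0, 1, 1, 1])
    centroids = np.array([X[:3].mean(axis=0), X[3:].mean(axis=0)])
    return X, labels, centroids


class TestValidityIndices:
    """Each index value at k=2 on the toy set equals a hand computation
    from its published formula (naive loops, independent code path)."""

    @pytest.fixture
    def battery_k2(self):
        from cilgibbs.clustering import ClusteringResult

        X, labels, C = _toy_six_points()
        wss = np.array([((X[labels == j] - C[j]) ** 2).sum()
                        for j in range(2)])
        res = ClusteringResult(k=2, labels=labels, centroids=C,
                               inertia=float(wss.sum()),
                               within_cluster_ss=wss)
        return X, labels, C, index_battery(X, {2: res}, gap_B=5, seed=0)

    @staticmethod
    def _pairs(X, labels):
        within, between = [], []
        n = len(X)
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.hypot(*(X[i] - X[j])))
                (within if labels[i] == labels[j] else between).append(d)
        return within, between

    def test_dunn(self, battery_k2):
        X, labels, _, out = battery_k2
        within, between = self._pairs(X, labels)
        expected = min(between) / max(within)
        assert out["dunn"]["values"][2] == pytest.approx(expected)

    def test_c_index(self, battery_k2):
        X, labels, _, out = battery_k2
        within, between = self._pairs(X, labels)
        alld = sorted(within + between)
        nw = len(within)
        s = sum(within)
        expected = (s - sum(alld[:nw])) / (sum(alld[-nw:]) - sum(alld[:nw]))
        assert out["c_index"]["values"][2] == pytest.approx(expected)

    def test_mcclain_rao(self, battery_k2):
        X, labels, _, out = battery_k2
        within, between = self._pairs(X, labels)
        expected = np.mean(within) / np.mean(between)
        assert out["mcclain_rao"]["values"][2] == pytest.approx(expected)

    def test_point_biserial(self, battery_k2):
        X, labels, _, out = battery_k2
        within, between = self._pairs(X, labels)
        alld = np.array(within + between)
        nw, nb = len(within), len(between)
        nt = nw + nb
        expected = (np.mean(between) - np.mean(within)) * \
            np.sqrt(nw * nb / nt ** 2) / alld.std()
        assert out["point_biserial"]["values"][2] == pytest.approx(expected)

    def test_ball_hall(self, battery_k2):
        X, labels, C, out = battery_k2
        W = sum(((X[labels == j] - C[j]) ** 2).sum() for j in range(2))
        assert out["ball_hall"]["values"][2] == pytest.approx(W / 2)

    def test_ratkowsky_lance(self, battery_k2):
        X, labels, C, out = battery_k2
        xbar = X.mean(axis=0)
        ratios = []
        for v in range(2):
            bgss = sum((labels == j).sum() * (C[j, v] - xbar[v]) ** 2
                       for j in range(2))
            tss = ((X[:, v] - xbar[v]) ** 2).sum()
            ratios.append(np.sqrt(bgss / tss))
        expected = np.mean(ratios) / np.sqrt(2)
        assert out["ratkowsky_lance"]["values"][2] == pytest.approx(expected)

    def test_silhouette(self, battery_k2):
        X, labels, _, out = battery_k2
        svals = []
        for i in range(len(X)):
            same = [np.hypot(*(X[i] - X[j])) for j in range(len(X))
                    if j != i and labels[j] == labels[i]]
            other = [np.hypot(*(X[i] - X[j])) for j in range(len(X))
                     if labels[j] != labels[i]]
            a, b = np.mean(same), np.mean(other)
            svals.append((b - a) / max(a, b))
        assert out["silhouette"]["values"][2] == pytest.approx(
            np.mean(svals))

    def test_calinski_harabasz(self, battery_k2):
        X, labels, C, out = battery_k2
        xbar = X.mean(axis=0)
        n, k = len(X), 2
        bg = sum((labels == j).sum() * np.sum((C[j] - xbar) ** 2)
                 for j in range(k))
        wg = sum(np.sum((X[labels == j] - C[j]) ** 2) for j in range(k))
        expected = (bg / (k - 1)) / (wg / (n - k))
        assert out["calinski_harabasz"]["values"][2] == pytest.approx(
            expected)

    def test_davies_bouldin(self, battery_k2):
        X, labels, C, out = battery_k2
        s = [np.mean([np.hypot(*(x - C[j])) for x in X[labels == j]])
             for j in range(2)]
        m01 = np.hypot(*(C[0] - C[1]))
        expected = np.mean([max((s[0] + s[1]) / m01,
                                (s[0] + s[1]) / m01)] * 2)
        assert out["davies_bouldin"]["values"][2] == pytest.approx(expected)


class TestOptimalK:
    def test_two_blobs_majority_two(self, two_blobs):
        X, _ = two_blobs
        k_star, votes = optimal_k(X, range(2, 9), seed=3)
        assert k_star == 2
        assert sum(v == 2 for v in votes.values()) >= 8  # near-unanimous

    def test_needs_enough_points(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            optimal_k(rng.normal(size=(10, 2)), range(2, 9))


class TestIncrementalCentroids:
    def test_identical_points_constant_trajectory(self):
        X = np.ones((30, 2)) * 3.0
        traj = incremental_centroids(X, start=4, k=2, seed=0)
        assert traj.shape == (27, 2, 2)
        np.testing.assert_allclose(traj, 3.0)

    def test_two_blob_trajectories_converge(self, two_blobs):
        X, _ = two_blobs
        rng = np.random.default_rng(4)
        order = rng.permutation(len(X))
        traj = incremental_centroids(X, order, start=20, k=2, seed=0)
        final = traj[-1]
        # tail of the trajectory stays near the final centroids
        tail = traj[-20:]
        drift = np.linalg.norm(tail - final, axis=2).max()
        assert drift < 0.2
        # trajectories never cross: consistently separated
        sep = np.linalg.norm(traj[:, 0] - traj[:, 1], axis=1)
        assert (sep > 3.0).all()

    def test_start_validation(self, two_blobs):
        X, _ = two_blobs
        with pytest.raises(ValueError):
            incremental_centroids(X, start=3, k=2)
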