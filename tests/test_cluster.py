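"""Stratification tests: GK clustering, PCA, loadings, DBS-ranked report."""

import numpy as np
import pandas as pd
import pytest

from spinbath.cluster import (
    GustafsonKessel,
    cluster_db_report,
    factor_loading_table,
    hard_assign,
    pca_2d,
)


def _rotate2(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


@pytest.fixture(scope="module")
def anisotropic_blobs():
    """Two elongated, rotated, parallel Gaussian clusters.

    Their long axes dwarf the gap between them, so a spherical (identity
    norm) partition cuts across both; an adaptive Mahalanobis norm resolves
    them.  Fixed fixture.
    """
    rng = np.random.default_rng(42)
    cov = _rotate2(30) @ np.diag([25.0, 0.05]) @ _rotate2(30).T
    a = rng.multivariate_normal([0.0, 0.0], cov, size=60)
    offset = _rotate2(30) @ np.array([0.0, 2.0])
    b = rng.multivariate_normal(offset, cov, size=60)
    X = np.vstack([a, b])
    y = np.repeat([0, 1], 60)
    return X, y


def _pair_accuracy(labels, truth):
    """Best-permutation accuracy for two clusters."""
    acc = np.mean(labels == truth)
    return max(acc, 1.0 - acc)


class TestGustafsonKessel:
    def test_single_cluster_is_the_mean_with_full_membership(self, rng):
        X = rng.normal(size=(20, 3))
        gk = GustafsonKessel(n_clusters=1, n_init=2, random_state=0).fit(X)
        np.testing.assert_array_equal(gk.memberships_, np.ones((20, 1)))
        np.testing.assert_allclose(gk.cluster_centers_[0], X.mean(axis=0), rtol=1e-12)

    def test_separated_spherical_blobs_fully_recovered(self, rng):
        a = rng.normal(0.0, 1.0, (40, 4))
        b = rng.normal(0.0, 1.0, (40, 4))
        b[:, 0] += 10.0
        X = np.vstack([a, b])
        gk = GustafsonKessel(n_clusters=2, n_init=4, random_state=0).fit(X)
        truth = np.repeat([0, 1], 40)
        assert _pair_accuracy(gk.labels_, truth) == 1.0

    def test_membership_rows_sum_to_one_and_lie_in_unit_interval(self, rng):
        X = rng.normal(size=(30, 5))
        gk = GustafsonKessel(n_clusters=4, n_init=4, random_state=1).fit(X)
        np.testing.assert_allclose(gk.memberships_.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(gk.memberships_ >= 0.0) and np.all(gk.memberships_ <= 1.0)

    @pytest.mark.parametrize("kwargs", [{"cov_blend": 0.0}, {"norm": "identity"}])
    def test_objective_trace_nonincreasing_for_canonical_updates(self, rng, kwargs):
        """The exact alternating updates descend the fuzzy objective."""
        X = rng.normal(size=(40, 4))
        for seed in range(3):
            gk = GustafsonKessel(n_clusters=3, n_init=1, random_state=seed, **kwargs).fit(X)
            trace = np.array(gk.objective_trace_)
            assert np.all(np.diff(trace) <= 1e-9 * max(1.0, trace[0]))

    def test_blended_norm_objective_drift_is_bounded(self, rng):
        # the blended covariance is not the exact minimizer of the alternating
        # step, so the objective may rise by roundoff-scale amounts only
        X = rng.normal(size=(40, 4))
        for seed in range(3):
            gk = GustafsonKessel(n_clusters=3, n_init=1, random_state=seed).fit(X)
            trace = np.array(gk.objective_trace_)
            assert np.all(np.diff(trace) <= 1e-4 * max(1.0, trace[0]))

    def test_point_on_center_gets_full_membership(self, rng):
        X = rng.normal(size=(25, 3))
        gk = GustafsonKessel(n_clusters=2, n_init=2, random_state=0).fit(X)
        u = gk.soft_predict(gk.cluster_centers_)
        np.testing.assert_allclose(np.diag(u), 1.0)

    def test_identity_norm_reproduces_fuzzy_c_means(self, rng):
        """GK with identity norms must coincide with textbook FCM updates."""
        X = rng.normal(size=(40, 3))
        X[20:, 0] += 4.0
        seed, c, m = 7, 2, 2.0
        gk = GustafsonKessel(
            n_clusters=c, fuzzifier=m, norm="identity", n_init=1,
            tol=1e-9, random_state=seed,
        ).fit(X)

        # independent FCM with the identical initial membership draw
        root = np.random.default_rng(seed)
        s = int(root.integers(0, 2**31 - 1, size=1)[0])
        r = np.random.default_rng(s)
        u = r.random((40, c)) + 1e-3
        u /= u.sum(axis=1, keepdims=True)
        for _ in range(500):
            um = u**m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-300)
            w = d2 ** (-1.0 / (m - 1.0))
            u_new = w / w.sum(axis=1, keepdims=True)
            if np.max(np.abs(u_new - u)) < 1e-9:
                u = u_new
                break
            u = u_new
        np.testing.assert_allclose(gk.memberships_, u, atol=1e-6)

    def test_adaptive_norm_resolves_blobs_that_spherical_norm_cannot(self, anisotropic_blobs):
        X, y = anisotropic_blobs
        gk = GustafsonKessel(n_clusters=2, n_init=8, random_state=0).fit(X)
        fcm = GustafsonKessel(n_clusters=2, norm="identity", n_init=8, random_state=0).fit(X)
        assert _pair_accuracy(gk.labels_, y) >= 0.97
        assert _pair_accuracy(fcm.labels_, y) < 0.8

    def test_overprovisioned_clustering_flags_spare_capacity(self, rng):
        a = rng.normal(0.0, 0.3, (15, 5))
        b = rng.normal(0.0, 0.3, (15, 5))
        b[:, 0] += 6.0
        gk = GustafsonKessel(n_clusters=6, fuzzifier=3.0, n_init=8, random_state=0).fit(
            np.vstack([a, b])
        )
        sizes = np.bincount(gk.labels_, minlength=6)
        assert len(gk.empty_clusters_) >= 1 or sizes.min() <= 2

    def test_more_clusters_than_points_rejected(self, rng):
        with pytest.raises(ValueError):
            GustafsonKessel(n_clusters=5).fit(rng.normal(size=(4, 2)))

    def test_sklearn_param_round_trip(self):
        gk = GustafsonKessel(n_clusters=3, fuzzifier=2.5)
        params = gk.get_params()
        clone = GustafsonKessel(**params)
        assert clone.get_params() == params


class TestHardAssign:
    def test_argmax_and_tie_break_to_lowest_index(self):
        u = np.array([[0.6, 0.4], [0.5, 0.5], [0.1, 0.9]])
        labels, empty = hard_assign(u)
        np.testing.assert_array_equal(labels, [0, 0, 1])
        assert empty == []

    def test_empty_cluster_reported(self):
        u = np.array([[0.9, 0.05, 0.05], [0.8, 0.1, 0.1], [0.2, 0.7, 0.1]])
        labels, empty = hard_assign(u)
        assert empty == [2]


class TestPCA:
    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(30, 10))
        res = pca_2d(X)
        np.testing.assert_allclose(res.loadings @ res.loadings.T, np.eye(2), atol=1e-9)

    def test_agrees_with_covariance_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(25, 6))
        X[:, 3] += 2.5 * X[:, 0]  # give the spectrum structure
        res = pca_2d(X)
        evals, evecs = np.linalg.eigh(np.cov(X, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in (0, 1):
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(res.loadings[k], v, atol=1e-8)
        np.testing.assert_allclose(res.full_spectrum, evals, atol=1e-8)

    def test_rank_one_data_has_unit_first_ratio(self, rng):
        direction = rng.normal(size=6)
        X = np.outer(rng.normal(size=20), direction)
        res = pca_2d(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert res.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_rank_two_scores_preserve_pairwise_distances(self, rng):
        basis = np.linalg.qr(rng.normal(size=(8, 2)))[0]
        X = rng.normal(size=(20, 2)) @ basis.T
        res = pca_2d(X)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(res.scores), pdist(X), atol=1e-8)

    def test_rank_zero_data_rejected(self):
        with pytest.raises(ValueError):
            pca_2d(np.ones((10, 4)))

    def test_sign_convention_makes_dominant_loading_positive(self, rng):
        X = rng.normal(size=(30, 5))
        res = pca_2d(X)
        for k in (0, 1):
            assert res.loadings[k, np.argmax(np.abs(res.loadings[k]))] > 0


class TestFactorLoadings:
    def test_squared_shares_sum_to_one(self, rng):
        X = rng.normal(size=(30, 6))
        table = factor_loading_table(pca_2d(X), [f"v{i}" for i in range(6)])
        assert table["share_pc1"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["share_pc2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_name_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            factor_loading_table(pca_2d(rng.normal(size=(10, 4))), ["a", "b"])

    def test_constructed_variance_direction_dominates_first_component(self, rng):
        # features 0 and 1 carry a strong common factor; 2..5 are weak noise
        factor = rng.normal(size=400)
        X = 0.05 * rng.normal(size=(400, 6))
        X[:, 0] += factor
        X[:, 1] += factor
        table = factor_loading_table(pca_2d(X), [f"v{i}" for i in range(6)])
        top2 = set(table["share_pc1"].nlargest(2).index)
        assert top2 == {"v0", "v1"}


class TestClusterReport:
    @staticmethod
    def _cohort():
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(6)],
                "group": ["control", "control", "premanifest", "premanifest", "manifest", "manifest"],
                "dbs": [np.nan, np.nan, 150.0, 260.0, 420.0, 500.0],
            }
        )

    def test_manifest_cluster_ranked_first(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        report = cluster_db_report(labels, self._cohort(), n_clusters=3)
        assert report.top_cluster == 2
        assert report.bottom_cluster == 0
        assert report.transition_clusters == [1]

    def test_empty_cluster_has_no_dbs_summary(self):
        labels = np.array([0, 0, 1, 1, 3, 3])
        report = cluster_db_report(labels, self._cohort(), n_clusters=4)
        assert report.empty_clusters == [2]
        empty_entry = report.clusters[2]
        assert empty_entry["size"] == 0
        assert "dbs_mean" not in empty_entry

    def test_controls_flagged_and_ranked_by_sentinel(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        report = cluster_db_report(labels, self._cohort(), n_clusters=2)
        assert report.clusters[0]["contains_controls"]
        # cluster 0 has two controls (sentinel 0) and one carrier at 150
        assert report.clusters[0]["mean_dbs_for_ranking"] == pytest.approx(50.0)
        assert report.dbs_rank == [1, 0]

    def test_degenerate_single_cluster_warns_but_reports(self):
        labels = np.zeros(6, dtype=int)
        with pytest.warns(UserWarning, match="degenerate"):
            report = cluster_db_report(labels, self._cohort(), n_clusters=2)
        assert report.dbs_rank == [0]

    def test_label_cohort_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_db_report(np.array([0, 1]), self._cohort(), n_clusters=2)
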