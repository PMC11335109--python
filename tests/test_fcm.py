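"""Fuzzy c-means: update-formula hand cases, monotone convergence, planted
cluster recovery, reference-implementation agreement, and the silhouette-based
choice of cluster count."""

import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from dyadlink import (
    ConfigError,
    DyadlinkError,
    FCMConfig,
    GeneratorConfig,
    best_cluster_count,
    fcm_fit,
    generate_dataset,
    label_sleep_quality,
    silhouette_curve,
)
from dyadlink.dataio import apply_minmax, fit_minmax
from dyadlink.fcm import FCMResult, _memberships_from_distances
from dyadlink.schema import SLEEP_FEATURES


def reference_fcm(X, c, m=2.0, tol=1e-12, max_iter=2000, seed=0):
    """Independently coded FCM: k-means++ centers, plain-loop updates."""
    X = np.asarray(X, dtype=float)
    centers = (
        KMeans(n_clusters=c, init="k-means++", n_init=1, max_iter=1, random_state=seed)
        .fit(X)
        .cluster_centers_
    )
    n = len(X)
    U = np.zeros((n, c))
    for _ in range(max_iter):
        for k in range(n):
            d = np.array([np.sum((X[k] - centers[i]) ** 2) for i in range(c)])
            if (d == 0).any():
                U[k] = (d == 0) / (d == 0).sum()
            else:
                for i in range(c):
                    U[k, i] = 1.0 / np.sum((d[i] / d) ** (1.0 / (m - 1.0)))
        new_centers = np.array([
            (U[:, i] ** m) @ X / np.sum(U[:, i] ** m) for i in range(c)
        ])
        if np.abs(new_centers - centers).max() < tol:
            centers = new_centers
            break
        centers = new_centers
    return centers, U


def align_centers(a, b):
    """Best-permutation match of two center sets; returns max coordinate gap."""
    c = len(a)
    return min(
        np.abs(a[list(perm)] - b).max() for perm in itertools.permutations(range(c))
    )


class TestMembershipUpdate:
    def test_hand_case_distances_one_and_two(self):
        # 1-D point with d1=1, d2=2 and m=2: u = (0.8, 0.2).
        U = _memberships_from_distances(np.array([[1.0, 4.0]]), m=2.0)
        assert U[0].tolist() == pytest.approx([0.8, 0.2], abs=1e-12)

    def test_equidistant_point_gets_uniform_membership(self):
        for c in (2, 3, 5):
            U = _memberships_from_distances(np.full((1, c), 2.5), m=2.0)
            assert U[0] == pytest.approx(np.full(c, 1 / c), abs=1e-12)

    def test_zero_distance_takes_full_membership(self):
        U = _memberships_from_distances(np.array([[0.0, 4.0]]), m=2.0)
        assert U[0].tolist() == [1.0, 0.0]

    def test_rows_always_stochastic(self, rng):
        d2 = rng.uniform(0.01, 5.0, size=(200, 4))
        U = _memberships_from_distances(d2, m=2.0)
        assert np.abs(U.sum(axis=1) - 1.0).max() < 1e-9
        assert (U >= 0).all() and (U <= 1).all()


class TestFCMFit:
    def test_memberships_and_objective_invariants(self, blobs300):
        X, _ = blobs300
        result = fcm_fit(X, FCMConfig(c=3, seed=0))
        assert np.abs(result.membership.sum(axis=1) - 1.0).max() < 1e-9
        J = result.objective_trajectory
        assert (np.diff(J) <= 1e-9).all()
        assert result.converged

    def test_planted_blobs_recovered(self, blobs300):
        X, labels = blobs300
        result = fcm_fit(X, FCMConfig(c=3, seed=0))
        assert adjusted_rand_score(labels, result.hard_labels) >= 0.95

    def test_matches_reference_implementation(self, blobs300):
        X, _ = blobs300
        ours = fcm_fit(X, FCMConfig(c=3, seed=1, tol=1e-12, max_iter=2000))
        ref_centers, _ = reference_fcm(X, c=3)
        assert align_centers(ours.centers, ref_centers) < 1e-6

    def test_small_fuzzifier_approaches_kmeans(self, blobs300):
        X, _ = blobs300
        result = fcm_fit(X, FCMConfig(c=3, m=1.05, seed=2))
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert adjusted_rand_score(km.labels_, result.hard_labels) == pytest.approx(1.0)
        assert align_centers(result.centers, km.cluster_centers_) < 1e-2

    def test_deterministic(self, blobs300):
        X, _ = blobs300
        a = fcm_fit(X, FCMConfig(c=3, seed=3))
        b = fcm_fit(X, FCMConfig(c=3, seed=3))
        assert np.array_equal(a.membership, b.membership)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError):
            fcm_fit(np.zeros((3, 2)) + np.arange(3)[:, None], FCMConfig(c=3))

    def test_identical_rows_rejected(self):
        with pytest.raises(DyadlinkError):
            fcm_fit(np.ones((10, 2)), FCMConfig(c=2))

    @pytest.mark.parametrize(
        "changes", [{"c": 1}, {"m": 1.0}, {"tol": 0.0}, {"max_iter": 0}]
    )
    def test_invalid_config_rejected(self, changes, blobs300):
        import dataclasses

        X, _ = blobs300
        with pytest.raises(ConfigError):
            fcm_fit(X, dataclasses.replace(FCMConfig(), **changes))


class TestSilhouetteCurve:
    def test_argmax_recovers_planted_three(self, blobs300):
        X, _ = blobs300
        curve = silhouette_curve(X, range(2, 7), FCMConfig(seed=0))
        assert [c for c, _ in curve] == [2, 3, 4, 5, 6]
        assert best_cluster_count(curve) == 3

    def test_deterministic(self, blobs300):
        X, _ = blobs300
        a = silhouette_curve(X, range(2, 5), FCMConfig(seed=1))
        b = silhouette_curve(X, range(2, 5), FCMConfig(seed=1))
        assert a == b

    def test_nan_entries_tolerated(self):
        curve = [(2, float("nan")), (3, 0.4), (4, 0.3)]
        assert best_cluster_count(curve) == 3

    def test_out_of_range_candidate_rejected(self, blobs300):
        X, _ = blobs300
        with pytest.raises(ConfigError):
            silhouette_curve(X[:5], [5], FCMConfig(seed=0))


class TestSleepQualityLabels:
    def _result_with_centers(self, centers, hard):
        centers = np.asarray(centers, dtype=float)
        n = len(hard)
        return FCMResult(
            membership=np.eye(centers.shape[0])[hard],
            centers=centers,
            objective_trajectory=np.array([1.0]),
            hard_labels=np.asarray(hard),
            n_iter=1,
            converged=True,
        )

    def test_ordering_by_sleep_time(self):
        result = self._result_with_centers(
            [[0.5, 0.3, 0.2], [0.9, 0.1, 0.2], [0.1, 0.8, 0.2]], [0, 1, 2]
        )
        labels = label_sleep_quality(result, SLEEP_FEATURES)
        assert labels.tolist() == ["moderate", "good", "poor"]

    def test_tie_broken_by_wake_times(self):
        result = self._result_with_centers(
            [[0.5, 0.6, 0.2], [0.5, 0.2, 0.2], [0.1, 0.9, 0.2]], [0, 1, 2]
        )
        labels = label_sleep_quality(result, SLEEP_FEATURES)
        assert labels.tolist() == ["moderate", "good", "poor"]

    def test_wrong_cluster_count_rejected(self, blobs300):
        X, _ = blobs300
        result = fcm_fit(X, FCMConfig(c=2, seed=0))
        with pytest.raises(ConfigError):
            label_sleep_quality(result, SLEEP_FEATURES)

    def test_generator_class_proportions_recovered(self):
        """FCM labelling of generated sleep blocks recovers the planted
        good/moderate/poor proportions within 0.08 on average."""
        recovered, planted = [], []
        code = {"good": 0, "moderate": 1, "poor": 2}
        for seed in range(10):
            df = generate_dataset(GeneratorConfig(n_dyads=378, seed=seed))
            X = apply_minmax(
                fit_minmax(df[list(SLEEP_FEATURES)]), df[list(SLEEP_FEATURES)]
            )
            result = fcm_fit(X, FCMConfig(c=3, seed=seed))
            labels = label_sleep_quality(result, SLEEP_FEATURES)
            got = np.array([code[l] for l in labels])
            recovered.append(np.bincount(got, minlength=3) / len(got))
            planted.append(
                np.bincount(df.attrs["sleep_quality_class"], minlength=3) / len(df)
            )
        gap = np.abs(np.mean(recovered, axis=0) - np.mean(planted, axis=0))
        assert gap.max() < 0.08
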