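import numpy as np
import pytest

from esoconvert.hlda import (
    HLDATransform,
    accumulate_stats,
    estimate_hlda,
    hlda_loglik,
    project,
)
from esoconvert.hlda import _objective_from, _loaded


def _per_frame_loglik(t, X, y, stats):
    """Brute-force oracle: evaluate the class-conditional Gaussian of every
    frame in the transformed space and sum."""
    theta, p = t.theta, t.p
    gm = stats.global_mean
    _, logdet = np.linalg.slogdet(theta)
    total = 0.0
    for ci, c in enumerate(stats.class_ids):
        sel = X[y == c]
        mean = np.concatenate([theta[:p] @ stats.means[ci], theta[p:] @ gm])
        var = np.concatenate(
            [
                np.einsum("ji,ik,jk->j", theta[:p], stats.covariances[ci], theta[:p]),
                np.einsum("ji,ik,jk->j", theta[p:], stats.total_covariance, theta[p:]),
            ]
        )
        Yp = sel @ theta.T
        ll = (
            logdet
            - 0.5 * np.sum(np.log(2 * np.pi * var))
            - 0.5 * np.sum((Yp - mean) ** 2 / var, axis=1)
        )
        total += ll.sum()
    return total


class TestAccumulateStats:
    def test_hand_built_two_class_moments(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 4.0], [6.0, 8.0]])
        y = np.array([0, 0, 1, 1])
        stats = accumulate_stats(X, y)
        np.testing.assert_allclose(stats.counts, [2, 2])
        np.testing.assert_allclose(stats.means[0], [1, 0])
        np.testing.assert_allclose(stats.means[1], [5, 6])
        np.testing.assert_allclose(stats.covariances[0], [[1, 0], [0, 0]])
        np.testing.assert_allclose(stats.covariances[1], [[1, 2], [2, 4]])
        np.testing.assert_allclose(stats.global_mean, [3, 3])

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            accumulate_stats(rng.standard_normal((10, 3)), np.zeros(10, int))

    def test_identical_classes_match_global_stats(self, rng):
        X = rng.standard_normal((40, 3))
        Xboth = np.vstack([X, X])
        y = np.array([0] * 40 + [1] * 40)
        stats = accumulate_stats(Xboth, y)
        np.testing.assert_allclose(stats.means[0], stats.means[1])
        np.testing.assert_allclose(stats.covariances[0], stats.total_covariance, atol=1e-10)

    def test_tiny_class_warns(self, rng):
        X = np.vstack([rng.standard_normal((2, 5)), rng.standard_normal((20, 5))])
        y = np.array([0] * 2 + [1] * 20)
        with pytest.warns(UserWarning, match="diagonally loaded"):
            accumulate_stats(X, y)


class TestEstimateHLDA:
    def test_objective_non_decreasing_per_sweep(self, rng):
        X = rng.standard_normal((400, 5)) + np.repeat(
            rng.standard_normal((4, 5)) * 3, 100, axis=0
        )
        y = np.repeat(np.arange(4), 100)
        stats = accumulate_stats(X, y)
        T = _loaded(stats.total_covariance)
        W = np.stack([_loaded(c) for c in stats.covariances])
        qs = []
        for iters in range(1, 6):
            t = estimate_hlda(stats, p=3, n_iters=iters, rel_tol=0.0)
            qs.append(_objective_from(t.theta, stats.counts, W, T, 3))
        for a, b in zip(qs, qs[1:]):
            assert b >= a - 1e-8 * max(1.0, abs(a))

    def test_saturated_model_keeps_full_information(self, rng):
        # p = n on homoscedastic classes: the transform is a bijection and
        # the objective cannot fall below the identity-model value
        X = rng.standard_normal((300, 3)) + np.repeat(
            [[0, 0, 0], [4, 0, 0], [0, 4, 0]], 100, axis=0
        )
        y = np.repeat(np.arange(3), 100)
        stats = accumulate_stats(X, y)
        t = estimate_hlda(stats, p=3, n_iters=30)
        from esoconvert.hlda import _objective

        assert abs(np.linalg.det(t.theta)) > 1e-8
        assert _objective(t.theta, stats, 3) >= _objective(np.eye(3), stats, 3) - 1e-6

    def test_retained_row_finds_discriminant_axis(self):
        rng = np.random.default_rng(42)
        n = 5000
        y = rng.integers(0, 2, n)
        X = np.column_stack(
            [np.where(y == 0, -5.0, 5.0) + rng.standard_normal(n), rng.standard_normal(n)]
        )
        stats = accumulate_stats(X, y)
        t = estimate_hlda(stats, p=1, n_iters=50)
        row = t.theta_p[0] / np.linalg.norm(t.theta_p[0])
        assert abs(row[0]) > 0.99

    def test_heteroscedastic_shared_mean_case(self):
        # classes share means but differ in variance along e1: mean-based
        # LDA is indifferent, the likelihood criterion is not
        rng = np.random.default_rng(43)
        n = 5000
        y = rng.integers(0, 2, n)
        X = np.column_stack(
            [np.where(y == 0, 1.0, 5.0) * rng.standard_normal(n), rng.standard_normal(n)]
        )
        stats = accumulate_stats(X, y)
        t = estimate_hlda(stats, p=1, n_iters=100)
        row = t.theta_p[0] / np.linalg.norm(t.theta_p[0])
        assert abs(row[0]) > 0.99

    def test_52_to_39_projection_shape(self, rng):
        X = rng.standard_normal((600, 52)) + np.repeat(
            rng.standard_normal((6, 52)), 100, axis=0
        )
        y = np.repeat(np.arange(6), 100)
        stats = accumulate_stats(X, y)
        t = estimate_hlda(stats, p=39, n_iters=3)
        out = project(t, X)
        assert out.shape == (600, 39)


class TestProject:
    def test_identity_transform(self, rng):
        t = HLDATransform(theta=np.eye(4), p=4)
        x = rng.standard_normal(4)
        np.testing.assert_allclose(project(t, x), x)

    def test_zero_vector(self, rng):
        t = HLDATransform(theta=rng.standard_normal((5, 5)), p=3)
        np.testing.assert_allclose(project(t, np.zeros(5)), np.zeros(3))

    def test_matches_direct_matrix_product(self, rng):
        theta = rng.standard_normal((6, 6))
        t = HLDATransform(theta=theta, p=4)
        x = rng.standard_normal(6)
        np.testing.assert_allclose(project(t, x), theta[:4] @ x)

    def test_dimension_mismatch_rejected(self, rng):
        t = HLDATransform(theta=np.eye(4), p=2)
        with pytest.raises(ValueError):
            project(t, np.zeros(5))


class TestLogLikelihood:
    def test_matches_per_frame_oracle(self, rng):
        X = rng.standard_normal((150, 3)) + np.repeat(
            [[0, 0, 0], [2, 1, 0], [0, 3, 1]], 50, axis=0
        )
        y = np.repeat(np.arange(3), 50)
        stats = accumulate_stats(X, y)
        t = estimate_hlda(stats, p=2, n_iters=20)
        assert hlda_loglik(t, stats) == pytest.approx(
            _per_frame_loglik(t, X, y, stats), rel=1e-10
        )

    def test_invariant_to_class_order(self, rng):
        X = rng.standard_normal((90, 3))
        y = np.repeat(np.arange(3), 30)
        t = estimate_hlda(accumulate_stats(X, y), p=2, n_iters=5)
        s1 = accumulate_stats(X, y)
        s2 = accumulate_stats(X[::-1], y[::-1])
        assert hlda_loglik(t, s1) == pytest.approx(hlda_loglik(t, s2), rel=1e-10)

    def test_random_perturbation_decreases_likelihood(self):
        rng = np.random.default_rng(44)
        X = rng.standard_normal((600, 4)) + np.repeat(
            rng.standard_normal((4, 4)) * 4, 150, axis=0
        )
        y = np.repeat(np.arange(4), 150)
        stats = accumulate_stats(X, y)
        t = estimate_hlda(stats, p=2, n_iters=60)
        converged = hlda_loglik(t, stats)
        worse = 0
        for _ in range(20):
            perturbed = HLDATransform(theta=rng.standard_normal((4, 4)), p=2)
            if hlda_loglik(perturbed, stats) < converged:
                worse += 1
        assert worse >= 19
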