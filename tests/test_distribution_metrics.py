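"""Frechet and kernel distances against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pytest

from synthmetrics import (
    FeatureMatrix,
    GaussianMoments,
    KernelConfig,
    frechet_distance,
    gaussian_moments,
    kid,
)


def brute_force_frechet(mu1, s1, mu2, s2):
    """Independent oracle: scipy's general matrix square root of S1 @ S2."""
    import scipy.linalg

    covmean = scipy.linalg.sqrtm(np.asarray(s1) @ np.asarray(s2))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    mu1, mu2 = np.atleast_1d(mu1), np.atleast_1d(mu2)
    return float(
        np.sum((mu1 - mu2) ** 2) + np.trace(s1) + np.trace(s2) - 2 * np.trace(covmean)
    )


def brute_force_mmd2(x, y, degree, scale, offset):
    """Term-by-term enumeration of the unbiased MMD^2 estimator."""
    def k(u, v):
        return (float(np.dot(u, v)) * scale + offset) ** degree

    m, n = len(x), len(y)
    xx = sum(k(x[i], x[j]) for i, j in itertools.permutations(range(m), 2))
    yy = sum(k(y[i], y[j]) for i, j in itertools.permutations(range(n), 2))
    xy = sum(k(x[i], y[j]) for i in range(m) for j in range(n))
    return xx / (m * (m - 1)) + yy / (n * (n - 1)) - 2 * xy / (m * n)


class TestGaussianMoments:
    def test_hand_computed_moments(self):
        f = FeatureMatrix(np.array([[0.0, 0.0], [2.0, 0.0]]))
        m = gaussian_moments(f)
        np.testing.assert_allclose(m.mean, [1.0, 0.0])
        np.testing.assert_allclose(m.covariance, [[2.0, 0.0], [0.0, 0.0]])

    def test_duplicated_dataset_same_moments(self, rng):
        x = rng.standard_normal((20, 3))
        m1 = gaussian_moments(FeatureMatrix(x))
        m2 = gaussian_moments(FeatureMatrix(np.vstack([x, x])))
        np.testing.assert_allclose(m1.mean, m2.mean)
        # duplication changes ddof weighting only: cov2 = cov1 * (2n-2)/(2n-1)... no:
        # sum of squared deviations doubles, divisor 2n-1 vs n-1
        np.testing.assert_allclose(m2.covariance, m1.covariance * (2 * 20 - 2) / (2 * 20 - 1))

    def test_large_sample_recovers_population_moments(self, rng):
        mu = np.array([1.0, -2.0])
        a = np.array([[2.0, 0.5], [0.0, 1.0]])
        sigma = a @ a.T
        x = rng.multivariate_normal(mu, sigma, size=40_000)
        m = gaussian_moments(FeatureMatrix(x))
        np.testing.assert_allclose(m.mean, mu, atol=0.05)
        np.testing.assert_allclose(m.covariance, sigma, atol=0.12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            gaussian_moments(FeatureMatrix(np.ones((1, 2))))


class TestFrechetDistance:
    def test_identical_moments_give_zero(self, rng):
        x = rng.standard_normal((30, 3))
        m = gaussian_moments(FeatureMatrix(x))
        assert frechet_distance(m, m) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize(
        "mu1, var1, mu2, var2, expected",
        [
            (0.0, 1.0, 1.0, 1.0, 1.0),  # (mu1-mu2)^2 + (s1-s2)^2
            (0.0, 1.0, 0.0, 4.0, 1.0),
            (2.0, 9.0, -1.0, 1.0, 13.0),
        ],
    )
    def test_univariate_closed_form(self, mu1, var1, mu2, var2, expected):
        a = GaussianMoments(np.array([mu1]), np.array([[var1]]), n=10)
        b = GaussianMoments(np.array([mu2]), np.array([[var2]]), n=10)
        assert frechet_distance(a, b) == pytest.approx(expected, abs=1e-8)

    def test_identity_covariance_closed_form(self):
        a = GaussianMoments(np.zeros(2), np.eye(2), n=10)
        b = GaussianMoments(np.array([3.0, 4.0]), np.eye(2), n=10)
        assert frechet_distance(a, b) == pytest.approx(25.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_psd_pairs_match_sqrtm_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a_ = rng.standard_normal((3, 3))
        b_ = rng.standard_normal((3, 3))
        s1, s2 = a_ @ a_.T + 0.1 * np.eye(3), b_ @ b_.T + 0.1 * np.eye(3)
        mu1, mu2 = rng.standard_normal(3), rng.standard_normal(3)
        ours = frechet_distance(
            GaussianMoments(mu1, s1, n=10), GaussianMoments(mu2, s2, n=10)
        )
        assert ours == pytest.approx(brute_force_frechet(mu1, s1, mu2, s2), abs=1e-8)

    def test_symmetry_and_rotation_invariance(self, rng):
        a_ = rng.standard_normal((3, 3))
        b_ = rng.standard_normal((3, 3))
        s1, s2 = a_ @ a_.T + 0.1 * np.eye(3), b_ @ b_.T + 0.1 * np.eye(3)
        mu1, mu2 = rng.standard_normal(3), rng.standard_normal(3)
        ma, mb = GaussianMoments(mu1, s1, n=5), GaussianMoments(mu2, s2, n=5)
        assert frechet_distance(ma, mb) == pytest.approx(frechet_distance(mb, ma), rel=1e-9)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        mar = GaussianMoments(q @ mu1, q @ s1 @ q.T, n=5)
        mbr = GaussianMoments(q @ mu2, q @ s2 @ q.T, n=5)
        assert frechet_distance(mar, mbr) == pytest.approx(
            frechet_distance(ma, mb), rel=1e-7, abs=1e-9
        )

    def test_non_psd_covariance_rejected(self):
        bad = GaussianMoments(np.zeros(2), np.array([[1.0, 0.0], [0.0, -1.0]]), n=5)
        good = GaussianMoments(np.zeros(2), np.eye(2), n=5)
        with pytest.raises(np.linalg.LinAlgError):
            frechet_distance(bad, good)


class TestKid:
    def test_identical_zero_vectors_give_zero(self):
        x = FeatureMatrix(np.zeros((2, 2)) + 0.0, source="real")
        y = FeatureMatrix(np.zeros((2, 2)), source="synthetic")
        cfg = KernelConfig(subset_size=2, n_subsets=1, seed=0)
        mean, std = kid(x, y, cfg)
        assert mean == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_sets_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xv = rng.standard_normal((4, 1))
        yv = rng.standard_normal((3, 1))
        # subsets of size 3 cover both sets entirely, so the estimate equals
        # the exhaustive enumeration regardless of the drawn permutation
        cfg_full = KernelConfig(subset_size=3, n_subsets=1, seed=seed)
        mean, _ = kid(
            FeatureMatrix(xv[:3]), FeatureMatrix(yv, source="synthetic"), cfg_full
        )
        expected = brute_force_mmd2(xv[:3], yv, degree=3, scale=1.0, offset=1.0)
        assert mean == pytest.approx(expected, abs=1e-10)

    def test_two_plus_two_point_hand_case(self):
        xv = np.array([[0.0], [1.0]])
        yv = np.array([[2.0], [3.0]])
        cfg = KernelConfig(subset_size=2, n_subsets=1, seed=0)
        mean, _ = kid(FeatureMatrix(xv), FeatureMatrix(yv, source="synthetic"), cfg)
        expected = brute_force_mmd2(xv, yv, degree=3, scale=1.0, offset=1.0)
        assert mean == pytest.approx(expected, abs=1e-10)

    def test_unbiasedness_near_zero_for_same_distribution(self, rng):
        x = FeatureMatrix(rng.standard_normal((400, 4)))
        y = FeatureMatrix(rng.standard_normal((400, 4)), source="synthetic")
        cfg = KernelConfig(subset_size=100, n_subsets=50, seed=9)
        mean, std = kid(x, y, cfg)
        se = std / np.sqrt(50)
        assert abs(mean) < 4 * max(se, 1e-4)

    def test_oversized_subset_rejected(self, gaussian_pair):
        x, y = gaussian_pair
        with pytest.raises(ValueError, match="subset_size"):
            kid(x, y, KernelConfig(subset_size=1000, n_subsets=2))

    def test_seeded_reproducibility(self, gaussian_pair):
        x, y = gaussian_pair
        cfg = KernelConfig(subset_size=30, n_subsets=10, seed=5)
        assert kid(x, y, cfg) == kid(x, y, cfg)
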