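"""GMM-EM: density, E/M steps, log-likelihood, fitting and recovery."""

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from lesionseg.gmm_em import (
    GmmModel,
    Responsibilities,
    e_step,
    gaussian_density,
    gmm_fit,
    log_likelihood,
    m_step,
    mixture_density,
)


def model_1d(mus, sigmas, weights, seed=0):
    K = len(mus)
    return GmmModel(
        weights=np.asarray(weights, dtype=float),
        means=np.asarray(mus, dtype=float).reshape(K, 1),
        covariances=np.asarray(sigmas, dtype=float).reshape(K, 1, 1),
        K=K, d=1, loglik_trace=[], seed=seed,
    )


# ------------------------------------------------------------------ density

def test_standard_normal_mode():
    val = gaussian_density(np.array([0.0]), np.array([0.0]), np.array([[1.0]]))
    assert val == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-12)


def test_bivariate_identity_mode():
    mu = np.zeros(2)
    val = gaussian_density(mu, mu, np.eye(2))
    assert val == pytest.approx(1.0 / (2 * np.pi), abs=1e-12)


def test_density_integrates_to_one():
    total, _ = integrate.quad(
        lambda x: gaussian_density(np.array([x]), np.array([0.0]), np.array([[1.0]])),
        -8, 8,
    )
    assert total == pytest.approx(1.0, abs=1e-6)


def test_non_spd_covariance_rejected():
    with pytest.raises(ValueError, match="positive definite"):
        gaussian_density(np.zeros(2), np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))


# ------------------------------------------------------------------ mixture

def test_single_component_mixture_equals_density():
    m = model_1d([0.7], [[2.0]], [1.0])
    x = np.array([1.3])
    assert mixture_density(x, m) == pytest.approx(
        gaussian_density(x, np.array([0.7]), np.array([[2.0]])), rel=1e-12
    )


def test_identical_components_convexity():
    m = model_1d([1.0, 1.0], [[1.5], [1.5]], [0.3, 0.7])
    x = np.array([0.2])
    assert mixture_density(x, m) == pytest.approx(
        gaussian_density(x, np.array([1.0]), np.array([[1.5]])), rel=1e-12
    )


def test_symmetric_midpoint_hand_value():
    # pi=(.5,.5), mu=(0,4), unit variances, x=2 -> phi(2)
    m = model_1d([0.0, 4.0], [[1.0], [1.0]], [0.5, 0.5])
    assert mixture_density(np.array([2.0]), m) == pytest.approx(
        sps.norm.pdf(2.0), rel=1e-12
    )


# ------------------------------------------------------------------- E step

def test_identical_components_give_half_responsibility():
    m = model_1d([1.0, 1.0], [[1.0], [1.0]], [0.5, 0.5])
    X = np.array([[0.0], [3.0], [-2.0]])
    r = e_step(X, m)
    np.testing.assert_allclose(r.gamma, 0.5, atol=1e-14)


def test_far_point_saturates():
    m = model_1d([0.0, 100.0], [[1.0], [1.0]], [0.5, 0.5])
    r = e_step(np.array([[-50.0]]), m)  # 50 sd into component 1's basin
    assert r.gamma[0, 0] >= 1 - 1e-10


def test_scalar_hand_responsibility():
    # mu=(0,4), unit variances, equal weights, x=1 -> phi(1)/(phi(1)+phi(3))
    m = model_1d([0.0, 4.0], [[1.0], [1.0]], [0.5, 0.5])
    r = e_step(np.array([[1.0]]), m)
    expected = sps.norm.pdf(1.0) / (sps.norm.pdf(1.0) + sps.norm.pdf(3.0))
    assert r.gamma[0, 0] == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.9820, abs=5e-5)


def test_responsibility_rows_sum_to_one():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(200, 3))
    m = GmmModel(
        weights=np.array([0.2, 0.5, 0.3]),
        means=rng.normal(size=(3, 3)),
        covariances=np.stack([np.eye(3)] * 3),
        K=3, d=3, loglik_trace=[],
    )
    r = e_step(X, m)
    np.testing.assert_allclose(r.gamma.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((r.gamma >= 0) & (r.gamma <= 1))
    assert r.effective_counts.sum() == pytest.approx(200.0, abs=1e-9)


# ------------------------------------------------------------------- M step

def test_hard_responsibilities_reduce_to_cluster_moments():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 2))
    labels = (np.arange(30) >= 18).astype(int)
    gamma = np.zeros((30, 2))
    gamma[np.arange(30), labels] = 1.0
    w, mu, cov = m_step(X, Responsibilities(gamma, gamma.sum(axis=0)), reg=0.0)
    for c in (0, 1):
        rows = X[labels == c]
        np.testing.assert_allclose(mu[c], rows.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(cov[c], np.cov(rows, rowvar=False, bias=True), rtol=1e-10)
        assert w[c] == pytest.approx(rows.shape[0] / 30)


def test_uniform_responsibilities_give_global_moments():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 2))
    gamma = np.full((40, 3), 1 / 3)
    w, mu, cov = m_step(X, Responsibilities(gamma, gamma.sum(axis=0)), reg=0.0)
    np.testing.assert_allclose(w, 1 / 3, atol=1e-12)
    for c in range(3):
        np.testing.assert_allclose(mu[c], X.mean(axis=0), rtol=1e-10)
        np.testing.assert_allclose(cov[c], np.cov(X, rowvar=False, bias=True), rtol=1e-9)


def test_weighted_moments_hand_case():
    # X={0,2}, gamma_1=(0.75, 0.25): mu=0.5, sigma^2=0.75
    X = np.array([[0.0], [2.0]])
    gamma = np.array([[0.75, 0.25], [0.25, 0.75]])
    w, mu, cov = m_step(X, Responsibilities(gamma, gamma.sum(axis=0)), reg=0.0)
    assert mu[0, 0] == pytest.approx(0.5, abs=1e-14)
    assert cov[0, 0, 0] == pytest.approx(0.75, abs=1e-14)


# ----------------------------------------------------------- log-likelihood

def test_single_row_at_mean_loglik():
    m = model_1d([0.0], [[1.0]], [1.0])
    assert log_likelihood(np.array([[0.0]]), m) == pytest.approx(
        np.log(1.0 / np.sqrt(2 * np.pi)), abs=1e-12
    )


def test_duplicating_rows_doubles_loglik():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(25, 2))
    m = GmmModel(
        weights=np.array([0.4, 0.6]), means=rng.normal(size=(2, 2)),
        covariances=np.stack([np.eye(2)] * 2), K=2, d=2, loglik_trace=[],
    )
    ll = log_likelihood(X, m)
    assert log_likelihood(np.vstack([X, X]), m) == pytest.approx(2 * ll, rel=1e-12)


def test_log_space_agrees_with_naive_evaluation():
    rng = np.random.default_rng(7)
    for _ in range(20):
        K, d, n = int(rng.integers(1, 4)), int(rng.integers(1, 3)), int(rng.integers(2, 8))
        X = rng.normal(size=(n, d))
        w = rng.dirichlet(np.ones(K))
        means = rng.normal(size=(K, d))
        covs = np.stack([np.eye(d) * rng.uniform(0.5, 2.0) for _ in range(K)])
        m = GmmModel(weights=w, means=means, covariances=covs, K=K, d=d, loglik_trace=[])
        naive = sum(
            np.log(sum(w[k] * gaussian_density(X[i], means[k], covs[k]) for k in range(K)))
            for i in range(n)
        )
        assert log_likelihood(X, m) == pytest.approx(naive, abs=1e-9)


# ---------------------------------------------------------------------- fit

def test_k1_recovers_sample_moments_in_one_step():
    rng = np.random.default_rng(9)
    X = rng.normal(2.0, 1.5, size=(500, 1))
    model, resp, labels = gmm_fit(X, K=1, seed=0, reg=0.0, max_iter=5)
    np.testing.assert_allclose(model.means[0], X.mean(axis=0), rtol=1e-10)
    np.testing.assert_allclose(model.covariances[0, 0, 0], X.var(), rtol=1e-10)
    assert model.weights[0] == pytest.approx(1.0, abs=1e-15)
    assert np.all(labels == 0)


def test_two_component_1d_recovery():
    rng = np.random.default_rng(123)
    n = 4000
    X = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(6, 1, n // 2)]).reshape(-1, 1)
    model, _, _ = gmm_fit(X, K=2, seed=0)
    mus = np.sort(model.means.ravel())
    assert abs(mus[0] - 0.0) < 0.15
    assert abs(mus[1] - 6.0) < 0.15


def test_loglik_trace_nondecreasing_and_weights_normalized():
    rng = np.random.default_rng(10)
    for seed in range(3):
        X = np.concatenate(
            [rng.normal(0, 1, (150, 2)), rng.normal(5, 1, (150, 2))]
        )
        model, resp, _ = gmm_fit(X, K=2, seed=seed, init="random")
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(resp.gamma.sum(axis=1), 1.0, atol=1e-12)


def test_fit_requires_more_rows_than_components():
    with pytest.raises(ValueError, match="more observations"):
        gmm_fit(np.zeros((3, 2)), K=3)
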