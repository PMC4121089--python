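"""Variational Laplace: exactness on conjugate models, complexity, ascent."""

import numpy as np
import pytest

from eigendcm.exceptions import ConvergenceError
from eigendcm.generative import FeatureErrorModel, ParameterIndex, Priors
from eigendcm.variational import (
    LOG2PI,
    VLOptions,
    fit_variational_laplace,
    free_energy,
)


class LinearToy:
    """y = X psi + e with Gaussian prior and unit-AR(0) error blocks.

    The Laplace bound is exact here: the log evidence is
    ln N(y; X m0, Sigma_e + X S0 X').
    """

    def __init__(self, rng, n=40, d=3, noise_sd=0.3, seed_beta=None):
        self.X = rng.standard_normal((n, d))
        self.true = rng.standard_normal(d)
        self.y = self.X @ self.true + noise_sd * rng.standard_normal(n)
        idx = ParameterIndex.__new__(ParameterIndex)
        idx.slices = {"theta": slice(0, d)}
        idx.size = d
        self.index = idx
        self.priors = Priors(idx, np.zeros(d), np.full(d, 4.0))
        self.error = FeatureErrorModel([n], rho=0.0)
        self.noise_var = noise_sd ** 2

    def predict(self, psi):
        return self.X @ psi

    def exact_log_evidence(self):
        n = self.y.size
        S = self.noise_var * np.eye(n) + self.X @ np.diag(
            self.priors.variance
        ) @ self.X.T
        sign, logdet = np.linalg.slogdet(S)
        r = self.y
        return float(
            -0.5 * n * LOG2PI - 0.5 * logdet - 0.5 * r @ np.linalg.solve(S, r)
        )

    def conjugate_posterior(self):
        prec = self.X.T @ self.X / self.noise_var + np.diag(
            1.0 / self.priors.variance
        )
        cov = np.linalg.inv(prec)
        mean = cov @ (self.X.T @ self.y / self.noise_var)
        return mean, cov


@pytest.fixture
def toy(rng):
    return LinearToy(rng)


def _beta_for(toy):
    """Fix the error log precision at the true noise level (not estimated)."""
    return -np.log(toy.noise_var)


class TestFreeEnergy:
    def test_matches_exact_log_evidence_on_linear_gaussian(self, toy):
        # evaluate at the conjugate posterior mode with the correct noise level
        mean, _ = toy.conjugate_posterior()

        def predict(psi):
            return toy.predict(psi)

        beta = _beta_for(toy)
        # fold exp(beta) into the error model by scaling Q
        em = FeatureErrorModel([toy.y.size], rho=0.0,
                               block_scales=[np.exp(-beta)])
        F = free_energy(mean, toy.y, toy.priors, predict, em)
        assert F == pytest.approx(toy.exact_log_evidence(), abs=1e-6)

    def test_zero_residual_at_prior_mean_leaves_only_occam_terms(self, rng):
        toy = LinearToy(rng)
        y0 = toy.predict(np.zeros(3))  # data equal to the prior-mean prediction
        em = FeatureErrorModel([toy.y.size], rho=0.0)
        F = free_energy(np.zeros(3), y0, toy.priors, toy.predict, em)
        # F = 1/2 ln|Pi_e| - 1/2 ln|M| + 1/2 ln|Pi_0| - (n/2) ln 2 pi
        M = toy.X.T @ toy.X + np.diag(1.0 / toy.priors.variance)
        expected = (
            0.0
            - 0.5 * np.linalg.slogdet(M)[1]
            + 0.5 * np.sum(np.log(1.0 / toy.priors.variance))
            - 0.5 * toy.y.size * LOG2PI
        )
        assert F == pytest.approx(expected, abs=1e-8)

    def test_duplicated_parameter_lowers_evidence(self, rng):
        toy = LinearToy(rng, d=2)
        mean, _ = toy.conjugate_posterior()
        em = FeatureErrorModel([toy.y.size], rho=0.0)
        F2 = free_energy(mean, toy.y, toy.priors, toy.predict, em)
        # same model with a perfectly correlated duplicate column
        X3 = np.column_stack([toy.X, toy.X[:, -1]])
        idx3 = ParameterIndex.__new__(ParameterIndex)
        idx3.slices = {"theta": slice(0, 3)}
        idx3.size = 3
        pri3 = Priors(idx3, np.zeros(3), np.full(3, 4.0))
        post3 = fit_variational_laplace(toy.y, lambda p: X3 @ p, pri3, em)
        assert post3.free_energy < F2

    def test_freeing_a_useless_parameter_lowers_evidence(self, rng):
        # data generated without the third regressor; its column is still
        # informative-looking, so freeing it costs Occam mass
        X = rng.standard_normal((40, 3))
        y = X[:, :2] @ np.array([1.0, -0.7]) + 0.3 * rng.standard_normal(40)
        idx = ParameterIndex.__new__(ParameterIndex)
        idx.slices = {"theta": slice(0, 3)}
        idx.size = 3
        em = FeatureErrorModel([y.size], rho=0.0)
        pri_free = Priors(idx, np.zeros(3), np.full(3, 4.0))
        pri_fixed = Priors(idx, np.zeros(3), np.array([4.0, 4.0, 0.0]))
        post_free = fit_variational_laplace(y, lambda p: X @ p, pri_free, em)
        post_fixed = fit_variational_laplace(y, lambda p: X @ p, pri_fixed, em)
        assert post_fixed.free_energy > post_free.free_energy


class TestFit:
    def test_posterior_matches_conjugate_solution(self, toy):
        beta = _beta_for(toy)
        em = FeatureErrorModel([toy.y.size], rho=0.0,
                               block_scales=[np.exp(-beta)])
        post = fit_variational_laplace(toy.y, toy.predict, toy.priors, em)
        mean, cov = toy.conjugate_posterior()
        assert np.abs(post.mean - mean).max() < 1e-4
        assert np.abs(post.covariance - cov).max() < 1e-6
        assert post.free_energy == pytest.approx(toy.exact_log_evidence(), abs=1e-4)

    def test_trace_is_monotone_over_accepted_steps(self, toy):
        em = FeatureErrorModel([toy.y.size], rho=0.0)
        post = fit_variational_laplace(toy.y, toy.predict, toy.priors, em)
        assert np.all(np.diff(post.trace) >= 0)
        assert post.converged

    def test_fixed_parameters_keep_prior_mean_and_zero_variance(self, rng):
        toy = LinearToy(rng)
        pri = Priors(toy.index, np.array([0.0, 0.7, 0.0]),
                     np.array([4.0, 0.0, 4.0]))
        em = FeatureErrorModel([toy.y.size], rho=0.0)
        post = fit_variational_laplace(toy.y, toy.predict, pri, em)
        assert post.mean[1] == 0.7
        assert np.all(post.covariance[1, :] == 0.0)

    def test_non_finite_prediction_raises_with_parameter_context(self, toy):
        em = FeatureErrorModel([toy.y.size], rho=0.0)

        def bad_predict(psi):
            return np.full(toy.y.size, np.inf)

        with pytest.raises(ConvergenceError, match="non-finite"):
            fit_variational_laplace(toy.y, bad_predict, toy.priors, em)

    def test_multi_start_returns_best_evidence(self, toy):
        em = FeatureErrorModel([toy.y.size], rho=0.0)
        p1 = fit_variational_laplace(toy.y, toy.predict, toy.priors, em,
                                     options=VLOptions(n_starts=3), seed=5)
        p0 = fit_variational_laplace(toy.y, toy.predict, toy.priors, em)
        assert p1.free_energy >= p0.free_energy - 1e-6


def test_self_consistency_on_spectral_model(rng):
    """Features generated by the forward model at known parameters are
    recovered: every unstable log time constant within 2 posterior sd."""
    from eigendcm.generative import SpectralForwardModel, default_priors
    from eigendcm.modes import order_and_sign
    from eigendcm.simulate import reference_covariance

    w, v = np.linalg.eigh(reference_covariance())
    modes = order_and_sign(w, v)[1]
    f = np.linspace(0.005, 0.125, 16)
    fwd = SpectralForwardModel(modes, f, np.arange(16) * 2.0, 2.0)
    pri = default_priors(6, 3, 1.0)
    truth = pri.mean.copy()
    s = pri.index.slices
    truth[s["tau"]][:3] = [1.6, 0.8, 0.2]
    g = fwd.predict_features(pri.index.unpack(truth))
    y = g + 1e-4 * np.abs(g).mean() * rng.standard_normal(g.size)
    em = FeatureErrorModel.from_data(fwd.feature_map, y)
    post = fit_variational_laplace(
        y, lambda p: fwd.predict_features(pri.index.unpack(p)), pri, em,
        beta_index=s["beta"].start,
    )
    tau_hat = post.mean[s["tau"]][:3]
    sd = np.sqrt(np.diag(post.covariance)[s["tau"]][:3])
    assert np.all(np.abs(tau_hat - [1.6, 0.8, 0.2]) < 2.0 * np.maximum(sd, 0.05))
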