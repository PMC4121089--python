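"""Eigenmode/Lyapunov algebra: composition, covariance, transfer functions."""

import numpy as np
import pytest
from scipy import integrate
from scipy.linalg import expm, solve_continuous_lyapunov, subspace_angles

from eigendcm.exceptions import ConditioningError, StabilityError, ValidationError
from eigendcm.modes import (
    EffectiveConnectivity,
    EigenSpec,
    FluctuationAmplitude,
    compose_jacobian,
    csd_hidden,
    effective_from_functional,
    exponents_from_spec,
    stationary_covariance,
    transfer_function,
)

from .conftest import random_orthonormal, random_stable_symmetric


def lyapunov_quadrature(A, sigma_v):
    """Oracle: S = int_0^inf exp(tA) Sigma_v exp(tA') dt by adaptive quadrature."""
    sv = sigma_v * np.eye(A.shape[0])

    def integrand(t):
        e = expm(t * A)
        return (e @ sv @ e.T).ravel()

    val, _ = integrate.quad_vec(integrand, 0.0, np.inf, epsabs=1e-12, epsrel=1e-10)
    return val.reshape(A.shape)


class TestComposeJacobian:
    def test_identity_modes(self):
        spec = EigenSpec(np.eye(2), [0.0], log_decay=np.log(2.0))
        A = compose_jacobian(spec).jacobian
        assert np.allclose(A, np.diag([-1.0, -2.0]), atol=1e-12)

    def test_hand_expansion_2x2(self):
        # lambda = (-1, -3) on the (1,1)/sqrt2 and (-1,1)/sqrt2 modes
        modes = np.array([[1.0, -1.0], [1.0, 1.0]]) / np.sqrt(2.0)
        spec = EigenSpec(modes, [0.0], log_decay=np.log(3.0))
        A = compose_jacobian(spec).jacobian
        assert np.allclose(A, [[-2.0, 1.0], [1.0, -2.0]], atol=1e-12)

    def test_eigendecomposition_round_trip(self, rng):
        q = random_orthonormal(rng, 5)
        spec = EigenSpec(q, [1.5, 0.5], log_decay=0.7)
        A = compose_jacobian(spec)
        w, v = A.eigendecompose()
        assert np.allclose(np.sort(w), np.sort(spec.exponents), atol=1e-10)
        # mode subspace of the unstable block is recovered
        ang = subspace_angles(v[:, :2], q[:, :2])
        assert np.max(ang) < 1e-8

    def test_symmetric_negative_definite(self, rng):
        q = random_orthonormal(rng, 4)
        A = compose_jacobian(EigenSpec(q, [2.0, 1.0], 1.0)).jacobian
        assert np.abs(A - A.T).max() < 1e-10
        assert np.linalg.eigvalsh(A).max() < 0

    def test_non_orthonormal_modes_rejected(self):
        bad = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValidationError, match="columns"):
            EigenSpec(bad, [0.0], 1.0)

    def test_degenerate_counts(self):
        # m = 0: scaled negative identity dynamics
        spec0 = EigenSpec(np.eye(3), [], log_decay=0.5)
        A0 = compose_jacobian(spec0).jacobian
        assert np.allclose(A0, -np.exp(0.5) * np.eye(3), atol=1e-12)
        # m = N: no stable block
        specN = EigenSpec(np.eye(3), [1.0, 0.5, 0.0], log_decay=1.0)
        assert np.allclose(
            np.sort(np.linalg.eigvalsh(compose_jacobian(specN).jacobian)),
            np.sort(-np.exp([-1.0, -0.5, 0.0])),
        )


class TestExponents:
    def test_printed_values(self):
        spec = EigenSpec(np.eye(2), [2.0], log_decay=1.0)
        lam, tc = exponents_from_spec(spec)
        # principal mode: time constant exp(2) = 7.4 s
        assert tc[0] == pytest.approx(7.389, abs=1e-3)
        # stable mode: exponent -exp(1) = -2.72 Hz, time constant 368 ms
        assert lam[1] == pytest.approx(-2.718, abs=1e-3)
        assert tc[1] == pytest.approx(0.368, abs=1e-3)

    def test_unit_time_constant(self):
        spec = EigenSpec(np.eye(1), [0.0], 1.0)
        lam, tc = exponents_from_spec(spec)
        assert lam[0] == pytest.approx(-1.0) and tc[0] == pytest.approx(1.0)


class TestStationaryCovariance:
    def test_scalar(self):
        A = EffectiveConnectivity([[-1.0]])
        S = stationary_covariance(A, FluctuationAmplitude(1.0))
        assert S[0, 0] == pytest.approx(1.0)

    def test_mode_variance_is_gamma_times_tau(self):
        # gamma_i = Gamma * tau_i: with tau = 2 and Gamma = 0.5, var = 0.5 e^2
        spec = EigenSpec(np.eye(2), [2.0], 0.0)
        A = compose_jacobian(spec)
        S = stationary_covariance(A, FluctuationAmplitude(0.5))
        assert S[0, 0] == pytest.approx(0.5 * np.exp(2.0), rel=1e-10)

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_matches_quadrature_oracle(self, rng, n):
        A = random_stable_symmetric(rng, n)
        gamma = 0.8
        S = stationary_covariance(EffectiveConnectivity(A), FluctuationAmplitude(gamma))
        oracle = lyapunov_quadrature(A, 2.0 * gamma)
        assert np.abs(S - oracle).max() / np.abs(oracle).max() < 1e-5

    def test_matches_scipy_lyapunov(self, rng):
        A = random_stable_symmetric(rng, 5)
        gamma = 1.3
        S = stationary_covariance(EffectiveConnectivity(A), FluctuationAmplitude(gamma))
        ref = solve_continuous_lyapunov(A, -2.0 * gamma * np.eye(5))
        assert np.allclose(S, ref, atol=1e-10)

    def test_shares_eigenmodes_with_connectivity(self, rng):
        """Functional and effective connectivity share eigenmodes."""
        q = random_orthonormal(rng, 4)
        spec = EigenSpec(q, [2.0, 1.0], 1.0)
        S = stationary_covariance(compose_jacobian(spec), FluctuationAmplitude(1.0))
        w, v = np.linalg.eigh(S)
        # unstable modes have distinct variances: compare leading subspaces
        ang = subspace_angles(v[:, -2:], q[:, :2])
        assert np.max(ang) < 1e-8

    def test_unstable_matrix_rejected(self):
        with pytest.raises(StabilityError):
            stationary_covariance(
                EffectiveConnectivity([[1.0, 0.0], [0.0, -1.0]]),
                FluctuationAmplitude(1.0),
            )


class TestEffectiveFromFunctional:
    def test_identity(self):
        A = effective_from_functional(np.eye(3), FluctuationAmplitude(1.0))
        assert np.allclose(A.jacobian, -np.eye(3))

    def test_explicit_2x2(self):
        S = np.array([[2.0, 1.0], [1.0, 2.0]])
        A = effective_from_functional(S, FluctuationAmplitude(1.0))
        expected = -(1.0 / 3.0) * np.array([[2.0, -1.0], [-1.0, 2.0]])
        assert np.allclose(A.jacobian, expected, atol=1e-12)

    def test_round_trip_with_stationary_covariance(self, rng):
        A = random_stable_symmetric(rng, 4)
        gamma = 0.7
        S = stationary_covariance(EffectiveConnectivity(A), FluctuationAmplitude(gamma))
        back = effective_from_functional(S, FluctuationAmplitude(gamma))
        assert np.abs(back.jacobian - A).max() < 1e-8

    def test_singular_covariance_rejected(self):
        S = np.ones((3, 3))
        with pytest.raises(ConditioningError):
            effective_from_functional(S, FluctuationAmplitude(1.0))


class TestTransferFunction:
    def test_dc_limit_is_minus_inverse(self, rng):
        A = random_stable_symmetric(rng, 3)
        K = transfer_function(EffectiveConnectivity(A), [1e-12])[0]
        assert np.allclose(K.real, -np.linalg.inv(A), atol=1e-8)

    def test_scalar_magnitude_at_unit_angular_frequency(self):
        A = EffectiveConnectivity([[-1.0]])
        K = transfer_function(A, [1.0 / (2.0 * np.pi)])  # omega = 1 rad/s
        assert abs(K[0, 0, 0]) == pytest.approx(1.0 / np.sqrt(2.0), rel=1e-12)

    def test_matches_fft_of_impulse_response(self, rng):
        A = random_stable_symmetric(rng, 3, lam_range=(-2.0, -0.5))
        dt, T = 0.01, 200.0
        t = np.arange(0, T, dt)
        E = expm(A * dt)
        h = np.empty((t.size, 3, 3))
        M = np.eye(3)
        for i in range(t.size):
            h[i] = M
            M = E @ M
        # trapezoid end-point correction for the t = 0 sample
        Hf = np.fft.rfft(h, axis=0) * dt - 0.5 * dt * h[0]
        fr = np.fft.rfftfreq(t.size, dt)
        pick = [5, 20, 100]
        K = transfer_function(EffectiveConnectivity(A), fr[pick])
        assert np.abs(K - Hf[pick]).max() < 1e-4

    def test_hermitian_across_sign_of_frequency(self, rng):
        A = EffectiveConnectivity(random_stable_symmetric(rng, 2))
        Kp = transfer_function(A, [0.1])
        Km = transfer_function(A, [-0.1])
        assert np.allclose(Km, Kp.conj(), atol=1e-12)


class TestCsdHidden:
    def test_scalar_lorentzian_peak(self):
        A = EffectiveConnectivity([[-1.0]])
        g = csd_hidden(A, 1.0, [1e-12])
        assert g[0, 0, 0].real == pytest.approx(1.0, abs=1e-9)

    def test_parseval_matches_stationary_variance(self, rng):
        A = random_stable_symmetric(rng, 3, lam_range=(-3.0, -1.0))
        gamma = 0.5
        f = np.linspace(1e-4, 40.0, 20000)
        g = csd_hidden(EffectiveConnectivity(A), 2.0 * gamma, f)
        var = 2.0 * np.trapezoid(np.diagonal(g, axis1=1, axis2=2).real, f, axis=0)
        S = stationary_covariance(EffectiveConnectivity(A), FluctuationAmplitude(gamma))
        assert np.abs(var - np.diag(S)).max() / np.diag(S).max() < 0.01

    def test_hermitian_psd(self, rng):
        A = EffectiveConnectivity(random_stable_symmetric(rng, 3))
        g = csd_hidden(A, 1.0, np.linspace(0.01, 1.0, 16))
        assert np.abs(g - g.conj().transpose(0, 2, 1)).max() < 1e-10
        for gk in g:
            assert np.linalg.eigvalsh(gk).min() > -1e-12

    def test_shape_mismatch_rejected(self, rng):
        A = EffectiveConnectivity(random_stable_symmetric(rng, 3))
        with pytest.raises(ValidationError):
            csd_hidden(A, np.ones((5, 2)), np.linspace(0.01, 0.1, 5))
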