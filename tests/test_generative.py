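"""Spectral forward model: parameter vector, features, error model, predictions."""

import numpy as np
import pytest

from eigendcm.exceptions import ValidationError
from eigendcm.generative import (
    FeatureErrorModel,
    FeatureMap,
    ParameterIndex,
    SpectralForwardModel,
    ar1_correlation,
    ar1_precision,
    default_priors,
    fluctuation_spectrum,
    sampling_error_covariance,
)
from eigendcm.modes import EffectiveConnectivity, csd_hidden
from eigendcm.simulate import reference_covariance
from eigendcm.modes import order_and_sign

N = 6
F_GRID = np.linspace(0.005, 0.125, 16)
LAGS = np.arange(16) * 2.0


@pytest.fixture(scope="module")
def modes():
    w, v = np.linalg.eigh(reference_covariance())
    return order_and_sign(w, v)[1]


@pytest.fixture(scope="module")
def forward(modes):
    return SpectralForwardModel(modes, F_GRID, LAGS, 2.0)


@pytest.fixture(scope="module")
def priors():
    return default_priors(N, 3, 1.0)


class TestFluctuationSpectrum:
    def test_flat_at_zero_exponent(self):
        g = fluctuation_spectrum(0.3, 0.0, F_GRID)
        assert np.allclose(g, np.exp(0.3))

    def test_amplitude_doubles_spectrum(self):
        g1 = fluctuation_spectrum(0.1, 0.7, F_GRID)
        g2 = fluctuation_spectrum(0.1 + np.log(2.0), 0.7, F_GRID)
        assert np.allclose(g2, 2.0 * g1)

    def test_loglog_slope_equals_minus_exponent(self):
        g = fluctuation_spectrum(0.0, 1.3, F_GRID)
        slope = np.polyfit(np.log(F_GRID), np.log(g), 1)[0]
        assert slope == pytest.approx(-1.3, abs=1e-10)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValidationError):
            fluctuation_spectrum(0.0, 1.0, [0.0, 0.1])


class TestParameterIndex:
    def test_pack_unpack_round_trip(self, rng):
        idx = ParameterIndex(4, with_input=True)
        v = rng.standard_normal(idx.size)
        assert np.allclose(idx.pack(idx.unpack(v)), v)

    def test_priors_follow_table(self, priors):
        s = priors.index.slices
        assert np.allclose(priors.variance[s["tau"]][:3], 1.0)
        assert np.allclose(priors.variance[s["tau"]][3:], 0.0)
        assert np.allclose(priors.mean[s["tau"]][3:], -1.0)
        assert np.allclose(priors.variance[s["neuronal_amp"]], 1.0 / 64.0)
        assert priors.mean[s["beta"]][0] == 4.0
        assert priors.variance[s["beta"]][0] == 1.0 / 64.0
        assert np.allclose(priors.variance[s["log_decay_scale"]], np.exp(-6.0))

    def test_only_m_tau_parameters_are_free(self, priors):
        """Stable modes are pinned: 3 of 6 tau entries carry free mass."""
        s = priors.index.slices["tau"]
        assert int(priors.free[s].sum()) == 3


class TestFeatureMap:
    def test_round_trip(self, rng):
        fm = FeatureMap(3, 5, 4)
        csd = rng.standard_normal((5, 3, 3)) + 1j * rng.standard_normal((5, 3, 3))
        csd = 0.5 * (csd + csd.conj().transpose(0, 2, 1))
        ccf = rng.standard_normal((4, 3, 3))
        vec = fm.pack(csd, ccf)
        csd2, ccf2 = fm.unpack(vec)
        assert np.abs(csd2 - csd).max() < 1e-12
        assert np.abs(ccf2 - ccf).max() < 1e-12

    def test_hand_counted_length(self):
        # N=2, 3 frequencies, 3 lags: csd re+im = 3*2*(2+1) = 18; ccf = 3*4 = 12
        fm = FeatureMap(2, 3, 3)
        assert fm.size == 18 + 12
        assert fm.n_csd_features == 18

    def test_diagonal_imaginary_features_are_zero(self, rng):
        fm = FeatureMap(2, 3, 2)
        csd = np.ones((3, 2, 2), dtype=complex)
        vec = fm.pack(csd, np.zeros((2, 2, 2)))
        p = len(fm.pairs)
        im = vec[p * 3: 2 * p * 3].reshape(p, 3)
        diag_rows = [k for k, (i, j) in enumerate(fm.pairs) if i == j]
        assert np.all(im[diag_rows] == 0.0)


class TestErrorModel:
    def test_beta_zero_recovers_template(self):
        em = FeatureErrorModel([3, 2], rho=0.5)
        q = em.covariance(0.0)
        assert np.allclose(q[:3, :3], ar1_correlation(3, 0.5))
        assert np.allclose(q[3:, 3:], ar1_correlation(2, 0.5))
        assert np.all(q[:3, 3:] == 0)

    def test_precision_scales_with_beta(self):
        em = FeatureErrorModel([4], rho=0.5)
        assert np.allclose(
            em.covariance(np.log(10.0)) * 10.0, em.covariance(0.0)
        )

    def test_ar1_precision_is_tridiagonal_inverse(self):
        for n, rho in ((5, 0.5), (8, 0.3)):
            P = ar1_precision(n, rho).toarray()
            assert np.allclose(P, np.linalg.inv(ar1_correlation(n, rho)), atol=1e-10)
            off = np.triu(np.abs(P), 2)
            assert off.max() < 1e-12

    def test_sampling_error_covariance_function(self):
        q = ar1_correlation(4, 0.5)
        assert np.allclose(sampling_error_covariance(0.0, q), q)
        assert np.allclose(
            sampling_error_covariance(np.log(10.0), q), q / 10.0
        )
        with pytest.raises(ValidationError):
            sampling_error_covariance(0.0, np.zeros((2, 2)))

    def test_data_scaled_blocks_track_magnitude(self, rng):
        fm = FeatureMap(2, 4, 3)
        y = rng.standard_normal(fm.size)
        y[:4] *= 50.0  # first block much larger
        em = FeatureErrorModel.from_data(fm, y)
        assert em.block_scales[0] > 100 * em.block_scales[1]


class TestPredictCsd:
    def test_silent_neurons_leave_noise_spectrum(self, forward, priors):
        psi = priors.index.unpack(priors.mean)
        from dataclasses import replace

        psi_silent = replace(psi, neuronal_amp=psi.neuronal_amp - 40.0)
        pred = forward.predict_csd(psi_silent)
        gw = fluctuation_spectrum(
            psi.noise_amp, psi.noise_exponent, F_GRID, scale=forward.noise_scale
        )
        diag = np.diagonal(pred.csd, axis1=1, axis2=2).real
        assert np.allclose(diag, gw, rtol=1e-6)
        off = pred.csd.copy()
        for i in range(N):
            off[:, i, i] = 0.0
        assert np.abs(off).max() < 1e-12

    def test_identity_hemodynamics_reduces_to_hidden_csd(self, modes, priors):
        fwd = SpectralForwardModel(
            modes, F_GRID, LAGS, 2.0, identity_hemodynamics=True
        )
        psi = priors.index.unpack(priors.mean)
        from dataclasses import replace

        psi = replace(psi, noise_amp=psi.noise_amp - 40.0)  # silence the noise
        pred = fwd.predict_csd(psi)
        lam = -np.exp(-psi.tau)
        A = EffectiveConnectivity((modes * lam) @ modes.T)
        gv = fluctuation_spectrum(
            psi.neuronal_amp, psi.neuronal_exponent, F_GRID, scale=fwd.neuronal_scale
        )
        gx = csd_hidden(A, gv, F_GRID)
        assert np.abs(pred.csd - gx).max() < 1e-10

    def test_hermitian_psd_for_prior_draws(self, forward, priors, rng):
        """Predicted cross spectra stay Hermitian PSD over the prior."""
        sd = np.sqrt(priors.variance)
        for _ in range(10):
            v = priors.mean + sd * rng.standard_normal(priors.mean.size)
            pred = forward.predict_csd(priors.index.unpack(v))
            herm = np.abs(
                pred.csd - pred.csd.conj().transpose(0, 2, 1)
            ).max()
            assert herm < 1e-8 * max(1.0, np.abs(pred.csd).max())
            for gk in pred.csd:
                wmin = np.linalg.eigvalsh(gk).min()
                assert wmin > -1e-10 * np.abs(gk).max()

    def test_slower_mode_gains_low_frequency_power(self, forward, priors, modes):
        """Raising an unstable mode's log time constant raises its projected
        low-frequency power (monotonicity of the Lorentzian corner)."""
        base = priors.index.unpack(priors.mean)
        lowf = F_GRID < 0.02

        def mode_power(psi, k):
            g = forward.predict_csd(psi).csd
            u = modes[:, k]
            proj = np.einsum("i,fij,j->f", u, g, u).real
            return proj[lowf].sum()

        from dataclasses import replace

        for k in range(3):
            tau_hi = base.tau.copy()
            tau_hi[k] += 0.5
            psi_hi = replace(base, tau=tau_hi)
            assert mode_power(psi_hi, k) > mode_power(base, k)

    def test_observation_noise_is_identifiable_in_the_prediction(
        self, forward, priors
    ):
        base = priors.index.unpack(priors.mean)
        from dataclasses import replace

        bumped = replace(base, noise_amp=base.noise_amp + 0.25)
        d = np.abs(
            forward.predict_features(bumped) - forward.predict_features(base)
        ).max()
        assert d > 1e-4

    def test_exogenous_input_adds_rank_one_power(self, modes, priors):
        gu = np.full(F_GRID.size, 0.01)
        fwd = SpectralForwardModel(modes, F_GRID, LAGS, 2.0, input_spectrum=gu)
        pri = default_priors(N, 3, 1.0, with_input=True)
        psi0 = pri.index.unpack(pri.mean)  # C = 0: no input contribution
        from dataclasses import replace

        psi1 = replace(psi0, input_scaling=np.ones(N))
        p0 = fwd.predict_csd(psi0).csd
        p1 = fwd.predict_csd(psi1).csd
        diag0 = np.diagonal(p0, axis1=1, axis2=2).real
        diag1 = np.diagonal(p1, axis1=1, axis2=2).real
        assert np.all(diag1 >= diag0 - 1e-14)
        assert diag1.sum() > diag0.sum()

    def test_empty_frequency_grid_rejected(self, modes):
        with pytest.raises(ValidationError):
            SpectralForwardModel(modes, np.array([]), LAGS, 2.0)


def test_prediction_matches_long_nonlinear_simulation(modes):
    """Forward spectra at prior means agree with Welch estimates of a long
    balloon-model simulation driven at the matching white-noise amplitudes
    (band-averaged power within 10%)."""
    from eigendcm.features import detrend_standardise, welch_csd
    from eigendcm.generative import NEURONAL_DENSITY_SCALE, NOISE_DENSITY_SCALE
    from eigendcm.hemodynamics import HemodynamicParams
    from eigendcm.modes import EigenSpec
    from eigendcm.simulate import DRIVE_EFFICACY, simulate_ar1, simulate_bold

    T, dt = 4096, 2.0
    spec = EigenSpec(modes, np.zeros(3), 1.0)
    rng = np.random.default_rng(42)
    sd_neuronal = np.sqrt(NEURONAL_DENSITY_SCALE / dt) / DRIVE_EFFICACY
    sd_noise = np.sqrt(NOISE_DENSITY_SCALE / dt)
    neuronal = simulate_ar1(N, T, 0.0, sd_neuronal, rng)
    noise = simulate_ar1(N, T, 0.0, sd_noise, rng)
    ts = simulate_bold(spec, HemodynamicParams(np.zeros(N), np.zeros(N)), neuronal,
                       noise, dt)
    f = np.linspace(1.0 / 1024.0, 0.125, 32)
    fwd = SpectralForwardModel(modes, f, np.arange(32) * dt, dt)
    pri = default_priors(N, 3, 1.0)
    pred = fwd.predict_csd(pri.index.unpack(pri.mean))
    S = welch_csd(detrend_standardise(ts.values), dt, f, nperseg=512)
    band_data = np.trapezoid(np.diagonal(S, axis1=1, axis2=2).real, f, axis=0)
    band_pred = np.trapezoid(
        np.diagonal(pred.csd, axis1=1, axis2=2).real, f, axis=0
    )
    rel = np.abs(band_data - band_pred) / band_pred
    assert rel.max() < 0.10
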