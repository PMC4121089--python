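"""Spectral generative model: parameters -> predicted cross spectra.

Given fixed eigenmodes ``mu`` (taken from the functional connectivity of the
data) the model predicts observed complex cross spectra as

    g_y(w) = H(w) K(w) [g_v(w) + C g_u(w) C'] K(w)* H(w)* + g_w(w)

where ``K`` is the neuronal transfer function built from the mode time
constants, ``H`` is the diagonal per-region haemodynamic transfer function,
``g_v``/``g_w`` are power-law spectra of neuronal fluctuations and
observation noise, and the optional ``C g_u C'`` term injects the spectrum of
exogenous experimental input.  Cross-covariance functions derived from the
predicted spectra are appended as data features.

The parameter set psi = {alpha, beta, tau, theta} comprises fluctuation and
noise amplitudes/exponents (alpha), the log precision of spectral sampling
error (beta), mode log time constants (tau) and haemodynamic scales (theta).
Stable modes are handled by fixing their tau entries at ``-eta`` with zero
prior variance, so only the unstable time constants are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

from .exceptions import ValidationError
from .hemodynamics import HemodynamicParams, hemodynamic_transfer
from .spectra import CrossSpectralData, CsdCcfTransform

__all__ = [
    "NEURONAL_DENSITY_SCALE",
    "NOISE_DENSITY_SCALE",
    "ParameterVector",
    "ParameterIndex",
    "Priors",
    "default_priors",
    "fluctuation_spectrum",
    "FeatureMap",
    "feature_vector",
    "ar1_correlation",
    "ar1_precision",
    "FeatureErrorModel",
    "sampling_error_covariance",
    "SpectralForwardModel",
]


#: reference spectral densities (signal^2/Hz) multiplying the power-law
#: fluctuation and noise spectra.  Log amplitudes have tight priors
#: (variance 1/64), so these constants anchor "amplitude parameter = 0" at
#: the magnitudes typical of percent-BOLD resting-state data under the
#: default study conditions: endogenous drive with the low-frequency density
#: of an AR(1) process of sd 1/4 (coefficient 1/2, 2 s bins) scaled by the
#: conventional 1/16 input efficacy, and observation noise of sd 1/8.
NEURONAL_DENSITY_SCALE = 1.5e-3
NOISE_DENSITY_SCALE = 9.4e-2


@dataclass(frozen=True)
class ParameterVector:
    """The DCM parameters psi = {alpha, beta, tau, theta}.

    ``tau`` has one entry per mode; trailing (stable) entries are normally
    pinned at ``-eta`` by a zero-variance prior.  Amplitudes are per-region
    log scales; the power-law exponents are shared across regions (one for
    neuronal fluctuations, one for observation noise).
    """

    tau: np.ndarray
    neuronal_amp: np.ndarray
    neuronal_exponent: float
    noise_amp: np.ndarray
    noise_exponent: float
    beta: float
    hemo: HemodynamicParams
    input_scaling: np.ndarray = None

    def __post_init__(self):
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        na = np.atleast_1d(np.asarray(self.neuronal_amp, dtype=float))
        wa = np.atleast_1d(np.asarray(self.noise_amp, dtype=float))
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "neuronal_amp", na)
        object.__setattr__(self, "noise_amp", wa)
        if self.input_scaling is not None:
            object.__setattr__(
                self, "input_scaling",
                np.atleast_1d(np.asarray(self.input_scaling, dtype=float)),
            )
        for arr in (tau, na, wa):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("parameter vector contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.neuronal_amp.size


class ParameterIndex:
    """Stable flattening of :class:`ParameterVector` to a single vector."""

    def __init__(self, n_nodes: int, with_input: bool = False):
        self.n_nodes = n_nodes
        self.with_input = with_input
        n = n_nodes
        names = [
            ("tau", n),
            ("neuronal_amp", n),
            ("neuronal_exponent", 1),
            ("noise_amp", n),
            ("noise_exponent", 1),
            ("beta", 1),
            ("log_decay_scale", n),
            ("log_transit_scale", n),
        ]
        if with_input:
            names.append(("input_scaling", n))
        self.slices = {}
        start = 0
        for name, size in names:
            self.slices[name] = slice(start, start + size)
            start += size
        self.size = start

    def pack(self, pv: ParameterVector) -> np.ndarray:
        out = np.empty(self.size)
        s = self.slices
        out[s["tau"]] = pv.tau
        out[s["neuronal_amp"]] = pv.neuronal_amp
        out[s["neuronal_exponent"]] = pv.neuronal_exponent
        out[s["noise_amp"]] = pv.noise_amp
        out[s["noise_exponent"]] = pv.noise_exponent
        out[s["beta"]] = pv.beta
        out[s["log_decay_scale"]] = pv.hemo.log_decay_scale
        out[s["log_transit_scale"]] = pv.hemo.log_transit_scale
        if self.with_input:
            out[s["input_scaling"]] = pv.input_scaling
        return out

    def unpack(self, vector: np.ndarray) -> ParameterVector:
        v = np.asarray(vector, dtype=float)
        if v.size != self.size:
            raise ValidationError(f"expected vector of length {self.size}, got {v.size}")
        s = self.slices
        return ParameterVector(
            tau=v[s["tau"]],
            neuronal_amp=v[s["neuronal_amp"]],
            neuronal_exponent=float(v[s["neuronal_exponent"]][0]),
            noise_amp=v[s["noise_amp"]],
            noise_exponent=float(v[s["noise_exponent"]][0]),
            beta=float(v[s["beta"]][0]),
            hemo=HemodynamicParams(v[s["log_decay_scale"]], v[s["log_transit_scale"]]),
            input_scaling=v[s["input_scaling"]] if self.with_input else None,
        )


@dataclass(frozen=True)
class Priors:
    """Gaussian priors (mean and diagonal variance) over the flat vector."""

    index: ParameterIndex
    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mean, dtype=float)
        v = np.asarray(self.variance, dtype=float)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "variance", v)
        if m.size != self.index.size or v.size != self.index.size:
            raise ValidationError("prior vectors do not match the parameter index")
        if np.any(v < 0):
            raise ValidationError("prior variances must be non-negative")

    @property
    def free(self) -> np.ndarray:
        """Boolean mask of parameters with non-zero prior variance."""
        return self.variance > 0

    def with_values(self, name: str, mean=None, variance=None) -> "Priors":
        """Return priors with one named block overridden."""
        m = self.mean.copy()
        v = self.variance.copy()
        sl = self.index.slices[name]
        if mean is not None:
            m[sl] = mean
        if variance is not None:
            v[sl] = variance
        return replace(self, mean=m, variance=v)


def default_priors(
    n_nodes: int,
    n_unstable: int,
    log_decay: float,
    with_input: bool = False,
) -> Priors:
    """Priors used throughout: tau ~ N(0,1) for unstable modes (stable modes
    pinned at ``-eta`` with zero variance), alpha ~ N(0, 1/64),
    beta ~ N(4, 1/64), C ~ N(0, 1), ln a, ln b ~ N(0, exp(-6))."""
    if not 0 <= n_unstable <= n_nodes:
        raise ValidationError("n_unstable must lie in [0, n_nodes]")
    idx = ParameterIndex(n_nodes, with_input)
    mean = np.zeros(idx.size)
    var = np.zeros(idx.size)
    s = idx.slices
    tau_mean = np.full(n_nodes, -float(log_decay))
    tau_var = np.zeros(n_nodes)
    tau_mean[:n_unstable] = 0.0
    tau_var[:n_unstable] = 1.0
    mean[s["tau"]], var[s["tau"]] = tau_mean, tau_var
    for name in ("neuronal_amp", "neuronal_exponent", "noise_amp", "noise_exponent"):
        var[s[name]] = 1.0 / 64.0
    mean[s["beta"]] = 4.0
    var[s["beta"]] = 1.0 / 64.0
    var[s["log_decay_scale"]] = np.exp(-6.0)
    var[s["log_transit_scale"]] = np.exp(-6.0)
    if with_input:
        var[s["input_scaling"]] = 1.0
    return Priors(idx, mean, var)


def fluctuation_spectrum(
    amplitude: np.ndarray,
    exponent: float,
    frequencies: np.ndarray,
    scale: float = 1.0,
) -> np.ndarray:
    """Power-law spectral density ``scale exp(amp) (f / 1 Hz)^(-exponent)``.

    ``amplitude`` may be scalar or per-region; returns (n_freq,) or
    (n_freq, n_regions).  ``scale`` is the fixed reference density anchoring
    ``amp = 0`` (see :data:`NEURONAL_DENSITY_SCALE`).
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(f <= 0):
        raise ValidationError("frequencies must be positive for power-law spectra")
    amp = np.asarray(amplitude, dtype=float)
    base = float(scale) * f ** (-float(exponent))
    if amp.ndim == 0:
        return np.exp(amp) * base
    return np.exp(amp)[None, :] * base[:, None]


class FeatureMap:
    """Deterministic ordering of csd/ccf entries into a real feature vector.

    Layout: real parts of the csd upper triangle (incl. diagonal), one
    contiguous run of frequencies per pair; then the matching imaginary
    parts (identically zero on the diagonal); then the full ccf matrix, one
    run of lags per ordered pair (both orderings are kept because
    ``ccf_ij(l) = ccf_ji(-l)`` carries the negative-lag information).

    Spectral densities are tabulated per angular frequency (the per-Hz
    arrays are divided by 2 pi), which puts csd and ccf features on a
    common magnitude scale.
    """

    CSD_SCALE = 1.0 / (2.0 * np.pi)

    def __init__(self, n_nodes: int, n_freq: int, n_lag: int):
        self.n_nodes = n_nodes
        self.n_freq = n_freq
        self.n_lag = n_lag
        self.pairs = [(i, j) for i in range(n_nodes) for j in range(i, n_nodes)]
        self.ordered_pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes)]
        p = len(self.pairs)
        self.n_csd_features = 2 * p * n_freq
        self.n_ccf_features = len(self.ordered_pairs) * n_lag
        self.size = self.n_csd_features + self.n_ccf_features
        # block structure: (length, is_csd_block) for the error covariance
        self.blocks = (
            [n_freq] * (2 * p) + [n_lag] * len(self.ordered_pairs)
        )
        ii = [p_[0] for p_ in self.pairs]
        jj = [p_[1] for p_ in self.pairs]
        self._tri = (ii, jj)

    def pack(self, csd: np.ndarray, ccf: np.ndarray) -> np.ndarray:
        """Flatten (n_freq, N, N) csd and (n_lag, N, N) ccf to features."""
        ii, jj = self._tri
        tri = self.CSD_SCALE * csd[:, ii, jj]  # (n_freq, n_pairs)
        re = tri.real.T.reshape(-1)
        im = tri.imag.T.reshape(-1)
        cc = ccf.reshape(self.n_lag, -1).T.reshape(-1)
        return np.concatenate([re, im, cc])

    def unpack(self, vector: np.ndarray):
        """Invert :meth:`pack`; returns (csd, ccf)."""
        v = np.asarray(vector, dtype=float)
        if v.size != self.size:
            raise ValidationError(f"expected {self.size} features, got {v.size}")
        p = len(self.pairs)
        K, L, n = self.n_freq, self.n_lag, self.n_nodes
        re = v[: p * K].reshape(p, K).T
        im = v[p * K: 2 * p * K].reshape(p, K).T
        cc = v[2 * p * K:].reshape(n * n, L).T.reshape(L, n, n)
        csd = np.zeros((K, n, n), dtype=complex)
        ii, jj = self._tri
        csd[:, ii, jj] = (re + 1j * im) / self.CSD_SCALE
        csd[:, jj, ii] = (re - 1j * im) / self.CSD_SCALE
        return csd, cc


def feature_vector(data: CrossSpectralData):
    """Feature vector and index map of a :class:`CrossSpectralData`."""
    fmap = FeatureMap(data.n_nodes, data.frequencies.size, data.lags.size)
    return fmap.pack(data.csd, data.ccf), fmap


def ar1_correlation(n: int, rho: float = 0.5) -> np.ndarray:
    """Unit-variance AR(1) correlation matrix ``rho^|i-j|``."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def ar1_precision(n: int, rho: float = 0.5) -> sparse.csr_matrix:
    """Tridiagonal inverse of :func:`ar1_correlation` (closed form)."""
    if n == 1:
        return sparse.csr_matrix(np.array([[1.0]]))
    c = 1.0 / (1.0 - rho ** 2)
    main = np.full(n, (1.0 + rho ** 2) * c)
    main[0] = main[-1] = c
    off = np.full(n - 1, -rho * c)
    return sparse.diags([off, main, off], [-1, 0, 1], format="csr")


class FeatureErrorModel:
    """Sampling-error covariance ``exp(-beta) Q`` over the feature vector.

    ``Q`` is block diagonal with AR(1) correlation (rho = 1/2) over adjacent
    frequencies or lags within each (pair, part) feature block; its precision
    is tridiagonal within blocks and precomputed sparse.  Each block may
    carry a fixed variance scale: the sampling error of spectral estimates
    grows with the magnitude of the spectrum itself, so
    :meth:`from_data` sets the block scales from the observed features
    (approximately constant *relative* error, with a floor for
    near-zero blocks).
    """

    def __init__(self, blocks, rho: float = 0.5, block_scales=None):
        if not 0 <= rho < 1:
            raise ValidationError("rho must lie in [0, 1)")
        if isinstance(blocks, FeatureMap):
            blocks = blocks.blocks
        self.blocks = list(blocks)
        self.rho = rho
        if block_scales is None:
            block_scales = np.ones(len(self.blocks))
        self.block_scales = np.asarray(block_scales, dtype=float)
        if self.block_scales.size != len(self.blocks) or np.any(self.block_scales <= 0):
            raise ValidationError("need one positive variance scale per block")
        precs = [
            ar1_precision(b, rho) / s for b, s in zip(self.blocks, self.block_scales)
        ]
        self.q_precision = sparse.block_diag(precs, format="csr")
        self.logdet_q = float(
            sum(
                (b - 1) * np.log(1.0 - rho ** 2) + b * np.log(s)
                for b, s in zip(self.blocks, self.block_scales)
            )
        )
        self.n_features = sum(self.blocks)

    @classmethod
    def from_data(
        cls,
        fmap: FeatureMap,
        data_features: np.ndarray,
        rho: float = 0.5,
        rel_floor: float = 0.1,
    ) -> "FeatureErrorModel":
        """Error model with block variances matched to the data magnitude.

        Each block's scale is its mean squared feature value plus a floor of
        ``(rel_floor * overall rms)^2``, so residuals are judged relative to
        the size of the spectral quantity they belong to.
        """
        y = np.asarray(data_features, dtype=float)
        if y.size != fmap.size:
            raise ValidationError("data features do not match the feature map")
        floor = (rel_floor * np.sqrt(np.mean(y ** 2))) ** 2
        scales = []
        idx = 0
        for b in fmap.blocks:
            scales.append(np.mean(y[idx: idx + b] ** 2) + floor)
            idx += b
        return cls(fmap.blocks, rho=rho, block_scales=np.asarray(scales))

    def covariance(self, beta: float) -> np.ndarray:
        """Dense covariance ``exp(-beta) Q`` (for small problems/tests)."""
        q = sparse.block_diag(
            [
                s * ar1_correlation(b, self.rho)
                for b, s in zip(self.blocks, self.block_scales)
            ]
        ).toarray()
        return np.exp(-beta) * q

    def precision(self, beta: float) -> sparse.csr_matrix:
        """Sparse precision ``exp(beta) Q^{-1}``."""
        return np.exp(beta) * self.q_precision

    def logdet_precision(self, beta: float) -> float:
        return self.n_features * beta - self.logdet_q


def sampling_error_covariance(beta: float, q_template: np.ndarray) -> np.ndarray:
    """Covariance of feature residuals, ``exp(-beta) Q``."""
    q = np.asarray(q_template, dtype=float)
    w = np.linalg.eigvalsh(q)
    if w.min() <= 0:
        raise ValidationError("Q template must be positive definite")
    return np.exp(-float(beta)) * q


class SpectralForwardModel:
    """Maps a :class:`ParameterVector` to predicted cross-spectral features.

    Fixed quantities (modes, grids, input spectrum) are bound at
    construction; repeated evaluations cache the neuronal and haemodynamic
    transfer functions, which makes finite-difference Jacobians cheap.
    """

    def __init__(
        self,
        modes: np.ndarray,
        frequencies: np.ndarray,
        lags: np.ndarray,
        sampling_interval: float,
        input_spectrum: np.ndarray = None,
        neuronal_scale: float = NEURONAL_DENSITY_SCALE,
        noise_scale: float = NOISE_DENSITY_SCALE,
        identity_hemodynamics: bool = False,
    ):
        self.modes = np.asarray(modes, dtype=float)
        n = self.modes.shape[0]
        if self.modes.shape != (n, n):
            raise ValidationError("modes must be square")
        gram = self.modes.T @ self.modes
        if np.abs(gram - np.eye(n)).max() > 1e-8:
            raise ValidationError("modes must be orthonormal")
        self.frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
        if self.frequencies.size == 0:
            raise ValidationError("frequency grid is empty")
        self.lags = np.atleast_1d(np.asarray(lags, dtype=float))
        self.sampling_interval = float(sampling_interval)
        self.n_nodes = n
        self.transform = CsdCcfTransform(self.frequencies, self.lags)
        self.feature_map = FeatureMap(n, self.frequencies.size, self.lags.size)
        self.error_model = FeatureErrorModel(self.feature_map)
        if input_spectrum is not None:
            input_spectrum = np.asarray(input_spectrum, dtype=float)
            if input_spectrum.shape != self.frequencies.shape:
                raise ValidationError("input spectrum must match the frequency grid")
        self.input_spectrum = input_spectrum
        self.neuronal_scale = float(neuronal_scale)
        self.noise_scale = float(noise_scale)
        #: replace the balloon transfer by unity (tests/composition checks)
        self.identity_hemodynamics = bool(identity_hemodynamics)
        self._h_cache = {}
        self._k_cache = {}

    # -- cached transfer functions ------------------------------------------
    def _regional_transfer(self, ln_a: float, ln_b: float) -> np.ndarray:
        key = (round(float(ln_a), 12), round(float(ln_b), 12))
        h = self._h_cache.get(key)
        if h is None:
            h = hemodynamic_transfer(
                HemodynamicParams(ln_a, ln_b), self.frequencies
            )[:, 0]
            if len(self._h_cache) > 4096:
                self._h_cache.clear()
            self._h_cache[key] = h
        return h

    def _neuronal_transfer(self, tau: np.ndarray) -> np.ndarray:
        key = tau.tobytes()
        K = self._k_cache.get(key)
        if K is None:
            if tau.size != self.n_nodes:
                raise ValidationError(
                    f"tau has {tau.size} entries for {self.n_nodes} modes"
                )
            lam = -np.exp(-tau)
            omega = 2.0 * np.pi * self.frequencies
            r = 1.0 / (1j * omega[:, None] - lam[None, :])
            K = np.einsum("ij,fj,kj->fik", self.modes, r, self.modes)
            if len(self._k_cache) > 4096:
                self._k_cache.clear()
            self._k_cache[key] = K
        return K

    # -- prediction ----------------------------------------------------------
    def _predict_arrays(self, psi: ParameterVector):
        f = self.frequencies
        K = self._neuronal_transfer(psi.tau)
        g_v = fluctuation_spectrum(
            psi.neuronal_amp, psi.neuronal_exponent, f, scale=self.neuronal_scale
        )
        g_x = np.einsum("fik,fk,fjk->fij", K, g_v.astype(complex), K.conj())
        if self.input_spectrum is not None and psi.input_scaling is not None:
            kc = K @ psi.input_scaling.astype(complex)  # (F, N)
            g_x = g_x + self.input_spectrum[:, None, None] * np.einsum(
                "fi,fj->fij", kc, kc.conj()
            )
        if self.identity_hemodynamics:
            H = np.ones((f.size, self.n_nodes), dtype=complex)
        else:
            H = np.column_stack(
                [
                    self._regional_transfer(
                        psi.hemo.log_decay_scale[r], psi.hemo.log_transit_scale[r]
                    )
                    for r in range(self.n_nodes)
                ]
            )  # (F, N)
        g_y = H[:, :, None] * g_x * H.conj()[:, None, :]
        g_w = fluctuation_spectrum(
            psi.noise_amp, psi.noise_exponent, f, scale=self.noise_scale
        )
        idx = np.arange(self.n_nodes)
        g_y[:, idx, idx] = g_y[:, idx, idx].real + g_w
        # enforce exact Hermitian symmetry against rounding
        g_y = 0.5 * (g_y + g_y.conj().transpose(0, 2, 1))
        ccf = self.transform.csd_to_ccf(g_y)
        return g_y, ccf

    def predict_csd(self, psi: ParameterVector) -> CrossSpectralData:
        """Predicted cross spectra and cross covariances as a data object."""
        g_y, ccf = self._predict_arrays(psi)
        return CrossSpectralData(
            self.frequencies, g_y, self.lags, ccf, self.sampling_interval
        )

    def predict_features(self, psi: ParameterVector) -> np.ndarray:
        """Predicted feature vector (no container validation; fast path)."""
        g_y, ccf = self._predict_arrays(psi)
        return self.feature_map.pack(g_y, ccf)
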