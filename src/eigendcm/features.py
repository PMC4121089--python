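"""Sample spectral features of observed multi-region timeseries.

The model's fixed inputs are estimated here: complex cross spectra (by a
parametric multivariate autoregressive fit, with a nonparametric Welch
fallback), the derived cross-covariance functions, and the eigenmodes of the
sample covariance, which stand in for the eigenmodes of the underlying
effective connectivity.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal
from statsmodels.tsa.api import VAR

from .exceptions import ValidationError
from .modes import order_and_sign
from .spectra import (
    CrossSpectralData,
    csd_to_ccf,
    default_frequency_grid,
    default_lag_grid,
)

__all__ = [
    "detrend_standardise",
    "sample_csd",
    "mar_csd",
    "welch_csd",
    "functional_eigenmodes",
]

MIN_SAMPLES = 64
DEFAULT_MAR_ORDER = 8


def detrend_standardise(
    timeseries: np.ndarray, standardise: bool = False
) -> np.ndarray:
    """Remove a per-node linear trend; optionally scale to unit variance.

    ``timeseries`` is (n_samples, n_nodes).  Constant channels are retained
    with a warning (they carry no spectral information but keep indexing
    intact).
    """
    y = np.atleast_2d(np.asarray(timeseries, dtype=float))
    if y.shape[0] < MIN_SAMPLES:
        raise ValidationError(f"need at least {MIN_SAMPLES} samples, got {y.shape[0]}")
    t = np.arange(y.shape[0], dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = y - X @ coef
    sd = out.std(axis=0, ddof=1)
    const = sd < 1e-12 * max(1.0, np.abs(y).max())
    if const.any():
        warnings.warn(
            f"channels {np.flatnonzero(const).tolist()} are constant after "
            "detrending; retained as zeros"
        )
    if standardise:
        scale = np.where(const, 1.0, sd)
        out = out / scale
    return out


def mar_csd(
    timeseries: np.ndarray,
    sampling_interval: float,
    frequencies: np.ndarray,
    order: int = DEFAULT_MAR_ORDER,
) -> np.ndarray:
    """Cross-spectral density from a multivariate autoregressive fit.

    Fits ``y_t = sum_k A_k y_{t-k} + e_t`` (no trend; input should be
    detrended) and evaluates the two-sided density per Hz,
    ``S(f) = dt H(f) Sigma_e H(f)^H`` with ``H = (I - sum_k A_k z^k)^{-1}``,
    ``z = exp(-2j pi f dt)``.
    """
    y = np.asarray(timeseries, dtype=float)
    dt = float(sampling_interval)
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    n = y.shape[1]
    res = VAR(y).fit(maxlags=order, trend="n")
    coefs = res.coefs  # (order, n, n)
    sigma = res.sigma_u
    z = np.exp(-2j * np.pi * f[:, None] * dt * np.arange(1, coefs.shape[0] + 1))
    Aw = np.eye(n) - np.einsum("fk,kij->fij", z, coefs.astype(complex))
    H = np.linalg.inv(Aw)
    S = dt * np.einsum("fik,kl,fjl->fij", H, sigma.astype(complex), H.conj())
    return 0.5 * (S + S.conj().transpose(0, 2, 1))


def welch_csd(
    timeseries: np.ndarray,
    sampling_interval: float,
    frequencies: np.ndarray,
    nperseg: int = 128,
) -> np.ndarray:
    """Nonparametric windowed-segment (Welch) cross-spectral estimate.

    Interpolated from the Welch grid onto the requested frequencies; the
    two-sided density per Hz (half the one-sided scipy output).
    """
    y = np.asarray(timeseries, dtype=float)
    fs = 1.0 / float(sampling_interval)
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    n = y.shape[1]
    nperseg = min(nperseg, y.shape[0])
    fw, _ = sp_signal.csd(y[:, 0], y[:, 0], fs=fs, nperseg=nperseg)
    S = np.empty((f.size, n, n), dtype=complex)
    for i in range(n):
        for j in range(i, n):
            _, sij = sp_signal.csd(y[:, i], y[:, j], fs=fs, nperseg=nperseg)
            sij = 0.5 * sij  # one-sided -> two-sided density
            re = np.interp(f, fw, sij.real)
            im = np.interp(f, fw, sij.imag)
            S[:, i, j] = re + 1j * im
            S[:, j, i] = re - 1j * im
    return S


def sample_csd(
    timeseries: np.ndarray,
    sampling_interval: float,
    frequencies: np.ndarray = None,
    lags: np.ndarray = None,
    estimator: str = "mar",
    mar_order: int = DEFAULT_MAR_ORDER,
) -> CrossSpectralData:
    """Estimate cross spectra and cross covariances of a timeseries.

    ``timeseries`` is (n_samples, n_nodes), assumed detrended.  Frequencies
    must stay below the Nyquist frequency; defaults use 32 points up to half
    Nyquist and 32 lags of one sample each.
    """
    y = np.atleast_2d(np.asarray(timeseries, dtype=float))
    dt = float(sampling_interval)
    if frequencies is None:
        frequencies = default_frequency_grid(y.shape[0], dt)
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if f.max() > 0.5 / dt + 1e-12:
        raise ValidationError(
            f"frequencies exceed the Nyquist frequency {0.5 / dt:.4g} Hz"
        )
    if lags is None:
        lags = default_lag_grid(dt)
    if estimator == "mar":
        csd = mar_csd(y, dt, f, order=mar_order)
    elif estimator == "welch":
        csd = welch_csd(y, dt, f)
    else:
        raise ValidationError(f"unknown spectral estimator '{estimator}'")
    ccf = csd_to_ccf(csd, f, lags)
    return CrossSpectralData(f, csd, lags, ccf, dt)


def functional_eigenmodes(timeseries: np.ndarray):
    """Eigenmodes and eigenvalues of the sample covariance matrix.

    Returns (modes, eigenvalues) with modes orthonormal, columns ordered by
    descending eigenvalue under the deterministic sign convention.  A
    rank-deficient covariance yields pseudo-eigenmodes with a warning.
    """
    y = np.atleast_2d(np.asarray(timeseries, dtype=float))
    t, n = y.shape
    if t < n + 1:
        raise ValidationError(f"need at least {n + 1} samples for {n} nodes")
    cov = np.cov(y, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(np.atleast_2d(cov))
    w = np.clip(w, 0.0, None)
    if w.min() < 1e-12 * max(w.max(), 1.0):
        warnings.warn("sample covariance is rank deficient; "
                      "trailing eigenmodes have (near) zero eigenvalues")
    w, v = order_and_sign(w, v)
    return v, w
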