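"""Cross-spectral data containers and Fourier-pair conversions.

Spectral densities are two-sided densities per Hz, stored on a uniform grid of
positive frequencies; the negative-frequency half is implied by Hermitian
symmetry, ``g(-f) = conj(g(f))``.  The cross-covariance function on a uniform
lag grid is the band-limited Fourier transform

    ccf(l) = int g(f) exp(2j pi f l) df  ~=  sum_k w_k 2 Re[g(f_k) exp(2j pi f_k l)]

with trapezoid quadrature weights ``w_k``.  The inverse map solves the same
linear system by least squares, so ``csd -> ccf -> csd`` is an identity (to
machine precision) whenever the lag grid is at least as informative as the
frequency grid, and ``ccf -> csd -> ccf`` recovers any band-limited input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import TOL
from .exceptions import ValidationError

__all__ = [
    "CrossSpectralData",
    "CsdCcfTransform",
    "csd_to_ccf",
    "ccf_to_csd",
    "default_frequency_grid",
    "default_lag_grid",
]


def default_frequency_grid(
    n_samples: int, sampling_interval: float, n_freq: int = 32
) -> np.ndarray:
    """Uniform grid from 1/(T*dt) to half the Nyquist frequency, in Hz."""
    f_min = 1.0 / (n_samples * sampling_interval)
    f_max = 0.25 / sampling_interval
    return np.linspace(f_min, f_max, n_freq)


def default_lag_grid(sampling_interval: float, n_lags: int = 32) -> np.ndarray:
    """Uniform non-negative lag grid in seconds (n_lags bins of one sample)."""
    return np.arange(n_lags) * float(sampling_interval)


def _check_uniform(grid: np.ndarray, name: str) -> float:
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        return 1.0
    d = np.diff(grid)
    if d.min() <= 0:
        raise ValidationError(f"{name} grid must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-6, atol=0.0):
        raise ValidationError(f"{name} grid must be uniform")
    return float(d[0])


class CsdCcfTransform:
    """Precomputed linear maps between csd and ccf on fixed uniform grids."""

    def __init__(self, frequencies: np.ndarray, lags: np.ndarray):
        self.frequencies = np.asarray(frequencies, dtype=float)
        self.lags = np.asarray(lags, dtype=float)
        df = _check_uniform(self.frequencies, "frequency")
        _check_uniform(self.lags, "lag")
        if np.any(self.frequencies <= 0):
            raise ValidationError("frequencies must be positive")
        weights = np.full(self.frequencies.size, df)
        weights[0] = weights[-1] = df / 2.0
        phase = 2.0 * np.pi * np.outer(self.lags, self.frequencies)
        # ccf_ij(l) = C @ Re(g_ij) - S @ Im(g_ij)
        self._C = 2.0 * np.cos(phase) * weights
        self._S = 2.0 * np.sin(phase) * weights
        # inverse maps (least squares): off-diagonal pairs use both orderings
        self._pinv_diag = np.linalg.pinv(self._C, rcond=1e-12)
        self._pinv_pair = np.linalg.pinv(
            np.block([[self._C, -self._S], [self._C, self._S]]), rcond=1e-12
        )

    def csd_to_ccf(self, csd: np.ndarray) -> np.ndarray:
        """Map (n_freq, N, N) Hermitian csd to real (n_lag, N, N) ccf."""
        csd = np.asarray(csd)
        if csd.shape[0] != self.frequencies.size:
            raise ValidationError(
                f"csd has {csd.shape[0]} frequencies, transform expects "
                f"{self.frequencies.size}"
            )
        flat = csd.reshape(csd.shape[0], -1)
        ccf = self._C @ flat.real - self._S @ flat.imag
        return ccf.reshape((self.lags.size,) + csd.shape[1:])

    def ccf_to_csd(self, ccf: np.ndarray) -> np.ndarray:
        """Least-squares inverse of :meth:`csd_to_ccf`."""
        ccf = np.asarray(ccf, dtype=float)
        if ccf.shape[0] != self.lags.size:
            raise ValidationError(
                f"ccf has {ccf.shape[0]} lags, transform expects {self.lags.size}"
            )
        if ccf.ndim == 1:
            re = self._pinv_diag @ ccf
            return re.astype(complex)
        n = ccf.shape[1]
        K = self.frequencies.size
        csd = np.zeros((K, n, n), dtype=complex)
        for i in range(n):
            re = self._pinv_diag @ ccf[:, i, i]
            csd[:, i, i] = re
            for j in range(i + 1, n):
                sol = self._pinv_pair @ np.concatenate([ccf[:, i, j], ccf[:, j, i]])
                g = sol[:K] + 1j * sol[K:]
                csd[:, i, j] = g
                csd[:, j, i] = g.conj()
        return csd


def csd_to_ccf(csd: np.ndarray, frequencies: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Cross-covariance functions from cross-spectral densities (see class)."""
    return CsdCcfTransform(frequencies, lags).csd_to_ccf(csd)


def ccf_to_csd(ccf: np.ndarray, frequencies: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Cross-spectral densities from cross-covariance functions (see class)."""
    return CsdCcfTransform(frequencies, lags).ccf_to_csd(ccf)


@dataclass(frozen=True)
class CrossSpectralData:
    """Complex cross spectra plus real cross covariances on fixed grids."""

    frequencies: np.ndarray
    csd: np.ndarray
    lags: np.ndarray
    ccf: np.ndarray
    sampling_interval: float

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        csd = np.asarray(self.csd, dtype=complex)
        lags = np.asarray(self.lags, dtype=float)
        ccf = np.asarray(self.ccf, dtype=float)
        for name, val in (("frequencies", f), ("csd", csd), ("lags", lags), ("ccf", ccf)):
            object.__setattr__(self, name, val)
        if np.any(np.diff(f) <= 0) or np.any(f <= 0):
            raise ValidationError("frequencies must be positive and strictly increasing")
        if csd.shape[0] != f.size or ccf.shape[0] != lags.size:
            raise ValidationError("grid lengths do not match array shapes")
        if csd.shape[1] != csd.shape[2] or ccf.shape[1:] != csd.shape[1:]:
            raise ValidationError("csd/ccf must be square and matching in node count")
        scale = max(np.abs(csd).max(), 1e-300)
        herm = np.abs(csd - csd.conj().transpose(0, 2, 1)).max()
        if herm > TOL["hermitian"] * max(1.0, scale):
            raise ValidationError(f"csd slices are not Hermitian (max deviation {herm:.3e})")
        diag = np.diagonal(csd, axis1=1, axis2=2)
        if np.abs(diag.imag).max() > TOL["hermitian"] * max(1.0, scale):
            raise ValidationError("csd diagonals must be real")
        if diag.real.min() < -TOL["hermitian"] * max(1.0, scale):
            raise ValidationError("csd diagonals must be non-negative")
        c0 = ccf[np.argmin(np.abs(lags))] if lags.size else None
        if c0 is not None:
            sym = 0.5 * (c0 + c0.T)
            w = np.linalg.eigvalsh(sym)
            if w.min() < -1e-6 * max(1.0, np.abs(w).max()):
                raise ValidationError("zero-lag covariance is not positive semidefinite")

    @property
    def n_nodes(self) -> int:
        return self.csd.shape[1]

    @classmethod
    def from_csd(
        cls,
        frequencies: np.ndarray,
        csd: np.ndarray,
        lags: np.ndarray,
        sampling_interval: float,
    ) -> "CrossSpectralData":
        """Build the container, deriving the ccf from the csd."""
        ccf = csd_to_ccf(csd, frequencies, lags)
        return cls(frequencies, csd, lags, ccf, sampling_interval)
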