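"""Multi-Lorentzian origin of 1/f spectra.

Each mode of a symmetric linear stochastic system contributes a Lorentzian
auto-spectrum ``1 / (w^2 + tau^-2)`` with corner set by its time constant.
If time constants are drawn from the scale-free density

    p(tau) = eps * tau^-2   on [eps, inf),

the expected spectrum is ``eps * pi / (2 w) = eps / (4 f)`` in the limit of a
small lower bound ``eps`` — the classical 1/f form.  With time constants
restricted to a finite interval the 1/f regime holds between the corner
frequencies of the slowest and fastest modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .exceptions import ValidationError

__all__ = [
    "PowerLawEnsemble",
    "sample_time_constants",
    "mixture_spectrum",
    "analytic_spectrum",
    "quadrature_spectrum",
    "loglog_slope",
    "DEFAULT_TAU_RANGE",
]

#: default truncation range for sampled time constants (seconds)
DEFAULT_TAU_RANGE = (1.0 / 256.0, 4.0)


@dataclass(frozen=True)
class PowerLawEnsemble:
    """Time constants sampled from ``p(tau) = eps tau^-2`` (optionally truncated)."""

    epsilon: float
    time_constants: np.ndarray
    upper_bound: float = None

    def __post_init__(self):
        tc = np.asarray(self.time_constants, dtype=float)
        object.__setattr__(self, "time_constants", tc)
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if tc.size and tc.min() < self.epsilon * (1 - 1e-12):
            raise ValidationError("sampled time constants fall below epsilon")
        if self.upper_bound is not None and tc.size and tc.max() > self.upper_bound * (1 + 1e-12):
            raise ValidationError("sampled time constants exceed the upper bound")

    @property
    def n_modes(self) -> int:
        return self.time_constants.size


def sample_time_constants(
    epsilon: float,
    n: int,
    seed: int,
    upper_bound: float = None,
) -> PowerLawEnsemble:
    """Draw ``n`` time constants from ``p(tau) = eps tau^-2`` by inverse CDF.

    Unbounded: ``tau = eps / (1 - u)`` with ``u ~ U(0, 1)``.  Truncated on
    ``[eps, upper_bound]`` the density is renormalised and
    ``tau = 1 / (1/eps - u (1/eps - 1/upper))``.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    if upper_bound is None:
        tau = epsilon / (1.0 - u)
    else:
        if upper_bound <= epsilon:
            raise ValidationError("upper bound must exceed epsilon")
        tau = 1.0 / (1.0 / epsilon - u * (1.0 / epsilon - 1.0 / upper_bound))
    return PowerLawEnsemble(epsilon, tau, upper_bound)


def analytic_spectrum(epsilon: float, frequencies: np.ndarray) -> np.ndarray:
    """Small-``eps`` limit of the mixture: ``eps pi / (2 w) = eps / (4 f)``."""
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(f <= 0):
        raise ValidationError("frequencies must be positive")
    return epsilon / (4.0 * f)


def quadrature_spectrum(
    epsilon: float,
    frequencies: np.ndarray,
    upper_bound: float = None,
    abs_tol: float = 1e-10,
) -> np.ndarray:
    """Numerically integrate the Lorentzian mixture over the tau density.

    Evaluates ``int p(tau) / (w^2 + tau^-2) dtau`` with adaptive quadrature
    (``w = 2 pi f``); ``p`` is renormalised when truncated.
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(f <= 0):
        raise ValidationError("frequencies must be positive")
    hi = np.inf if upper_bound is None else upper_bound
    norm = 1.0 / epsilon if upper_bound is None else (1.0 / epsilon - 1.0 / upper_bound)
    out = np.empty(f.size)
    for k, fk in enumerate(f):
        w = 2.0 * np.pi * fk

        def integrand(tau, w=w):
            return tau ** -2 / (w ** 2 + tau ** -2)

        val, _ = integrate.quad(
            integrand, epsilon, hi, epsabs=abs_tol, epsrel=1e-10, limit=400
        )
        out[k] = val / norm
    return out


def mixture_spectrum(
    ensemble: PowerLawEnsemble,
    frequencies: np.ndarray,
) -> np.ndarray:
    """Average the equal-weight Lorentzians of a sampled ensemble.

    Returns ``mean_i 1 / (w^2 + tau_i^-2)`` on the frequency grid (Hz), the
    Monte-Carlo counterpart of :func:`quadrature_spectrum`.
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(f <= 0):
        raise ValidationError("frequencies must be positive")
    w = 2.0 * np.pi * f
    rates = 1.0 / ensemble.time_constants
    return np.mean(1.0 / (w[:, None] ** 2 + rates[None, :] ** 2), axis=1)


def loglog_slope(
    spectrum: np.ndarray,
    frequencies: np.ndarray,
    band: tuple = None,
) -> float:
    """Least-squares slope of log spectrum against log frequency in a band."""
    f = np.asarray(frequencies, dtype=float)
    s = np.asarray(spectrum, dtype=float)
    if band is not None:
        mask = (f >= band[0]) & (f <= band[1])
        f, s = f[mask], s[mask]
    if f.size < 3:
        raise ValidationError("need at least 3 points inside the band")
    if np.any(s <= 0) or np.any(f <= 0):
        raise ValidationError("spectrum and frequencies must be positive")
    x = np.log(f)
    y = np.log(s)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)
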