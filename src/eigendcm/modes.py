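"""Eigenmode/Lyapunov algebra for symmetric linear stochastic networks.

The neuronal model is a multivariate Ornstein--Uhlenbeck process

    dx/dt = A x + v,

where the effective connectivity ``A`` (units Hz) is symmetric and negative
definite, so it can be composed from an orthonormal set of modes ``mu`` and
real negative Lyapunov exponents ``lambda``:  ``A = mu @ diag(lambda) @ mu.T``.
Unstable (slow) modes carry free log time constants ``tau`` with exponents
``lambda = -exp(-tau)``; the remaining stable modes share a single log decay
``eta`` with ``lambda = -exp(eta)``.

Because modes of a symmetric system are dynamically and statistically
uncoupled, the stationary covariance of the hidden states shares the same
eigenvectors, with mode variances ``gamma_i = Gamma * tau_i`` proportional to
the time constants — slow modes dominate functional connectivity.  This module
implements that algebra together with the frequency-domain transfer function
and the cross-spectral / cross-covariance conversions used downstream.

All user-facing frequency grids are in Hz; angular frequency ``w = 2*pi*f`` is
used internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import TOL
from .exceptions import ConditioningError, StabilityError, ValidationError

__all__ = [
    "EigenSpec",
    "EffectiveConnectivity",
    "FluctuationAmplitude",
    "order_and_sign",
    "compose_jacobian",
    "exponents_from_spec",
    "stationary_covariance",
    "effective_from_functional",
    "transfer_function",
    "csd_hidden",
]


def _check_orthonormal(modes: np.ndarray, tol: float = TOL["orthonormal"]) -> None:
    gram = modes.T @ modes
    dev = np.abs(gram - np.eye(modes.shape[1]))
    if dev.max() > tol:
        i, j = np.unravel_index(np.argmax(dev), dev.shape)
        raise ValidationError(
            f"mode matrix is not orthonormal: columns {i} and {j} have "
            f"inner-product deviation {dev[i, j]:.3e} (tolerance {tol:.1e})"
        )


def order_and_sign(eigenvalues: np.ndarray, eigenvectors: np.ndarray):
    """Order eigenpairs by descending eigenvalue with a deterministic sign.

    The sign convention makes the largest-magnitude component of each
    eigenvector positive; ties in eigenvalue are broken by the sign and index
    of the first non-negligible component, so repeated calls on the same input
    are reproducible.
    """
    order = np.argsort(-eigenvalues, kind="stable")
    w = np.asarray(eigenvalues)[order]
    v = np.asarray(eigenvectors)[:, order].copy()
    for k in range(v.shape[1]):
        col = v[:, k]
        i = np.argmax(np.abs(col))
        if col[i] < 0:
            v[:, k] = -col
    return w, v


@dataclass(frozen=True)
class EigenSpec:
    """Eigenmode parameterisation of symmetric effective connectivity.

    Parameters
    ----------
    modes : ndarray (N, N)
        Orthonormal modes, columns ordered by descending data eigenvalue.
        The first ``n_unstable`` columns are the slow (unstable) modes.
    log_time_constants : ndarray (m,)
        Log time constants ``tau`` of the unstable modes (log seconds).
        Exponents are ``lambda = -exp(-tau)``.
    log_decay : float
        Shared log decay ``eta >= 0`` of the stable modes (log Hz),
        exponent ``lambda = -exp(eta)``.
    """

    modes: np.ndarray
    log_time_constants: np.ndarray
    log_decay: float = 1.0
    node_labels: tuple = field(default=None)

    def __post_init__(self):
        modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        tau = np.atleast_1d(np.asarray(self.log_time_constants, dtype=float))
        object.__setattr__(self, "modes", modes)
        object.__setattr__(self, "log_time_constants", tau)
        if modes.shape[0] != modes.shape[1]:
            raise ValidationError(f"modes must be square, got {modes.shape}")
        if tau.size > modes.shape[0]:
            raise ValidationError(
                f"{tau.size} unstable modes exceed {modes.shape[0]} nodes"
            )
        if not np.all(np.isfinite(tau)) or not np.isfinite(self.log_decay):
            raise ValidationError("non-finite time-constant parameters")
        _check_orthonormal(modes)
        if self.node_labels is None:
            object.__setattr__(
                self, "node_labels",
                tuple(f"node{i}" for i in range(modes.shape[0])),
            )

    @property
    def n_nodes(self) -> int:
        return self.modes.shape[0]

    @property
    def n_unstable(self) -> int:
        return self.log_time_constants.size

    @property
    def exponents(self) -> np.ndarray:
        """Lyapunov exponents (Hz), strictly negative, one per mode."""
        lam = np.empty(self.n_nodes)
        lam[: self.n_unstable] = -np.exp(-self.log_time_constants)
        lam[self.n_unstable:] = -np.exp(self.log_decay)
        return lam

    @property
    def time_constants(self) -> np.ndarray:
        """Per-mode time constants (s), the negative inverse exponents."""
        return -1.0 / self.exponents


@dataclass(frozen=True)
class EffectiveConnectivity:
    """Symmetric stable effective connectivity (Jacobian, units Hz)."""

    jacobian: np.ndarray
    node_labels: tuple = None

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.jacobian, dtype=float))
        object.__setattr__(self, "jacobian", A)
        if A.shape[0] != A.shape[1]:
            raise ValidationError(f"jacobian must be square, got {A.shape}")
        asym = np.abs(A - A.T).max()
        if asym > max(TOL["symmetry"], 1e-10 * max(1.0, np.abs(A).max())):
            raise ValidationError(f"jacobian asymmetry {asym:.3e} exceeds tolerance")
        if self.node_labels is None:
            object.__setattr__(
                self, "node_labels", tuple(f"node{i}" for i in range(A.shape[0]))
            )

    @property
    def n_nodes(self) -> int:
        return self.jacobian.shape[0]

    def eigendecompose(self):
        """Eigenpairs ordered by descending eigenvalue, deterministic sign."""
        w, v = np.linalg.eigh(self.jacobian)
        return order_and_sign(w, v)

    def require_stable(self) -> None:
        w = np.linalg.eigvalsh(self.jacobian)
        if w.max() >= 0:
            raise StabilityError(
                f"jacobian is not negative definite (max eigenvalue {w.max():.3e})"
            )


@dataclass(frozen=True)
class FluctuationAmplitude:
    """Amplitude of state noise: ``Gamma = Sigma_v / 2`` (signal^2 * Hz)."""

    gamma: float

    def __post_init__(self):
        if not (self.gamma > 0):
            raise ValidationError(f"gamma must be positive, got {self.gamma}")

    @property
    def sigma_v(self) -> float:
        """Spectral density of the white state noise (twice gamma)."""
        return 2.0 * self.gamma


def compose_jacobian(spec: EigenSpec) -> EffectiveConnectivity:
    """Compose the effective connectivity ``A = mu @ diag(lambda) @ mu.T``.

    The result is symmetric negative definite by construction; its
    eigenvalues are the Lyapunov exponents of the spec.
    """
    lam = spec.exponents
    A = (spec.modes * lam) @ spec.modes.T
    A = 0.5 * (A + A.T)  # remove rounding asymmetry
    return EffectiveConnectivity(A, node_labels=spec.node_labels)


def exponents_from_spec(spec: EigenSpec):
    """Return (Lyapunov exponents in Hz, time constants in s) per mode."""
    return spec.exponents, spec.time_constants


def stationary_covariance(
    A: EffectiveConnectivity, fluct: FluctuationAmplitude
) -> np.ndarray:
    """Stationary covariance of ``dx/dt = A x + v`` with white ``v``.

    Equals ``mu @ diag(Gamma * tau_i) @ mu.T`` where ``tau_i = -1/lambda_i``,
    i.e. the solution of the Lyapunov equation ``A S + S A' = -Sigma_v`` for
    ``Sigma_v = 2 Gamma I``.
    """
    A.require_stable()
    w, v = A.eigendecompose()
    gamma_i = -fluct.gamma / w
    return (v * gamma_i) @ v.T


def effective_from_functional(
    sigma_x: np.ndarray, fluct: FluctuationAmplitude
) -> EffectiveConnectivity:
    """Invert the stationary covariance: ``A = -Gamma * Sigma_x^{-1}``."""
    S = np.atleast_2d(np.asarray(sigma_x, dtype=float))
    if np.abs(S - S.T).max() > 1e-8 * max(1.0, np.abs(S).max()):
        raise ValidationError("functional covariance must be symmetric")
    w = np.linalg.eigvalsh(S)
    if w.min() <= 0 or w.max() / w.min() > 1e12:
        raise ConditioningError(
            f"functional covariance is singular or ill-conditioned "
            f"(eigenvalue range [{w.min():.3e}, {w.max():.3e}])"
        )
    A = -fluct.gamma * np.linalg.inv(S)
    return EffectiveConnectivity(0.5 * (A + A.T))


def transfer_function(
    A: EffectiveConnectivity, frequencies: np.ndarray
) -> np.ndarray:
    """Neuronal transfer function ``K(w) = mu (jw - lambda)^{-1} mu.T``.

    ``frequencies`` are in Hz; returns a complex array (n_freq, N, N).
    ``K(0) = -A^{-1}`` and ``K(-f) = conj(K(f))``.
    """
    A.require_stable()
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    w, v = A.eigendecompose()
    omega = 2.0 * np.pi * f
    r = 1.0 / (1j * omega[:, None] - w[None, :])  # (F, N)
    return np.einsum("ij,fj,kj->fik", v, r, v)


def csd_hidden(
    A: EffectiveConnectivity,
    g_v: np.ndarray,
    frequencies: np.ndarray,
) -> np.ndarray:
    """Cross-spectral density of hidden states, ``g_x = K g_v K*``.

    Parameters
    ----------
    g_v : scalar, (n_freq,), (n_freq, N) or (n_freq, N, N)
        Spectral density of the state noise.  Scalar or per-frequency inputs
        denote a white/common density on all nodes; a 2-d input gives
        per-node (diagonal) densities.
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    K = transfer_function(A, f)
    n = A.n_nodes
    g = np.asarray(g_v, dtype=complex)
    if g.ndim == 0:
        g = np.broadcast_to(g, (f.size,))
    if g.ndim == 1:
        if g.shape[0] != f.size:
            raise ValidationError(
                f"g_v length {g.shape[0]} does not match {f.size} frequencies"
            )
        gd = np.zeros((f.size, n, n), dtype=complex)
        idx = np.arange(n)
        gd[:, idx, idx] = g[:, None]
        g = gd
    elif g.ndim == 2:
        if g.shape != (f.size, n):
            raise ValidationError(f"diagonal g_v has shape {g.shape}, expected {(f.size, n)}")
        gd = np.zeros((f.size, n, n), dtype=complex)
        idx = np.arange(n)
        gd[:, idx, idx] = g
        g = gd
    elif g.shape != (f.size, n, n):
        raise ValidationError(
            f"g_v has shape {g.shape}, expected {(f.size, n, n)}"
        )
    gx = np.einsum("fik,fkl,fjl->fij", K, g, K.conj())
    return gx
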