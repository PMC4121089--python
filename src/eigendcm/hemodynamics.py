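"""Regional balloon-model haemodynamics.

Neuronal activity ``x`` drives a vasodilatory signal ``s``, which drives
normalised blood flow ``f``; flow inflates venous volume ``v`` and dilutes
deoxyhaemoglobin ``q``:

    ds/dt = x - kappa s - g (f - 1)
    df/dt = s
    t_h dv/dt = f - v^(1/alpha)
    t_h dq/dt = f E(f)/E0 - v^(1/alpha) q / v,     E(f) = 1 - (1 - E0)^(1/f)

with neurovascular decay ``kappa = KAPPA exp(ln a)``, autoregulation ``g``,
transit time ``t_h = TRANSIT_TIME exp(ln b)`` and Grubb exponent ``alpha``.
The BOLD observer maps (q, v) to percent signal change.  Only the decay and
transit scales (ln a, ln b) are free parameters, with tight log-normal priors;
everything else is fixed at the literature constants in :mod:`.constants`.

For the spectral generative model the system is linearised at its resting
fixed point (s, f, v, q) = (0, 1, 1, 1), giving a per-region low-pass transfer
function from neuronal input to BOLD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .exceptions import StabilityError, ValidationError

__all__ = [
    "HemodynamicParams",
    "REST_STATE",
    "oxygen_extraction",
    "hemodynamic_ode",
    "bold_observer",
    "hemodynamic_jacobian",
    "observer_gradient",
    "hemodynamic_transfer",
]

#: resting fixed point (s, f, v, q)
REST_STATE = np.array([0.0, 1.0, 1.0, 1.0])


@dataclass(frozen=True)
class HemodynamicParams:
    """Per-region free haemodynamic scales (log deviations from defaults)."""

    log_decay_scale: np.ndarray = field(default=0.0)   # ln a
    log_transit_scale: np.ndarray = field(default=0.0) # ln b

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.log_decay_scale, dtype=float))
        b = np.atleast_1d(np.asarray(self.log_transit_scale, dtype=float))
        if a.shape != b.shape:
            raise ValidationError("log scale arrays must have matching shapes")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValidationError("haemodynamic log scales must be finite")
        object.__setattr__(self, "log_decay_scale", a)
        object.__setattr__(self, "log_transit_scale", b)

    @property
    def n_regions(self) -> int:
        return self.log_decay_scale.size

    @property
    def kappa(self) -> np.ndarray:
        """Neurovascular decay rate per region (1/s)."""
        return C.KAPPA * np.exp(self.log_decay_scale)

    @property
    def transit(self) -> np.ndarray:
        """Mean transit time per region (s)."""
        return C.TRANSIT_TIME * np.exp(self.log_transit_scale)


def oxygen_extraction(f: np.ndarray, e0: float = C.E0) -> np.ndarray:
    """Oxygen extraction fraction as a function of normalised flow."""
    f = np.asarray(f, dtype=float)
    return 1.0 - (1.0 - e0) ** (1.0 / f)


def hemodynamic_ode(
    state: np.ndarray, neuronal_input: np.ndarray, params: HemodynamicParams
) -> np.ndarray:
    """Time derivative of the balloon states.

    ``state`` has shape (..., 4) ordered (s, f, v, q); ``neuronal_input``
    broadcasts against the leading dimensions.  Raises on non-positive flow,
    volume or deoxyhaemoglobin, where the model is undefined.
    """
    state = np.asarray(state, dtype=float)
    s, f, v, q = np.moveaxis(state, -1, 0)
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValidationError("flow, volume and deoxyhaemoglobin must stay positive")
    x = np.asarray(neuronal_input, dtype=float)
    kappa = params.kappa
    th = params.transit
    inv_alpha = 1.0 / C.GRUBB_EXPONENT
    outflow = v ** inv_alpha
    ds = x - kappa * s - C.AUTOREGULATION * (f - 1.0)
    df = s
    dv = (f - outflow) / th
    dq = (f * oxygen_extraction(f) / C.E0 - outflow * q / v) / th
    ds, df, dv, dq = np.broadcast_arrays(ds, df, dv, dq)
    return np.stack([ds, df, dv, dq], axis=-1)


def bold_observer(state: np.ndarray, params: HemodynamicParams = None) -> np.ndarray:
    """BOLD percent signal change from the balloon states (zero at rest)."""
    state = np.asarray(state, dtype=float)
    v = state[..., 2]
    q = state[..., 3]
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValidationError("volume and deoxyhaemoglobin must stay positive")
    return C.V0 * (
        C.K1 * (1.0 - q) + C.K2 * (1.0 - q / v) + C.K3 * (1.0 - v)
    )


def _numeric_gradient(fun, x0, step=1e-6):
    x0 = np.asarray(x0, dtype=float)
    cols = []
    for i in range(x0.size):
        dx = np.zeros_like(x0)
        dx[i] = step
        cols.append((fun(x0 + dx) - fun(x0 - dx)) / (2 * step))
    return np.stack(cols, axis=-1)


def hemodynamic_jacobian(params: HemodynamicParams) -> np.ndarray:
    """Jacobian of the balloon ODE at rest, shape (n_regions, 4, 4)."""
    n = params.n_regions
    jac = np.empty((n, 4, 4))
    for r in range(n):
        pr = HemodynamicParams(params.log_decay_scale[r], params.log_transit_scale[r])

        def rhs(state, pr=pr):
            return hemodynamic_ode(state, 0.0, pr)[0]

        jac[r] = _numeric_gradient(rhs, REST_STATE)
    return jac


def observer_gradient() -> np.ndarray:
    """Gradient of the BOLD observer with respect to the state, at rest."""
    return _numeric_gradient(lambda st: np.atleast_1d(bold_observer(st)), REST_STATE)[0]


def hemodynamic_transfer(
    params: HemodynamicParams, frequencies: np.ndarray
) -> np.ndarray:
    """Linearised neuronal-to-BOLD transfer function per region.

    ``H(w) = grad_y . (jw I - J_h)^{-1} . B`` with ``J_h`` the resting-state
    Jacobian and ``B`` the input gradient (neuronal drive enters the
    vasodilatory signal with unit efficacy).  Frequencies in Hz; returns a
    complex array (n_freq, n_regions).  ``|H|`` is low-pass.
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    jac = hemodynamic_jacobian(params)
    for r in range(jac.shape[0]):
        ev = np.linalg.eigvals(jac[r])
        if ev.real.max() >= 0:
            raise StabilityError(
                f"haemodynamic Jacobian of region {r} is unstable "
                f"(max Re eigenvalue {ev.real.max():.3e})"
            )
    grad = observer_gradient()
    B = np.array([1.0, 0.0, 0.0, 0.0])
    omega = 2.0 * np.pi * f
    n = jac.shape[0]
    M = 1j * omega[:, None, None, None] * np.eye(4) - jac[None, :, :, :]
    z = np.linalg.solve(M.reshape(-1, 4, 4), np.broadcast_to(B, (f.size * n, 4))[..., None])
    z = z[..., 0].reshape(f.size, n, 4)
    return z @ grad.astype(complex)
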