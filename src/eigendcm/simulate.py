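"""Synthetic resting-state BOLD scenarios with known ground truth.

The default scenario mirrors a six-node resting-state experiment: effective
connectivity composed from fixed eigenmodes with three slow (unstable) modes
of log time constants [2, 1, 0] and three stable modes sharing log decay
eta = 1; temporally correlated neuronal fluctuations and observation noise
(AR(1), coefficient 1/2, standard deviations 1/4 and 1/8); balloon-model
haemodynamics with ~5% regional jitter of the decay and transit scales; 512
samples at a 2 s sampling interval.

Because no empirical covariance ships with the package, the generating
eigenmodes come from a fixed, documented synthetic 6x6 covariance whose
structure mimics commonly reported resting-state topographies: a positively
coupled three-node cluster, an anticorrelated pair, and a near-isolated node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .exceptions import EigenDCMError, ValidationError
from .hemodynamics import HemodynamicParams, oxygen_extraction
from .io import Timeseries
from .modes import EigenSpec, compose_jacobian, order_and_sign

__all__ = [
    "ScenarioBundle",
    "simulate_ar1",
    "simulate_bold",
    "default_scenario",
    "reference_covariance",
    "DEFAULTS",
]

#: study conditions of the default scenario
DEFAULTS = {
    "n_nodes": 6,
    "n_samples": 512,
    "sampling_interval": 2.0,
    "ar_coefficient": 0.5,
    "neuronal_sd": 0.25,
    "noise_sd": 0.125,
    "tau_true": (2.0, 1.0, 0.0),
    "log_decay": 1.0,
    "hemo_jitter_sd": 0.05,
    "steps_per_sample": 16,
}

#: conventional DCM input efficacy: driving inputs are scaled by 1/16 before
#: entering the neuronal equations.  Keeps haemodynamics in their
#: physiological regime and yields maximum signal changes of about 2% under
#: the default fluctuation amplitudes.
DRIVE_EFFICACY = 1.0 / 16.0


def reference_covariance() -> np.ndarray:
    """Fixed synthetic 6x6 covariance supplying the generating eigenmodes.

    Synthetic stand-in for an empirical resting-state covariance: nodes 0-2
    form a positively correlated cluster (r = 0.6), nodes 3 and 4 are
    anticorrelated (r = -0.6), node 5 is nearly isolated; small secondary
    couplings keep the matrix generic (distinct eigenvalues).
    """
    c = np.eye(6)
    for i, j in ((0, 1), (0, 2), (1, 2)):
        c[i, j] = c[j, i] = 0.6
    c[3, 4] = c[4, 3] = -0.6
    c[0, 3] = c[3, 0] = 0.15
    c[1, 4] = c[4, 1] = -0.10
    c[2, 5] = c[5, 2] = 0.05
    return c


def simulate_ar1(
    n_nodes: int,
    n_samples: int,
    coefficient: float,
    sd: float,
    seed,
) -> np.ndarray:
    """Independent AR(1) series per node, exactly scaled to ``sd``.

    Gaussian innovations; after generation each channel is rescaled so its
    empirical standard deviation equals ``sd`` exactly.  ``seed`` may be an
    integer or a numpy Generator.
    """
    if abs(coefficient) >= 1:
        raise ValidationError("AR(1) coefficient must satisfy |a| < 1")
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    innov = rng.standard_normal((n_samples, n_nodes))
    out = np.empty_like(innov)
    out[0] = innov[0] / np.sqrt(1.0 - coefficient ** 2)
    for t in range(1, n_samples):
        out[t] = coefficient * out[t - 1] + innov[t]
    if sd == 0:
        return np.zeros((n_samples, n_nodes))
    emp = out.std(axis=0, ddof=1)
    return out * (sd / emp)


def _joint_rhs(x, hemo_log, v_now, A, kappa, transit):
    """Derivatives of neuronal states and log-balloon states.

    ``hemo_log`` columns are (s, ln f, ln v, ln q) per region; integrating
    flow, volume and deoxyhaemoglobin in log coordinates keeps them positive
    without changing the trajectories.
    """
    s = hemo_log[:, 0]
    f = np.exp(hemo_log[:, 1])
    v = np.exp(hemo_log[:, 2])
    q = np.exp(hemo_log[:, 3])
    dx = A @ x + v_now
    ds = x - kappa * s - C.AUTOREGULATION * (f - 1.0)
    dlnf = s / f
    outflow = v ** (1.0 / C.GRUBB_EXPONENT)
    dlnv = (f - outflow) / (transit * v)
    dlnq = (f * oxygen_extraction(f) / C.E0 - outflow * q / v) / (transit * q)
    return dx, np.stack([ds, dlnf, dlnv, dlnq], axis=1)


def simulate_bold(
    spec: EigenSpec,
    theta: HemodynamicParams,
    neuronal: np.ndarray,
    noise: np.ndarray,
    sampling_interval: float,
    steps_per_sample: int = DEFAULTS["steps_per_sample"],
    drive_efficacy: float = DRIVE_EFFICACY,
    return_states: bool = False,
):
    """Integrate the coupled neuronal/balloon system and observe BOLD.

    ``neuronal`` and ``noise`` are (n_samples, n_nodes) series sampled at
    ``sampling_interval``; the neuronal drive is interpolated linearly
    between samples and scaled by the conventional input efficacy
    ``drive_efficacy`` before entering the neuronal equation.  Fixed-step
    RK4 at ``sampling_interval/steps_per_sample``.
    Returns a percent-signal :class:`~eigendcm.io.Timeseries` (plus hidden
    state trajectories at sample times when ``return_states``).
    """
    A = compose_jacobian(spec).jacobian
    neuronal = np.asarray(neuronal, dtype=float)
    noise = np.asarray(noise, dtype=float)
    n_samples, n = neuronal.shape
    if n != spec.n_nodes or noise.shape != neuronal.shape:
        raise ValidationError("neuronal/noise shapes do not match the spec")
    kappa = theta.kappa
    transit = theta.transit
    if kappa.size == 1:
        kappa = np.full(n, kappa[0])
        transit = np.full(n, transit[0])
    dt = sampling_interval / steps_per_sample
    x = np.zeros(n)
    hemo = np.zeros((n, 4))  # (s, ln f, ln v, ln q); rest state is all zeros
    bold = np.empty((n_samples, n))
    states_x = np.empty((n_samples, n)) if return_states else None
    states_h = np.empty((n_samples, n, 4)) if return_states else None

    def observe(hemo_log):
        v = np.exp(hemo_log[:, 2])
        q = np.exp(hemo_log[:, 3])
        return C.V0 * (C.K1 * (1 - q) + C.K2 * (1 - q / v) + C.K3 * (1 - v))

    scaled = drive_efficacy * neuronal

    def drive(t_cont):
        k = min(int(t_cont), n_samples - 1)
        frac = t_cont - k
        if k >= n_samples - 1:
            return scaled[n_samples - 1]
        return (1 - frac) * scaled[k] + frac * scaled[k + 1]

    for k in range(n_samples):
        bold[k] = observe(hemo)
        if return_states:
            states_x[k] = x
            states_h[k] = hemo
        if k == n_samples - 1:
            break
        for step in range(steps_per_sample):
            t_cont = k + step / steps_per_sample
            h_frac = 1.0 / steps_per_sample
            v0 = drive(t_cont)
            vh = drive(t_cont + 0.5 * h_frac)
            v1 = drive(t_cont + h_frac)
            k1x, k1h = _joint_rhs(x, hemo, v0, A, kappa, transit)
            k2x, k2h = _joint_rhs(x + 0.5 * dt * k1x, hemo + 0.5 * dt * k1h, vh, A, kappa, transit)
            k3x, k3h = _joint_rhs(x + 0.5 * dt * k2x, hemo + 0.5 * dt * k2h, vh, A, kappa, transit)
            k4x, k4h = _joint_rhs(x + dt * k3x, hemo + dt * k3h, v1, A, kappa, transit)
            x = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
            hemo = hemo + dt / 6.0 * (k1h + 2 * k2h + 2 * k3h + k4h)
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(hemo))):
                raise EigenDCMError(
                    f"integration blew up at sample {k}: "
                    f"max |x| = {np.nanmax(np.abs(x)):.3g}, "
                    f"max |hemo| = {np.nanmax(np.abs(hemo)):.3g}"
                )
    ts = Timeseries(bold + noise, sampling_interval, spec.node_labels)
    if return_states:
        return ts, states_x, states_h
    return ts


@dataclass(frozen=True)
class ScenarioBundle:
    """Ground truth plus simulated BOLD for a synthetic scenario."""

    spec: EigenSpec
    theta_true: HemodynamicParams
    neuronal: np.ndarray
    noise: np.ndarray
    bold: Timeseries
    seed: int

    @property
    def jacobian_true(self) -> np.ndarray:
        return compose_jacobian(self.spec).jacobian


def default_scenario(
    seed: int,
    n_samples: int = DEFAULTS["n_samples"],
    sampling_interval: float = DEFAULTS["sampling_interval"],
    tau_true=DEFAULTS["tau_true"],
    log_decay: float = DEFAULTS["log_decay"],
    neuronal_sd: float = DEFAULTS["neuronal_sd"],
    noise_sd: float = DEFAULTS["noise_sd"],
    ar_coefficient: float = DEFAULTS["ar_coefficient"],
    hemo_jitter_sd: float = DEFAULTS["hemo_jitter_sd"],
) -> ScenarioBundle:
    """Simulate the six-node default scenario, bit-reproducible from the seed.

    One seed sequence is split into named substreams (neuronal fluctuations,
    observation noise, haemodynamic jitter) so each ingredient is independent
    yet reproducible.
    """
    cov = reference_covariance()
    w, v = np.linalg.eigh(cov)
    w, modes = order_and_sign(w, v)
    spec = EigenSpec(modes, np.asarray(tau_true, dtype=float), float(log_decay))
    streams = np.random.SeedSequence(seed).spawn(3)
    rng_neuronal = np.random.default_rng(streams[0])
    rng_noise = np.random.default_rng(streams[1])
    rng_jitter = np.random.default_rng(streams[2])
    n = spec.n_nodes
    neuronal = simulate_ar1(n, n_samples, ar_coefficient, neuronal_sd, rng_neuronal)
    noise = simulate_ar1(n, n_samples, ar_coefficient, noise_sd, rng_noise)
    theta = HemodynamicParams(
        rng_jitter.normal(0.0, hemo_jitter_sd, size=n),
        rng_jitter.normal(0.0, hemo_jitter_sd, size=n),
    )
    bold = simulate_bold(spec, theta, neuronal, noise, sampling_interval)
    return ScenarioBundle(spec, theta, neuronal, noise, bold, seed)
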