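"""Variational Laplace: Gaussian posteriors and free-energy model evidence.

The observation model is ``y = g(psi) + e`` with feature residual precision
``Pi_e = exp(beta) Q^{-1}`` and Gaussian priors ``psi ~ N(psi_0, S_0)``.
Under the Laplace (fixed-form Gaussian) assumption the negative free energy

    F = -1/2 e' Pi_e e + 1/2 ln|Pi_e| - 1/2 d' Pi_0 d + 1/2 ln|Pi_0|
        - 1/2 ln|H| - (n/2) ln 2 pi,        d = psi - psi_0,

with ``H`` the curvature (negative Hessian) of the log joint at the mode, is
a lower bound on log evidence, exact for linear-Gaussian models.  The mode is
found by Gauss-Newton ascent with Levenberg-style damping and step rejection;
``beta`` is updated jointly (its likelihood gradient and curvature are
analytic because the prediction does not depend on it).

Parameters with zero prior variance are fixed at their prior mean and
excluded from the free subspace (this is how stable modes are pinned at
``tau = -eta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, ValidationError
from .generative import FeatureErrorModel, Priors

__all__ = ["VLOptions", "Posterior", "free_energy", "fit_variational_laplace"]

LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class VLOptions:
    """Settings for the Gauss-Newton/Levenberg free-energy ascent."""

    max_iter: int = 128
    tol: float = 0.01            # nats; convergence threshold on dF
    converged_streak: int = 4    # consecutive small accepted improvements
    fd_step: float = 2.0 ** -6   # central finite-difference step
    damping: float = 1.0 / 128.0 # initial Levenberg factor
    max_rejects: int = 8         # consecutive rejections before stopping
    n_starts: int = 1            # seeded multi-start (1 = prior mean only)
    start_jitter: float = 0.5    # prior-sd multiples for extra starts


@dataclass(frozen=True)
class Posterior:
    """Gaussian posterior over the flat parameter vector plus evidence."""

    mean: np.ndarray
    covariance: np.ndarray
    free_energy: float
    trace: np.ndarray
    converged: bool = True
    n_iter: int = 0
    hit_max_iter: bool = False

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "trace", np.asarray(self.trace, dtype=float))
        if not np.isfinite(self.free_energy):
            raise ValidationError("free energy must be finite")
        cov = self.covariance
        if np.abs(cov - cov.T).max() > 1e-8 * max(1.0, np.abs(cov).max()):
            raise ValidationError("posterior covariance must be symmetric")


class _Objective:
    """Shared machinery for F, gradients and curvature on the free subspace."""

    def __init__(self, data_features, predict, priors: Priors,
                 error_model: FeatureErrorModel, beta_index: int,
                 fd_step: float):
        self.y = np.asarray(data_features, dtype=float)
        self.predict = predict
        self.priors = priors
        self.error = error_model
        self.free = np.flatnonzero(priors.free)
        self.beta_index = beta_index
        self.beta_free_pos = None
        if beta_index is not None and priors.free[beta_index]:
            self.beta_free_pos = int(np.searchsorted(self.free, beta_index))
        self.pi0 = 1.0 / priors.variance[self.free]
        self.logdet_pi0 = float(np.sum(np.log(self.pi0)))
        self.fd_step = fd_step
        self.n = self.y.size
        self.n_eval = 0

    def residual(self, psi: np.ndarray) -> np.ndarray:
        g = self.predict(psi)
        self.n_eval += 1
        if g.shape != self.y.shape:
            raise ValidationError(
                f"prediction length {g.shape} does not match data {self.y.shape}"
            )
        if not np.all(np.isfinite(g)):
            raise ConvergenceError(
                "non-finite prediction; parameters (free subspace): "
                f"{np.array2string(psi[self.free], precision=3)}"
            )
        return g - self.y

    def jacobian(self, psi: np.ndarray) -> np.ndarray:
        """Central finite-difference Jacobian over free parameters.

        The beta column is identically zero (beta does not enter the
        prediction) and is skipped.
        """
        J = np.zeros((self.n, self.free.size))
        h = self.fd_step
        for col, idx in enumerate(self.free):
            if idx == self.beta_index:
                continue
            dp = np.zeros_like(psi)
            dp[idx] = h
            J[:, col] = (self.residual(psi + dp) - self.residual(psi - dp)) / (2 * h)
        return J

    def curvature_terms(self, psi, e, J):
        """Gradient and curvature (negative Hessian) of the log joint."""
        beta = float(psi[self.beta_index]) if self.beta_index is not None else 0.0
        prec = np.exp(beta) * self.error.q_precision  # sparse
        pe = prec @ e
        sse = float(e @ pe)
        d = (psi - self.priors.mean)[self.free]
        grad = -(J.T @ pe) - self.pi0 * d
        M = J.T @ (prec @ J)
        M[np.diag_indices_from(M)] += self.pi0
        if self.beta_free_pos is not None:
            # beta block: analytic gradient; Gauss-Newton curvature keeps the
            # diagonal only, which preserves positive definiteness
            b = self.beta_free_pos
            grad[b] = -0.5 * sse + 0.5 * self.n - self.pi0[b] * d[b]
            M[b, :] = 0.0
            M[:, b] = 0.0
            M[b, b] = 0.5 * sse + self.pi0[b]
        return grad, M, sse

    def free_energy(self, psi, e, M):
        beta = float(psi[self.beta_index]) if self.beta_index is not None else 0.0
        prec = np.exp(beta) * self.error.q_precision
        sse = float(e @ (prec @ e))
        d = (psi - self.priors.mean)[self.free]
        sign, logdet_m = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf
        return (
            -0.5 * sse
            + 0.5 * self.error.logdet_precision(beta)
            - 0.5 * float(d * self.pi0 @ d)
            + 0.5 * self.logdet_pi0
            - 0.5 * logdet_m
            - 0.5 * self.n * LOG2PI
        )


def free_energy(
    psi: np.ndarray,
    data_features: np.ndarray,
    priors: Priors,
    predict,
    error_model: FeatureErrorModel,
    beta_index: int = None,
    fd_step: float = VLOptions.fd_step,
) -> float:
    """Negative free energy (log-evidence bound) at a parameter vector.

    ``predict`` maps the full flat vector to a feature vector; ``beta_index``
    locates the sampling-error log precision inside the vector (None for a
    fixed unit-precision error model).  Exact for linear-Gaussian models when
    evaluated at the posterior mode.
    """
    obj = _Objective(data_features, predict, priors, error_model, beta_index, fd_step)
    e = obj.residual(np.asarray(psi, dtype=float))
    J = obj.jacobian(np.asarray(psi, dtype=float))
    _, M, _ = obj.curvature_terms(np.asarray(psi, dtype=float), e, J)
    return obj.free_energy(np.asarray(psi, dtype=float), e, M)


def _ascend(obj: _Objective, psi0: np.ndarray, options: VLOptions):
    psi = psi0.copy()
    e = obj.residual(psi)
    J = obj.jacobian(psi)
    grad, M, _ = obj.curvature_terms(psi, e, J)
    F = obj.free_energy(psi, e, M)
    if not np.isfinite(F):
        raise ConvergenceError(f"initial free energy is not finite (F={F})")
    trace = [F]
    nu = options.damping
    streak = 0
    rejects = 0
    hit_max = True
    for it in range(options.max_iter):
        damped = M + nu * np.diag(np.diag(M))
        try:
            step = np.linalg.solve(damped, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(damped, grad, rcond=None)[0]
        psi_new = psi.copy()
        psi_new[obj.free] += step
        try:
            e_new = obj.residual(psi_new)
            J_new = obj.jacobian(psi_new)
            g_new, M_new, _ = obj.curvature_terms(psi_new, e_new, J_new)
            F_new = obj.free_energy(psi_new, e_new, M_new)
        except ConvergenceError:
            F_new = -np.inf
        if np.isfinite(F_new) and F_new >= F:
            dF = F_new - F
            psi, e, J, grad, M, F = psi_new, e_new, J_new, g_new, M_new, F_new
            trace.append(F)
            nu = max(nu / 2.0, 1.0 / 1024.0)
            rejects = 0
            streak = streak + 1 if dF < options.tol else 0
            if streak >= options.converged_streak:
                hit_max = False
                break
        else:
            nu *= 4.0
            rejects += 1
            if rejects >= options.max_rejects:
                hit_max = False
                break
    return psi, M, F, np.asarray(trace), hit_max


def fit_variational_laplace(
    data_features: np.ndarray,
    predict,
    priors: Priors,
    error_model: FeatureErrorModel,
    beta_index: int = None,
    options: VLOptions = VLOptions(),
    seed: int = 0,
    start: np.ndarray = None,
) -> Posterior:
    """Fit the Gaussian posterior by Gauss-Newton ascent on free energy.

    Starts at the prior mean, or at ``start`` when given (e.g. a data-scale
    initialisation), plus ``options.n_starts - 1`` seeded jittered restarts,
    keeping the best evidence.  Fixed (zero-prior-variance) entries of
    ``start`` are reset to their prior mean.  Returns the posterior over the
    full vector; fixed parameters keep their prior mean and zero variance.
    """
    obj = _Objective(data_features, predict, priors, error_model,
                     beta_index, options.fd_step)
    rng = np.random.default_rng(seed)
    sd = np.sqrt(priors.variance[obj.free])
    base = priors.mean.copy()
    if start is not None:
        base[obj.free] = np.asarray(start, dtype=float)[obj.free]
    best = None
    for k_start in range(max(1, options.n_starts)):
        psi0 = base.copy()
        if k_start > 0:
            psi0[obj.free] += options.start_jitter * sd * rng.standard_normal(sd.size)
        result = _ascend(obj, psi0, options)
        if best is None or result[2] > best[2]:
            best = result
    psi, M, F, trace, hit_max = best
    cov_free = np.linalg.inv(M)
    cov_free = 0.5 * (cov_free + cov_free.T)
    cov = np.zeros((priors.mean.size, priors.mean.size))
    cov[np.ix_(obj.free, obj.free)] = cov_free
    if hit_max:
        import warnings

        warnings.warn("variational Laplace hit the iteration limit before "
                      "meeting the convergence criterion")
    return Posterior(
        mean=psi, covariance=cov, free_energy=F, trace=trace,
        converged=not hit_max, n_iter=len(trace) - 1, hit_max_iter=hit_max,
    )
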