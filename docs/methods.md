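# Methods

## Model

`eigendcm` fits a linear stochastic network model to the second-order
statistics of multi-region BOLD timeseries. Hidden neuronal states obey
`dx/dt = A x + v` with a symmetric, negative-definite effective connectivity
`A` (Hz). Symmetry lets `A = mu diag(lambda) mu'` with orthonormal modes `mu`
and real negative Lyapunov exponents `lambda`. The central identity exploited
throughout is that the stationary covariance of `x` is
`Sigma_x = mu diag(Gamma tau) mu'` with `tau_i = -1/lambda_i`
(equivalently `A = -Gamma Sigma_x^{-1}`): functional and effective
connectivity share eigenmodes, and slow modes dominate covariance. Slow
("unstable") modes carry free log time constants `tau_i` with
`lambda_i = -exp(-tau_i)`; the remaining stable modes share one fixed log
decay `eta`, `lambda = -exp(eta)`.

The observation model passes each region's neuronal state through the
standard balloon model (vasodilatory signal, flow, volume, deoxyhaemoglobin;
constants in `eigendcm.constants`: decay 0.64 s^-1, autoregulation
0.32 s^-1, transit 2 s, Grubb exponent 0.32, resting extraction 0.4, resting
volume 4%, echo time 40 ms with the standard observer coefficients). Only
the log scales of decay (`ln a`) and transit (`ln b`) are free, per region,
with N(0, e^-6) priors. For the spectral model the balloon system is
linearised at its resting fixed point, giving a per-region low-pass transfer
function `H(w)`; its Jacobian is obtained by central differences on the
exact equations (step 1e-6), which is accurate to rounding for this smooth
4-state system.

Predicted cross spectra of the observations are

    g_y(w) = H(w) K(w) [g_v(w) + C g_u(w) C'] K(w)* H(w)* + g_w(w)

with neuronal transfer `K(w) = mu (jw - lambda)^{-1} mu'`. Neuronal
fluctuations `g_v` and observation noise `g_w` are power laws
`scale · exp(amp_r) (f / 1 Hz)^{-b}` with per-region log amplitudes and one
shared exponent for each of the two sources (shared exponents reduce
non-identifiability). The optional `C g_u C'` term injects the spectral
density of exogenous experimental input for activation paradigms. All
user-facing frequency grids are in Hz; angular frequency `w = 2 pi f` is
used internally.

Two fixed reference densities anchor the amplitude parameters
(`NEURONAL_DENSITY_SCALE = 1.5e-3`, `NOISE_DENSITY_SCALE = 9.4e-2`
signal^2/Hz). The amplitude priors are deliberately tight (below), so
"amplitude = 0" must correspond to realistic percent-BOLD magnitudes; the
constants are derived from the default study conditions (endogenous AR(1)
drive of sd 1/4 at 2 s bins under the conventional 1/16 input efficacy;
observation noise of sd 1/8). Without such anchors a tight-prior amplitude
block cannot reach the data scale and the inversion degenerates into a
"large sampling error" optimum.

## Data features and sampling-error model

The data are reduced to complex cross spectra on 32 uniform frequencies from
`1/(T dt)` to `0.25/dt` Hz and cross-covariance functions on 32 lags of one
sample each (defaults; both configurable). The spectral estimator is a
multivariate autoregressive (MAR) fit of order 8 via `statsmodels`' VAR
(no trend, detrended input), converted to cross spectra; a nonparametric
Welch estimator is available (`estimator="welch"`). Cross-covariances are
obtained from the cross spectra by a band-limited Fourier quadrature whose
least-squares inverse makes `csd -> ccf -> csd` an identity on matched
grids. The feature vector stacks real and imaginary csd parts (upper
triangle, one contiguous frequency run per pair) and the full ccf matrix per
lag; spectral densities are tabulated per angular frequency so both halves
share a common magnitude scale.

Feature residuals are modelled as Gaussian with covariance `exp(-beta) Q`.
`Q` is block diagonal with AR(1) correlation (rho = 1/2) over adjacent
frequencies or lags within each (pair, part) block, and each block carries a
fixed variance scale equal to the block's observed mean-square feature value
(plus a floor of (0.1 x overall rms)^2). The magnitude-proportional scales
encode the statistical fact that the sampling error of a spectral estimate
grows with the spectrum itself (approximately constant relative error). This
choice matters: with unit block variances the huge low-frequency bins
receive implausibly high relative precision, and over-parameterised mode
structures can profitably absorb estimator noise, flattening the evidence
curve over `m`.

## Priors, inversion and model comparison

Priors (Gaussian, diagonal): `tau ~ N(0, 1)` for the `m` unstable modes
(stable modes fixed at `-eta` with zero variance — only `m` connectivity
parameters are estimated even though `A` has N(N+1)/2 free entries);
amplitudes and exponents `~ N(0, 1/64)`; sampling-error log precision
`beta ~ N(4, 1/64)`; input scaling `C ~ N(0, 1)`; `ln a, ln b ~ N(0, e^-6)`.

Inversion is variational Laplace: Gauss-Newton ascent on the negative free
energy

    F = -1/2 e' Pi_e e + 1/2 ln|Pi_e| - 1/2 d' Pi_0 d + 1/2 ln|Pi_0|
        - 1/2 ln|H| - (n/2) ln 2 pi

with Levenberg-style damping and step rejection; accepted steps never lower
F, and convergence is declared after 4 consecutive accepted improvements
below 0.01 nats (cap 128 iterations). Prediction gradients use central
finite differences (step 2^-6 in each parameter). `beta` is updated jointly
with the other parameters; its gradient and curvature are analytic (it does
not enter the prediction), and only its diagonal curvature is kept, which
preserves positive definiteness of the Gauss-Newton matrix. The ascent
starts from a cheap data-scale moment match (noise amplitudes from the
highest-frequency spectral floor; one common neuronal-amplitude shift
matching total diagonal power); priors are unaffected by the start. `F` is
exact for linear-Gaussian models, which the test suite verifies against the
conjugate closed form.

Model comparison sweeps the number of unstable modes `m = 1..N` and the
stable log decay `eta` (default grid 0..2 in steps of 0.25), re-inverting
the identical feature vector under each structure and comparing `F`
(posterior model probabilities are a softmax under uniform model priors).

## Synthetic scenarios

`default_scenario(seed)` reproduces the reference simulation: 6 nodes, 512
samples at 2 s; neuronal fluctuations and observation noise are AR(1)
series (coefficient 1/2) scaled exactly to sd 1/4 and 1/8; true log time
constants [2, 1, 0] (time constants 7.4, 2.7, 1.0 s) with stable log decay
`eta = 1`; haemodynamic log scales jittered N(0, 0.05^2) per region. The
generating eigenmodes come from a fixed, documented synthetic 6x6 covariance
(`reference_covariance`): a positively coupled three-node cluster, an
anticorrelated pair, and a near-isolated node. One seed sequence is split
into named substreams (drive, noise, jitter), so bundles are bit-reproducible.

Integration is fixed-step RK4 at 1/16 of the sampling interval, with flow,
volume and deoxyhaemoglobin integrated in log coordinates (identical
trajectories, guaranteed positivity); halving the step changes the output by
less than 0.1%. The discrete fluctuation series is interpolated linearly
between samples and scaled by the conventional DCM input efficacy of 1/16
before entering the neuronal equation — with unit efficacy the sustained
slow-mode excursions would drive flow to zero (the balloon model leaves its
physiological regime), whereas with the conventional efficacy the simulation
produces the intended maximum signal changes of about 2%.

What the scenario emulates: realistic second-order structure (slow-mode
dominated spectra, haemodynamic smoothing, measurement noise) under a known
ground truth. What it does not: nonstationarity, physiological confounds,
spatially correlated noise, asymmetric coupling, or raw-volume preprocessing.
Passing the recovery tests therefore shows the estimator is consistent with
its own model class under realistic magnitudes, not that real fMRI satisfies
the model.

## Numerical choices and known limitations

- Eigenvalue ordering is by descending data eigenvalue, with the
  largest-magnitude eigenvector component made positive; ties break by first
  non-negligible component. All validation tolerances live in one table
  (`eigendcm.constants.TOL`).
- Degenerate structures `m = 0` (pure isotropic decay) and `m = N` (no
  stable block) are supported.
- The power-law module evaluates the Lorentzian-mixture integral with
  adaptive quadrature (absolute tolerance 1e-10). At a finite lower bound
  `eps` the mixture equals `(eps/w) arctan(1/(eps w))`; its deviation from
  the `eps -> 0` limit `eps pi/(2w)` is `(2/pi) arctan(2 pi f eps)` — about
  4% at 10 Hz for `eps = 1e-3` — so comparisons against the limit must use
  either small `eps x f` products or the closed form.
- Laplace posterior intervals on the nonlinear spectral model are
  substantially overconfident (strong posterior correlations among the few
  estimated parameters; estimator bias outside the stated uncertainty).
  The interval machinery is calibrated in the linear-Gaussian limit, and the
  credible intervals on `A` should be read as relative, not frequentist,
  uncertainty.
- The evidence profile over `eta` is nearly flat above ~0.5 because stable
  modes contribute little in-band power; `eta` is a structural sweep
  variable here, not an estimated parameter.
- On clean block-structured synthetic systems the thresholded effective and
  functional adjacencies can coincide; the "filling in" of sparse effective
  connectivity by functional correlations appears for chain-like or
  heterogeneous couplings (unit-tested on a chain system).
- Asymmetric (complex-eigenvalue) connectivity and hierarchical extensions
  are out of scope; the symmetry constraint is what buys the eigenmode
  parameterisation.
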