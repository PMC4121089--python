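"""Numerical tolerances and fixed physical constants.

All tolerances used by validation code live in ``TOL`` so that every module
draws on a single table.  Balloon-model constants follow the standard DCM
haemodynamic model for 2 T gradient-echo data; only the decay and transit
scales carry free (log-scale) parameters.
"""

# -- validation tolerances ---------------------------------------------------
TOL = {
    "orthonormal": 1e-10,      # |modes' modes - I|
    "symmetry": 1e-10,         # max asymmetry of composed Jacobians
    "hermitian": 1e-8,         # csd slices
    "eigen_roundtrip": 1e-8,   # eigendecomposition round trips
    "fourier_roundtrip": 1e-6, # csd <-> ccf round trips (band-limited)
    "psd": 1e-10,              # eigenvalue floor for PSD checks (relative)
}

# -- balloon model (per-region haemodynamics) --------------------------------
#: neurovascular signal decay rate at ln a = 0 (1/s)
KAPPA = 0.64
#: flow autoregulation rate (1/s)
AUTOREGULATION = 0.32
#: mean transit time at ln b = 0 (s)
TRANSIT_TIME = 2.0
#: Grubb's vessel stiffness exponent
GRUBB_EXPONENT = 0.32
#: resting oxygen extraction fraction
E0 = 0.4
#: resting venous volume fraction, in percent signal units
V0 = 4.0
#: echo time (s)
ECHO_TIME = 0.04
#: frequency offset of the outer-surface magnetised vessel (1/s), 1.5 T-derived
NU0 = 40.3
#: slope of intravascular relaxation rate with oxygen saturation (1/s)
R0 = 25.0
#: ratio of intra- to extravascular signal
EPSILON_RATIO = 1.0

# observer coefficients (Buxton/Obata form used throughout DCM for fMRI)
K1 = 4.3 * NU0 * E0 * ECHO_TIME
K2 = EPSILON_RATIO * R0 * E0 * ECHO_TIME
K3 = 1.0 - EPSILON_RATIO
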