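"""Scaling space: metric multidimensional scaling of network nodes.

Principal-coordinates analysis of a covariance matrix places each node on a
hypersphere such that the correlation between two nodes is the cosine of the
angle they subtend at the centre: perfectly correlated nodes coincide,
anticorrelated nodes are antipodal, uncorrelated nodes are orthogonal.
The leading dimensions of this space correspond to the slow eigenmodes, so
its dimensionality is the number of unstable modes.  Also provided: the
effective-vs-functional sparsity comparison and per-mode time-constant
reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .modes import EigenSpec, order_and_sign

__all__ = [
    "ScalingCoordinates",
    "mds_coordinates",
    "effective_vs_functional",
    "time_constant_report",
]


@dataclass(frozen=True)
class ScalingCoordinates:
    """Node positions in scaling space.

    ``coordinates`` are unit-normalised rows (nodes on the unit sphere);
    ``loadings`` are the raw eigenvalue-weighted principal coordinates
    ``mu sqrt(gamma)`` restricted to the leading dimensions.
    """

    coordinates: np.ndarray
    loadings: np.ndarray
    dimension: int
    node_labels: tuple

    def cosines(self) -> np.ndarray:
        """Pairwise cosines of the (normalised) node positions."""
        return self.coordinates @ self.coordinates.T


def mds_coordinates(
    covariance: np.ndarray, m: int = None, node_labels=None, normalise_input: bool = True
) -> ScalingCoordinates:
    """Principal-coordinates embedding of nodes from a covariance matrix.

    With the full dimension ``m = N`` the pairwise cosines of the coordinates
    equal the correlations exactly; truncation to leading dimensions keeps
    the slow-mode geometry.  ``normalise_input`` converts covariance to
    correlation first, so all nodes lie on a common-radius hypersphere.
    """
    S = np.atleast_2d(np.asarray(covariance, dtype=float))
    n = S.shape[0]
    if S.shape != (n, n) or np.abs(S - S.T).max() > 1e-8 * max(1.0, np.abs(S).max()):
        raise ValidationError("covariance must be square symmetric")
    if normalise_input:
        d = np.sqrt(np.diag(S))
        if np.any(d <= 0):
            raise ValidationError("covariance has non-positive diagonal")
        S = S / np.outer(d, d)
    w, v = np.linalg.eigh(S)
    w, v = order_and_sign(np.clip(w, 0.0, None), v)
    rank = int(np.sum(w > 1e-12 * max(w.max(), 1.0)))
    if m is None:
        m = rank
    if m > rank:
        raise ValidationError(f"requested dimension {m} exceeds rank {rank}")
    load_full = v * np.sqrt(w)
    loadings = load_full[:, :m]
    norms = np.linalg.norm(loadings, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    coords = loadings / norms
    if node_labels is None:
        node_labels = tuple(f"node{i}" for i in range(n))
    return ScalingCoordinates(coords, loadings, int(m), tuple(node_labels))


def effective_vs_functional(
    jacobian: np.ndarray,
    covariance: np.ndarray,
    effective_threshold: float = 0.3,
    functional_threshold: float = 0.3,
) -> dict:
    """Compare sparsity of effective and functional connectivity.

    Thresholds the absolute off-diagonal effective connectivity (Hz) and the
    functional correlations; reports edge counts, the binary adjacencies and
    how many weak effective connections appear as strong functional ones
    (the "filling in" of sparse effective coupling).
    """
    A = np.atleast_2d(np.asarray(jacobian, dtype=float))
    S = np.atleast_2d(np.asarray(covariance, dtype=float))
    if A.shape != S.shape:
        raise ValidationError("jacobian and covariance shapes differ")
    d = np.sqrt(np.diag(S))
    corr = S / np.outer(d, d)
    off = ~np.eye(A.shape[0], dtype=bool)
    eff_adj = (np.abs(A) >= effective_threshold) & off
    fun_adj = (np.abs(corr) >= functional_threshold) & off
    return {
        "effective_adjacency": eff_adj,
        "functional_adjacency": fun_adj,
        "n_effective_edges": int(eff_adj.sum() // 2),
        "n_functional_edges": int(fun_adj.sum() // 2),
        "weak_effective_strong_functional": int((~eff_adj & fun_adj & off).sum() // 2),
        "correlation": corr,
    }


def time_constant_report(source, level: float = 0.90, n_samples: int = 4000) -> pd.DataFrame:
    """Unstable-mode time constants, descending, with intervals if available.

    ``source`` may be an :class:`~eigendcm.modes.EigenSpec` (point estimates
    only) or a fitted :class:`~eigendcm.model.SpectralDCMResults` (posterior
    intervals from the Gaussian posterior over log time constants).
    """
    if isinstance(source, EigenSpec):
        tc = np.exp(source.log_time_constants)
        order = np.argsort(-tc, kind="stable")
        return pd.DataFrame(
            {"mode": order, "time_constant": tc[order],
             "lower": tc[order], "upper": tc[order]}
        ).reset_index(drop=True)
    if hasattr(source, "time_constants"):
        table = source.time_constants(level=level, n_samples=n_samples)
        return table.sort_values(
            "time_constant", ascending=False, kind="stable"
        ).reset_index(drop=True)
    raise ValidationError("source must be an EigenSpec or fitted results object")
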