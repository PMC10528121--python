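"""Continuous-time Markov (birth-death) random walk over reliability levels.

The classical model assumes the participant occupies a *definite*
reliability level at every instant and hops only between neighbouring
levels.  Dynamics are generated by a tridiagonal intensity matrix K and the
Kolmogorov forward equation dphi/dt = K phi, solved by the matrix
exponential phi(t) = exp(tK) phi(0).

K is built column-oriented: column j holds the probability flow out of
state j (rate ``beta_plus`` upward, ``beta_minus`` downward, diagonal
-alpha with alpha = beta_plus + beta_minus), with reflecting boundaries so
every column sums to zero and probability is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .state_space import MarkovState, StateSpace

__all__ = [
    "IntensityParams",
    "IntensityMatrix",
    "build_intensity_matrix",
    "evolve_markov",
    "markov_predict",
    "stationary_distribution",
]

_COLSUM_TOL = 1e-12


@dataclass(frozen=True)
class IntensityParams:
    """Rates of the birth-death walk.

    ``beta_plus`` is the intensity to move one level up (evidence the AI is
    reliable accruing), ``beta_minus`` to move one level down.  The
    self-intensity to leave the current level is their sum,
    ``alpha = beta_plus + beta_minus``.
    """

    beta_plus: float = 0.6
    beta_minus: float = 0.4

    def __post_init__(self) -> None:
        if not (self.beta_plus > 0 and self.beta_minus > 0):
            raise ValueError(
                f"rates must be positive, got beta_plus={self.beta_plus}, "
                f"beta_minus={self.beta_minus}"
            )

    @property
    def alpha(self) -> float:
        return self.beta_plus + self.beta_minus


@dataclass(frozen=True)
class IntensityMatrix:
    """Tridiagonal generator K with its parameters and state space."""

    K: np.ndarray
    params: IntensityParams
    space: StateSpace

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        n = self.space.n
        if K.shape != (n, n):
            raise ValueError(f"K must be {n}x{n}, got {K.shape}")
        if np.any(np.abs(K[np.abs(np.subtract.outer(range(n), range(n))) > 1]) > 0):
            raise ValueError("K must be tridiagonal")
        if np.any(np.abs(K.sum(axis=0)) > _COLSUM_TOL):
            raise ValueError("every column of K must sum to zero")
        off = K[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal intensities must be non-negative")


def build_intensity_matrix(
    params: IntensityParams, space: StateSpace
) -> IntensityMatrix:
    """Assemble the birth-death generator on ``space``.

    Interior column j: K[j+1, j] = beta_plus, K[j-1, j] = beta_minus,
    K[j, j] = -alpha.  Boundary columns drop the out-of-range flow and
    adjust the diagonal (-beta_plus at state 0, -beta_minus at state n-1)
    so each column still sums to zero.
    """
    n = space.n
    bp, bm = params.beta_plus, params.beta_minus
    K = np.zeros((n, n))
    for j in range(n):
        if j + 1 < n:
            K[j + 1, j] = bp
        if j - 1 >= 0:
            K[j - 1, j] = bm
        K[j, j] = -(bp * (j + 1 < n) + bm * (j - 1 >= 0))
    return IntensityMatrix(K=K, params=params, space=space)


def evolve_markov(phi0: MarkovState, K: IntensityMatrix, t: float) -> MarkovState:
    """Evolve a probability vector for time ``t``: phi(t) = exp(tK) phi(0).

    Probability is conserved to better than 1e-9 (the column-zero-sum
    structure of K makes exp(tK) a stochastic matrix up to rounding).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if phi0.n != K.space.n:
        raise ValueError(f"state has {phi0.n} entries but K is for n={K.space.n}")
    probs = expm(t * K.K) @ phi0.probs
    # rounding can leave entries at ~ -1e-16; clip within the invariant tolerance
    probs = np.where(np.abs(probs) < 1e-12, np.abs(probs), probs)
    return MarkovState(probs, time=phi0.time + t)


def markov_predict(phi: MarkovState) -> np.ndarray:
    """Predicted rating distribution: P(R = i) is the occupancy p_i itself."""
    return phi.probs.copy()


def stationary_distribution(params: IntensityParams, space: StateSpace) -> np.ndarray:
    """Long-time limit of the walk: pi_i proportional to (beta_plus/beta_minus)^i.

    Follows from detailed balance of the birth-death chain with reflecting
    boundaries.
    """
    ratio = params.beta_plus / params.beta_minus
    pi = ratio ** np.arange(space.n)
    return pi / pi.sum()
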