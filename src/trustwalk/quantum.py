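"""Quantum random walk over reliability levels.

The quantum model treats the reliability judgement as *indeterminate*
between measurements: the cognitive state is a superposition over all
levels, evolved unitarily by a Hamiltonian H via the Schroedinger equation
dpsi/dt = -iH psi, i.e. psi(t) = exp(-itH) psi(0).  Asking for a rating
collapses the superposition; the probability of reporting level i is the
squared amplitude |psi_i|^2 (Born rule).

H is real symmetric with three ingredients:

* diagonal ``mu_slope * i`` — a linearly increasing potential that drives
  amplitude toward higher reliability levels, modelling the (contrived)
  tendency of the Wizard-of-Oz AI to agree with the participant;
* super/sub-diagonal ``sigma2`` — diffusion of amplitude to neighbouring
  levels, the wave analogue of the classical hop rates;
* corners H[0, n-1] = H[n-1, 0] = ``z`` — a novel coupling between the two
  extreme levels, letting high reliability expectations collapse abruptly
  to low ones (and vice versa) without traversing intermediate levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .state_space import StateSpace, WaveState

__all__ = [
    "HamiltonianParams",
    "Hamiltonian",
    "build_hamiltonian",
    "evolve_quantum",
    "born_probabilities",
]


@dataclass(frozen=True)
class HamiltonianParams:
    mu_slope: float = 0.05
    sigma2: float = 0.7
    z: float = 0.2

    def __post_init__(self) -> None:
        for name in ("mu_slope", "sigma2", "z"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.z < 0:
            raise ValueError(f"z must be >= 0, got {self.z}")


@dataclass(frozen=True)
class Hamiltonian:
    H: np.ndarray
    params: HamiltonianParams
    space: StateSpace

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        n = self.space.n
        if H.shape != (n, n):
            raise ValueError(f"H must be {n}x{n}, got {H.shape}")
        if not np.array_equal(H, H.T):
            raise ValueError("H must be exactly symmetric")


def build_hamiltonian(params: HamiltonianParams, space: StateSpace) -> Hamiltonian:
    """Assemble H: diagonal potential, neighbour diffusion, corner coupling.

    With the defaults (mu_slope=0.05, sigma2=0.7, z=0.2) on n=11 this is the
    published analysis matrix: diagonal 0, 0.05, ..., 0.50, off-diagonals
    0.7, corners 0.2.  The corner coupling is applied only for n >= 3 (at
    n = 2 the corner cell *is* the ordinary off-diagonal).
    """
    n = space.n
    H = np.zeros((n, n))
    idx = np.arange(n)
    H[idx, idx] = params.mu_slope * idx
    H[idx[:-1], idx[:-1] + 1] = params.sigma2
    H[idx[:-1] + 1, idx[:-1]] = params.sigma2
    if n >= 3:
        H[0, n - 1] = params.z
        H[n - 1, 0] = params.z
    return Hamiltonian(H=H, params=params, space=space)


def _propagate(psi: np.ndarray, H: Hamiltonian, t: float) -> np.ndarray:
    """exp(-itH) @ psi via the spectral decomposition of the symmetric H."""
    w, V = eigh(H.H)
    return (V * np.exp(-1j * t * w)) @ (V.T @ psi)


def evolve_quantum(psi0: WaveState, H: Hamiltonian, t: float) -> WaveState:
    """Evolve an amplitude vector for time ``t``: psi(t) = exp(-itH) psi(0).

    Evolution is unitary (H is symmetric), so the squared-modulus sum is
    conserved to better than 1e-9.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if psi0.n != H.space.n:
        raise ValueError(f"state has {psi0.n} entries but H is for n={H.space.n}")
    return WaveState(_propagate(psi0.amps, H, t), time=psi0.time + t)


def born_probabilities(psi: WaveState) -> np.ndarray:
    """Born-rule readout: P(R = i) = |psi_i|^2."""
    return np.abs(psi.amps) ** 2
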