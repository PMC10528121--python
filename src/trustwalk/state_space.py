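"""Discrete reliability state space, rating binning, and initial-state vectors.

A participant's judgement of an AI system's reliability is modelled on a
coarse discrete scale of ``n`` levels (0 = totally unreliable, n-1 = fully
reliable).  Continuous slider ratings on 0-100 are binned onto an 11-level
scale, and both dynamical models (the classical birth-death random walk and
the quantum random walk) start from either a uniform state vector or a
7-point symmetric stencil centred on the participant's first post-practice
rating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSpace",
    "RatingObservation",
    "MarkovState",
    "WaveState",
    "RAW_MARKOV_STENCIL",
    "RAW_QUANTUM_STENCIL",
    "map_rating_to_state",
    "state_to_rating",
    "uniform_initial",
    "weighted_initial",
]

#: 7-point probability stencil for the weighted classical initial state,
#: centred on the start state (values as published; sums to 1.015).
RAW_MARKOV_STENCIL = np.array([0.025, 0.0625, 0.17, 0.5, 0.17, 0.0625, 0.025])

#: 7-point amplitude stencil for the weighted quantum initial state
#: (squared norm 1.0133).
RAW_QUANTUM_STENCIL = np.array([0.17, 0.24, 0.41, 0.71, 0.41, 0.24, 0.17])

_STENCIL_REACH = 3  # three neighbour states either side of the start state

_PROB_TOL = 1e-9
_NONNEG_TOL = 1e-12


@dataclass(frozen=True)
class StateSpace:
    """The discrete reliability scale: states 0 ... n-1.

    Parameters
    ----------
    n
        Number of basis states.  The published analysis uses ``n=11``
        (states 0..10); the expository two-model walkthrough uses ``n=5``.
    """

    n: int = 11

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 2:
            raise ValueError(f"state space needs an integer n >= 2, got {self.n!r}")

    @property
    def labels(self) -> np.ndarray:
        """State indices 0 ... n-1."""
        return np.arange(self.n)


@dataclass(frozen=True)
class RatingObservation:
    """One reliability rating: raw percent plus its mapped discrete state.

    ``block_index`` 0 is the post-practice rating; -1 marks the pre-practice
    rating taken before any interaction; blocks 1..n_blocks follow.
    """

    block_index: int
    raw_rating: float
    state: int

    def __post_init__(self) -> None:
        if self.block_index < -1:
            raise ValueError(f"block_index must be >= -1, got {self.block_index}")
        if not 0.0 <= self.raw_rating <= 100.0:
            raise ValueError(f"raw_rating must lie in [0, 100], got {self.raw_rating}")


@dataclass
class MarkovState:
    """Probability distribution over the reliability levels at one time."""

    probs: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if np.any(self.probs < -_NONNEG_TOL):
            raise ValueError("probabilities must be non-negative")
        total = float(self.probs.sum())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {total:.12f})")

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass
class WaveState:
    """Complex amplitude vector over the reliability levels at one time.

    Amplitudes are stored complex: real initial states acquire complex
    phases under unitary evolution; report probabilities are the squared
    moduli (Born rule).
    """

    amps: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.amps = np.asarray(self.amps, dtype=complex)
        if self.amps.ndim != 1:
            raise ValueError("amps must be a 1-D vector")
        if self.time < 0:
            raise ValueError("time must be >= 0")
        norm2 = float(np.sum(np.abs(self.amps) ** 2))
        if abs(norm2 - 1.0) > _PROB_TOL:
            raise ValueError(f"squared moduli must sum to 1 (got {norm2:.12f})")

    @property
    def n(self) -> int:
        return self.amps.shape[0]


def map_rating_to_state(rating: float, space: StateSpace | None = None) -> int:
    """Bin a 0-100 reliability rating onto the 11-level scale.

    Bins are 9 percentage points wide and half-open — [0,9) -> 0,
    [9,18) -> 1, ..., [81,90) -> 9 — with everything at or above 90
    mapped to the top state 10 (so the top bin is closed at 100).

    Only ``n = 11`` is supported: the published binning is defined for the
    11-level scale only.
    """
    space = space if space is not None else StateSpace(11)
    if space.n != 11:
        raise ValueError(f"rating bins are defined for n=11 only, got n={space.n}")
    if not 0.0 <= rating <= 100.0:
        raise ValueError(f"rating must lie in [0, 100], got {rating}")
    return int(min(rating // 9, 10))


def state_to_rating(state: int) -> float:
    """Representative percent rating of a state: its bin midpoint.

    Inverse-maps through :func:`map_rating_to_state` (bins are 9 points
    wide; the top bin spans 90-100, midpoint 95).
    """
    if not 0 <= state <= 10:
        raise ValueError(f"state must lie in [0, 10], got {state}")
    return 95.0 if state == 10 else state * 9.0 + 4.5


def uniform_initial(space: StateSpace, flavor: str) -> MarkovState | WaveState:
    """Uniform initial state: probabilities 1/n, or amplitudes 1/sqrt(n).

    This is the conventional "know nothing" initial state; every
    reliability level carries equal weight (equal squared weight in the
    quantum case).
    """
    if flavor == "markov":
        return MarkovState(np.full(space.n, 1.0 / space.n), time=0.0)
    if flavor == "quantum":
        return WaveState(np.full(space.n, 1.0 / np.sqrt(space.n)), time=0.0)
    raise ValueError(f"flavor must be 'markov' or 'quantum', got {flavor!r}")


def weighted_initial(
    space: StateSpace,
    start_state: int,
    flavor: str,
    normalize: bool = True,
) -> MarkovState | WaveState | np.ndarray:
    """Weighted initial state: a 7-point symmetric stencil at ``start_state``.

    The stencil assigns the largest weight to the start state (mapped from
    the participant's post-practice rating) and decreasing weight to the
    three neighbour states either side; all other states get exactly zero.
    Stencil points falling outside [0, n-1] are truncated.

    With ``normalize=True`` (the default, required before evolution) the
    vector is rescaled to satisfy the probability / unit-norm invariant and
    a :class:`MarkovState` or :class:`WaveState` is returned.  With
    ``normalize=False`` the raw stencil values are returned verbatim as a
    plain array (they do not normalise exactly: the classical stencil sums
    to 1.015, the quantum one has squared norm 1.0133).
    """
    if flavor == "markov":
        stencil = RAW_MARKOV_STENCIL
    elif flavor == "quantum":
        stencil = RAW_QUANTUM_STENCIL
    else:
        raise ValueError(f"flavor must be 'markov' or 'quantum', got {flavor!r}")
    if not 0 <= start_state <= space.n - 1:
        raise ValueError(
            f"start_state must lie in [0, {space.n - 1}], got {start_state}"
        )

    vec = np.zeros(space.n)
    for offset, weight in zip(range(-_STENCIL_REACH, _STENCIL_REACH + 1), stencil):
        idx = start_state + offset
        if 0 <= idx < space.n:
            vec[idx] = weight

    if not normalize:
        return vec
    if flavor == "markov":
        return MarkovState(vec / vec.sum(), time=0.0)
    return WaveState(vec / np.sqrt(np.sum(vec**2)), time=0.0)
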