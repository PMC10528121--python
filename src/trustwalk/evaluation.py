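"""Model prediction trajectories and RMSE comparison against observed ratings.

Both models are evolved *continuously* from a single initial state — there
is no re-initialisation or collapse between block ratings — and read out at
a schedule of model times.  Model time is mapped to the experiment as
``t = trial_index * time_scale``, with each block's rating placed at its
last trial.  The default ``time_scale`` is 0.1 model time units per trial:
with the default diffusion sigma2 = 0.7 the quantum wave's dominant period
is about 4.5 time units, so 0.1 per trial puts that period at roughly 45
trials — a slow, regular wave across a 560-trial session, resolvable by
ratings taken every 28 trials (a time scale of a full unit per trial would
alias several whole oscillations between consecutive ratings).  The point prediction plotted /
scored at each time is the expected state E[R] = sum_i i * P(R = i); the
modal (maximum-probability) state is available as an alternative readout.

Observed ratings are binned onto the discrete scale first, so the RMSE is
on the 11-level state scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import (
    IntensityMatrix,
    IntensityParams,
    build_intensity_matrix,
    evolve_markov,
    markov_predict,
)
from .quantum import (
    Hamiltonian,
    HamiltonianParams,
    build_hamiltonian,
    born_probabilities,
    evolve_quantum,
)
from .state_space import (
    MarkovState,
    RatingObservation,
    StateSpace,
    WaveState,
    state_to_rating,
    uniform_initial,
    weighted_initial,
)

__all__ = [
    "DEFAULT_TIME_SCALE",
    "PredictionTrajectory",
    "ComparisonResult",
    "predict_trajectory",
    "expected_state",
    "modal_state",
    "rmse",
    "compare_models",
    "block_end_times",
    "sample_ratings_from_trajectory",
]

#: Model time units per experimental trial (see module docstring).
DEFAULT_TIME_SCALE = 0.1

_DIST_TOL = 1e-9


def expected_state(distribution: np.ndarray) -> float:
    """Expected reliability level under a distribution over states."""
    distribution = np.asarray(distribution, dtype=float)
    return float(np.arange(distribution.shape[0]) @ distribution)


def modal_state(distribution: np.ndarray) -> int:
    """Maximum-probability reliability level (ties break to the lowest index)."""
    return int(np.argmax(distribution))


@dataclass
class PredictionTrajectory:
    """Model readouts at an increasing schedule of times.

    ``distributions`` has one row per time (each a distribution over the n
    states); ``point_predictions`` holds the expected state at each time.
    """

    times: np.ndarray
    distributions: np.ndarray
    point_predictions: np.ndarray
    model_tag: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distributions = np.asarray(self.distributions, dtype=float)
        self.point_predictions = np.asarray(self.point_predictions, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(self.distributions.sum(axis=1) - 1.0) > _DIST_TOL):
            raise ValueError("each distribution must sum to 1")
        n = self.distributions.shape[1]
        expected = self.distributions @ np.arange(n)
        if np.any(np.abs(expected - self.point_predictions) > 1e-9):
            raise ValueError("point predictions must equal the expected state")

    def to_frame(self) -> pd.DataFrame:
        n = self.distributions.shape[1]
        df = pd.DataFrame(self.distributions, columns=[f"p{i}" for i in range(n)])
        df.insert(0, "time", self.times)
        df.insert(1, "point_prediction", self.point_predictions)
        df.insert(0, "model", self.model_tag)
        return df


def predict_trajectory(
    initial: MarkovState | WaveState,
    generator: IntensityMatrix | Hamiltonian,
    schedule,
    model_tag: str | None = None,
) -> PredictionTrajectory:
    """Evolve ``initial`` under ``generator`` and read out at each time.

    The state/generator flavours must match (probability vector with an
    intensity matrix, amplitude vector with a Hamiltonian); every time is
    reached from the *same* initial state.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("schedule must be non-empty")
    if np.any(schedule < 0):
        raise ValueError("schedule times must be >= 0")
    if np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must be strictly increasing")

    if isinstance(initial, MarkovState) and isinstance(generator, IntensityMatrix):
        readout = lambda t: markov_predict(evolve_markov(initial, generator, t))
        tag = model_tag or "markov"
    elif isinstance(initial, WaveState) and isinstance(generator, Hamiltonian):
        readout = lambda t: born_probabilities(evolve_quantum(initial, generator, t))
        tag = model_tag or "quantum"
    else:
        raise TypeError(
            "mismatched flavours: pair MarkovState with IntensityMatrix or "
            f"WaveState with Hamiltonian, got {type(initial).__name__} with "
            f"{type(generator).__name__}"
        )

    dists = np.array([readout(t) for t in schedule])
    points = dists @ np.arange(dists.shape[1])
    return PredictionTrajectory(
        times=schedule, distributions=dists, point_predictions=points, model_tag=tag
    )


def rmse(
    traj: PredictionTrajectory,
    observations: list[RatingObservation],
    block_times: dict[int, float],
) -> float:
    """Root mean square error of the point predictions against observed states."""
    if not observations:
        raise ValueError("need at least one observation")
    time_to_idx = {float(t): i for i, t in enumerate(traj.times)}
    errs = []
    for obs in observations:
        if obs.block_index not in block_times:
            raise KeyError(f"no model time for block {obs.block_index}")
        t = float(block_times[obs.block_index])
        if t not in time_to_idx:
            raise KeyError(f"block {obs.block_index} time {t} not in the trajectory")
        errs.append(traj.point_predictions[time_to_idx[t]] - obs.state)
    return float(np.sqrt(np.mean(np.square(errs))))


def block_end_times(
    blocks, trials_per_block: int = 28, time_scale: float = DEFAULT_TIME_SCALE
) -> dict[int, float]:
    """Model time of each block's rating: the block's last trial index scaled."""
    return {int(b): float(b * trials_per_block * time_scale) for b in blocks}


def sample_ratings_from_trajectory(
    traj: PredictionTrajectory,
    blocks,
    rng: np.random.Generator,
) -> list[RatingObservation]:
    """Draw one reported rating per block from the model's own readout.

    Both models are measurement-probabilistic — the trajectory's
    distribution at a block time *is* the model's distribution over the
    rating the participant would report — so a synthetic observation is a
    multinomial draw from it, converted to the bin-centre percent rating of
    the drawn state.
    """
    blocks = list(blocks)
    if len(blocks) != len(traj.times):
        raise ValueError("need exactly one block per trajectory time")
    n = traj.distributions.shape[1]
    observations = []
    for b, dist in zip(blocks, traj.distributions):
        p = np.clip(dist, 0.0, None)
        state = int(rng.choice(n, p=p / p.sum()))
        observations.append(
            RatingObservation(
                block_index=int(b),
                raw_rating=state_to_rating(state),
                state=state,
            )
        )
    return observations


@dataclass
class ComparisonResult:
    """Both models' RMSEs plus the per-block error table they derive from."""

    rmse_markov: float
    rmse_quantum: float
    per_block_error: pd.DataFrame
    markov_trajectory: PredictionTrajectory | None = None
    quantum_trajectory: PredictionTrajectory | None = None

    def recompute_rmse(self) -> tuple[float, float]:
        """RMSEs recomputed from the per-block table (consistency check)."""
        tab = self.per_block_error
        rm = float(np.sqrt(np.mean((tab["markov_prediction"] - tab["observed_state"]) ** 2)))
        rq = float(np.sqrt(np.mean((tab["quantum_prediction"] - tab["observed_state"]) ** 2)))
        return rm, rq

    def to_dict(self) -> dict:
        return {
            "rmse_markov": self.rmse_markov,
            "rmse_quantum": self.rmse_quantum,
            "per_block_error": self.per_block_error.to_dict(orient="records"),
        }


def compare_models(
    observations: list[RatingObservation],
    markov_params=None,
    quantum_params=None,
    space: StateSpace | None = None,
    time_scale: float = DEFAULT_TIME_SCALE,
    trials_per_block: int = 28,
    init: str = "weighted",
) -> ComparisonResult:
    """Score both models against one session's block ratings.

    The initial state (shared start between models) is built from the
    post-practice rating (block 0): a weighted 7-point stencil at its mapped
    state by default, or the uniform state with ``init='uniform'``.  Both
    models then evolve continuously and are read out at each block's end
    time; the RMSE is over blocks >= 1 (block 0 defines the start, the
    pre-practice rating, if present, is ignored).
    """
    space = space if space is not None else StateSpace(11)
    markov_params = markov_params if markov_params is not None else IntensityParams()
    quantum_params = quantum_params if quantum_params is not None else HamiltonianParams()

    scored = sorted(
        (o for o in observations if o.block_index >= 1), key=lambda o: o.block_index
    )
    if len(scored) < 2:
        raise ValueError("need at least two block ratings (blocks >= 1) to compare")

    if init == "weighted":
        post_practice = [o for o in observations if o.block_index == 0]
        if not post_practice:
            raise ValueError("weighted init needs the post-practice (block 0) rating")
        start = post_practice[0].state
        phi0 = weighted_initial(space, start, "markov")
        psi0 = weighted_initial(space, start, "quantum")
    elif init == "uniform":
        phi0 = uniform_initial(space, "markov")
        psi0 = uniform_initial(space, "quantum")
    else:
        raise ValueError(f"init must be 'weighted' or 'uniform', got {init!r}")

    blocks = [o.block_index for o in scored]
    times = block_end_times(blocks, trials_per_block, time_scale)
    schedule = [times[b] for b in blocks]

    K = build_intensity_matrix(markov_params, space)
    H = build_hamiltonian(quantum_params, space)
    traj_m = predict_trajectory(phi0, K, schedule)
    traj_q = predict_trajectory(psi0, H, schedule)

    table = pd.DataFrame(
        {
            "block": blocks,
            "observed_state": [o.state for o in scored],
            "markov_prediction": traj_m.point_predictions,
            "quantum_prediction": traj_q.point_predictions,
        }
    )
    return ComparisonResult(
        rmse_markov=rmse(traj_m, scored, times),
        rmse_quantum=rmse(traj_q, scored, times),
        per_block_error=table,
        markov_trajectory=traj_m,
        quantum_trajectory=traj_q,
    )
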