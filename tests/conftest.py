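import numpy as np
import pandas as pd
import pytest

from trustwalk import (
    EpochSet,
    HamiltonianParams,
    IntensityParams,
    StateSpace,
    build_hamiltonian,
    build_intensity_matrix,
)
from trustwalk.erp import n_samples_for_window


@pytest.fixture
def space11():
    return StateSpace(11)


@pytest.fixture
def default_K(space11):
    return build_intensity_matrix(IntensityParams(), space11)


@pytest.fixture
def default_H(space11):
    return build_hamiltonian(HamiltonianParams(), space11)


def rk4_evolve(matrix, y0, t_final, step=1e-4):
    """Fixed-step classical fourth-order integration of dy/dt = M y.

    Independent oracle for the matrix-exponential propagators (pass
    M = K for the classical walk, M = -iH for the quantum one).
    """
    y = np.asarray(y0, dtype=complex).copy()
    n_steps = int(round(t_final / step))
    M = np.asarray(matrix, dtype=complex)
    for _ in range(n_steps):
        k1 = M @ y
        k2 = M @ (y + 0.5 * step * k1)
        k3 = M @ (y + 0.5 * step * k2)
        k4 = M @ (y + step * k3)
        y = y + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


@pytest.fixture
def rk4():
    return rk4_evolve


def make_epochs(
    trial_values,
    conditions,
    rts=None,
    baseline=(-1300.0, -700.0),
    n_channels=3,
    sampling_rate=250.0,
    tmin_ms=-1300.0,
    tmax_ms=950.0,
    channel_labels=None,
):
    """Tiny constructed EpochSet: each trial is a constant-valued epoch."""
    n_trials = len(trial_values)
    n_samp = n_samples_for_window(tmin_ms, tmax_ms, sampling_rate)
    data = np.zeros((n_channels, n_samp, n_trials))
    for j, v in enumerate(trial_values):
        data[:, :, j] = v
    if rts is None:
        rts = [0.5] * n_trials
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "reaction_time_s": rts,
            "baseline_start_ms": [baseline[0]] * n_trials,
            "baseline_end_ms": [baseline[1]] * n_trials,
        }
    )
    labels = channel_labels if channel_labels is not None else [f"ch{i}" for i in range(n_channels)]
    return EpochSet(
        data=data,
        trial_meta=meta,
        sampling_rate=sampling_rate,
        tmin_ms=tmin_ms,
        tmax_ms=tmax_ms,
        channel_labels=labels,
    )


@pytest.fixture
def constant_epochs():
    return make_epochs
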