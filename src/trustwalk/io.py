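"""File dialects: ratings CSV, trials CSV, and the HDF5 epoch container.

Ratings CSV: header row required, columns ``block_index`` and
``raw_rating`` (percent), optional ``state`` (recomputed from the rating
when absent, validated when present).

Epoch container (HDF5): dataset ``data`` (channels x samples x trials,
microvolts), root attributes ``sampling_rate``, ``tmin_ms``, ``tmax_ms``,
``channel_labels``; group ``trial_meta`` with one dataset per metadata
column (strings UTF-8 encoded).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .erp import EpochSet
from .state_space import RatingObservation, map_rating_to_state

__all__ = [
    "read_ratings_csv",
    "write_ratings_csv",
    "save_epochs",
    "load_epochs",
]


def write_ratings_csv(observations: list[RatingObservation], path) -> None:
    pd.DataFrame(
        {
            "block_index": [o.block_index for o in observations],
            "raw_rating": [o.raw_rating for o in observations],
            "state": [o.state for o in observations],
        }
    ).to_csv(path, index=False)


def read_ratings_csv(path) -> list[RatingObservation]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ratings file not found: {path}")
    df = pd.read_csv(path)
    required = {"block_index", "raw_rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ratings CSV is missing columns: {sorted(missing)}")
    observations = []
    for _, row in df.iterrows():
        state = map_rating_to_state(float(row["raw_rating"]))
        if "state" in df.columns and not pd.isna(row["state"]) and int(row["state"]) != state:
            raise ValueError(
                f"stored state {int(row['state'])} disagrees with the rating "
                f"{row['raw_rating']} (maps to {state})"
            )
        observations.append(
            RatingObservation(
                block_index=int(row["block_index"]),
                raw_rating=float(row["raw_rating"]),
                state=state,
            )
        )
    return observations


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["tmin_ms"] = epochs.tmin_ms
        f.attrs["tmax_ms"] = epochs.tmax_ms
        f.attrs["channel_labels"] = list(epochs.channel_labels)
        meta = f.create_group("trial_meta")
        for col in epochs.trial_meta.columns:
            values = epochs.trial_meta[col].to_numpy()
            if values.dtype == object:
                meta.create_dataset(
                    col, data=np.array([str(v).encode() for v in values])
                )
            else:
                meta.create_dataset(col, data=values)


def load_epochs(path) -> EpochSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"epoch container not found: {path}")
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        columns = {}
        for col in f["trial_meta"]:
            values = f["trial_meta"][col][...]
            if values.dtype.kind in ("S", "O"):
                values = np.array(
                    [v.decode() if isinstance(v, bytes) else str(v) for v in values]
                )
            columns[col] = values
        return EpochSet(
            data=data,
            trial_meta=pd.DataFrame(columns),
            sampling_rate=float(f.attrs["sampling_rate"]),
            tmin_ms=float(f.attrs["tmin_ms"]),
            tmax_ms=float(f.attrs["tmax_ms"]),
            channel_labels=[
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f.attrs["channel_labels"]
            ],
        )
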