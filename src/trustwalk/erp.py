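"""Simplified event-related-potential stage for already-clean EEG epochs.

Epochs are time-locked to the AI-feedback event (the robot icon appearing
on screen).  The stage covers: trial rejection (>100 microvolt peak-to-peak
swings; responses slower than 2 s or missing), per-trial baseline
correction over 600 ms of the fixation period preceding the image stimulus
(the window's position relative to the feedback event varies with reaction
time, so it is carried per trial), condition averaging, the match-minus-
mismatch difference wave, scalp-region averaging, and sample-aligned
peak/trough latency detection.

The upstream cleaning chain (filtering, line-noise removal, ICA, artifact
subspace reconstruction, re-referencing) is assumed to have already been
applied; this stage operates on its output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "ErpResult",
    "PeakResult",
    "DEFAULT_CHANNELS",
    "DEFAULT_REGION_MAP",
    "reject_trials",
    "baseline_correct",
    "average_by_condition",
    "peak_latency",
]

#: 19-channel international 10-20 montage used by the synthetic generator.
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
]

#: Editable default region membership (the montage above).
DEFAULT_REGION_MAP = {
    "frontal": ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"],
    "central": ["C3", "Cz", "C4"],
    "left_temporal": ["T7", "P7"],
    "right_temporal": ["T8", "P8"],
    "parietal": ["P3", "Pz", "P4"],
    "occipital": ["O1", "O2"],
}

_META_COLUMNS = ["condition", "reaction_time_s", "baseline_start_ms", "baseline_end_ms"]


def n_samples_for_window(tmin_ms: float, tmax_ms: float, sampling_rate: float) -> int:
    """Samples on the grid tmin + k/fs that fit inside [tmin, tmax]."""
    return int(np.floor((tmax_ms - tmin_ms) / 1000.0 * sampling_rate + 1e-9)) + 1


@dataclass
class EpochSet:
    """Event-locked EEG trials: channels x samples x trials, in microvolts.

    ``trial_meta`` carries one row per trial with columns ``condition``
    ('match' or 'mismatch'), ``reaction_time_s`` (NaN when the participant
    did not respond), and the per-trial baseline window
    ``baseline_start_ms`` / ``baseline_end_ms`` (NaN when no usable window
    lies inside the epoch).
    """

    data: np.ndarray
    trial_meta: pd.DataFrame
    sampling_rate: float = 250.0
    tmin_ms: float = -1300.0
    tmax_ms: float = 950.0
    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x trials")
        n_ch, n_samp, n_tr = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {n_ch} channels"
            )
        expected = n_samples_for_window(self.tmin_ms, self.tmax_ms, self.sampling_rate)
        if n_samp != expected:
            raise ValueError(
                f"window {self.tmin_ms}..{self.tmax_ms} ms at {self.sampling_rate} Hz "
                f"needs {expected} samples, data has {n_samp}"
            )
        if len(self.trial_meta) != n_tr:
            raise ValueError(
                f"{len(self.trial_meta)} metadata rows for {n_tr} trials"
            )
        missing = [c for c in _META_COLUMNS if c not in self.trial_meta.columns]
        if missing:
            raise ValueError(f"trial_meta is missing columns: {missing}")
        self.trial_meta = self.trial_meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the AI-feedback event."""
        step = 1000.0 / self.sampling_rate
        return self.tmin_ms + step * np.arange(self.data.shape[1])

    def subset(self, keep: np.ndarray) -> "EpochSet":
        """New EpochSet with only the given trials (samples untouched)."""
        return replace(
            self,
            data=self.data[:, :, keep],
            trial_meta=self.trial_meta.iloc[np.atleast_1d(keep)].reset_index(drop=True),
        )


@dataclass
class PeakResult:
    latency_ms: float
    amplitude_uv: float
    flat: bool = False


@dataclass
class ErpResult:
    """Condition-averaged waveforms, their difference, and region averages.

    ``erp_difference`` is match minus mismatch.  ``region_averages`` maps
    region name -> {'match', 'mismatch', 'difference'} -> 1-D waveform
    (mean over the region's member channels).
    """

    erp_match: np.ndarray
    erp_mismatch: np.ndarray
    erp_difference: np.ndarray
    region_averages: dict[str, dict[str, np.ndarray]]
    n_trials_used: dict[str, int]
    times_ms: np.ndarray
    channel_labels: list[str]


def reject_trials(
    epochs: EpochSet,
    voltage_limit_uv: float = 100.0,
    rt_limit_s: float = 2.0,
    mode: str = "peak_to_peak",
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop artifact and no/slow-response trials; surviving trials unchanged.

    A trial is rejected when any channel's voltage swing exceeds
    ``voltage_limit_uv`` (peak-to-peak range by default; ``mode='absolute'``
    tests the largest absolute amplitude instead), or when the reaction
    time exceeds ``rt_limit_s`` or is missing.

    Returns the filtered set and a log with one row per rejected trial.
    A fully rejected set is returned as an empty EpochSet (averaging will
    refuse it).
    """
    if voltage_limit_uv <= 0 or rt_limit_s <= 0:
        raise ValueError("rejection limits must be positive")
    if mode == "peak_to_peak":
        swing = epochs.data.max(axis=1) - epochs.data.min(axis=1)  # channels x trials
    elif mode == "absolute":
        swing = np.abs(epochs.data).max(axis=1)
    else:
        raise ValueError(f"mode must be 'peak_to_peak' or 'absolute', got {mode!r}")
    voltage_bad = (swing > voltage_limit_uv).any(axis=0)
    rt = epochs.trial_meta["reaction_time_s"].to_numpy(dtype=float)
    rt_bad = np.isnan(rt) | (rt > rt_limit_s)

    rows = []
    for i in np.nonzero(voltage_bad | rt_bad)[0]:
        reasons = []
        if voltage_bad[i]:
            reasons.append(f"voltage swing > {voltage_limit_uv} uV")
        if rt_bad[i]:
            reasons.append(
                "no response" if np.isnan(rt[i]) else f"reaction time > {rt_limit_s} s"
            )
        rows.append({"trial": int(i), "reason": "; ".join(reasons)})
    log = pd.DataFrame(rows, columns=["trial", "reason"])
    keep = np.nonzero(~(voltage_bad | rt_bad))[0]
    return epochs.subset(keep), log


def baseline_correct(epochs: EpochSet) -> tuple[EpochSet, pd.DataFrame]:
    """Subtract each trial's mean over its own baseline window, per channel.

    Trials whose baseline window is missing (NaN) or falls outside the
    epoch are dropped with a warning and listed in the returned log.
    Applying the correction twice is a no-op (the baseline mean is zero
    after the first pass).
    """
    times = epochs.times_ms
    data = epochs.data.copy()
    starts = epochs.trial_meta["baseline_start_ms"].to_numpy(dtype=float)
    ends = epochs.trial_meta["baseline_end_ms"].to_numpy(dtype=float)

    keep, dropped = [], []
    for i in range(epochs.n_trials):
        lo, hi = starts[i], ends[i]
        if (
            np.isnan(lo)
            or np.isnan(hi)
            or lo >= hi
            or lo < epochs.tmin_ms - 1e-9
            or hi > epochs.tmax_ms + 1e-9
        ):
            dropped.append({"trial": int(i), "reason": "baseline window outside epoch"})
            continue
        mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
        if mask.sum() == 0:
            dropped.append({"trial": int(i), "reason": "baseline window has no samples"})
            continue
        data[:, :, i] -= data[:, mask, i].mean(axis=1, keepdims=True)
        keep.append(i)

    log = pd.DataFrame(dropped, columns=["trial", "reason"])
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} trial(s) with unusable baseline windows",
            stacklevel=2,
        )
    out = replace(
        epochs,
        data=data[:, :, keep],
        trial_meta=epochs.trial_meta.iloc[keep].reset_index(drop=True),
    )
    return out, log


def average_by_condition(
    epochs: EpochSet, region_map: dict[str, list[str]] | None = None
) -> ErpResult:
    """Per-condition mean waveforms, difference wave, and region averages."""
    region_map = region_map if region_map is not None else DEFAULT_REGION_MAP
    cond = epochs.trial_meta["condition"].to_numpy()
    erps: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    for label in ("match", "mismatch"):
        sel = cond == label
        n_used[label] = int(sel.sum())
        if n_used[label] == 0:
            raise ValueError(f"no '{label}' trials to average")
        erps[label] = epochs.data[:, :, sel].mean(axis=2)
    difference = erps["match"] - erps["mismatch"]

    label_to_idx = {ch: i for i, ch in enumerate(epochs.channel_labels)}
    region_averages: dict[str, dict[str, np.ndarray]] = {}
    for region, members in region_map.items():
        unknown = [ch for ch in members if ch not in label_to_idx]
        if unknown:
            raise ValueError(f"region {region!r} names unknown channels: {unknown}")
        idx = [label_to_idx[ch] for ch in members]
        region_averages[region] = {
            "match": erps["match"][idx].mean(axis=0),
            "mismatch": erps["mismatch"][idx].mean(axis=0),
            "difference": difference[idx].mean(axis=0),
        }

    return ErpResult(
        erp_match=erps["match"],
        erp_mismatch=erps["mismatch"],
        erp_difference=difference,
        region_averages=region_averages,
        n_trials_used=n_used,
        times_ms=epochs.times_ms,
        channel_labels=list(epochs.channel_labels),
    )


def peak_latency(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    search_window_ms: tuple[float, float],
    polarity: str = "positive",
) -> PeakResult:
    """Sample-aligned extremum within a latency window.

    Positive polarity locates the maximum, negative the minimum.  A flat
    waveform (all samples equal within 1e-12) returns the window start with
    ``flat=True``.  No sub-sample interpolation is performed.
    """
    waveform = np.asarray(waveform, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = search_window_ms
    if lo >= hi:
        raise ValueError("search window must have lo < hi")
    mask = (times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9)
    if mask.sum() < 3:
        raise ValueError("search window must span at least 3 samples")
    seg, seg_t = waveform[mask], times_ms[mask]
    if np.ptp(seg) < 1e-12:
        return PeakResult(latency_ms=float(seg_t[0]), amplitude_uv=float(seg[0]), flat=True)
    if polarity == "positive":
        k = int(np.argmax(seg))
    elif polarity == "negative":
        k = int(np.argmin(seg))
    else:
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    return PeakResult(latency_ms=float(seg_t[k]), amplitude_uv=float(seg[k]))
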