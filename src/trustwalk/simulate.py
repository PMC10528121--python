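"""Synthetic Wizard-of-Oz session, rating-trajectory, and EEG-epoch generators.

The study these models target collected (but did not release) three kinds of
data, all emulated here:

* a session of 20 blocks x 28 trials in which a pre-programmed "AI" agrees
  with the participant's real/fake face classification on exactly 75% of
  each block's trials (match) and disagrees on 25% (mismatch), drawing each
  face image at most once from a manifest of 294 real + 294 synthetic faces;
* per-block reliability ratings on a 0-100 slider that oscillate early and
  dampen with experience — emulated with an explicitly parametric damped
  cosine around an asymptote (the damped-cosine form is this package's own
  generator device, chosen to reproduce the oscillate-then-settle pattern,
  not an empirical claim);
* EEG epochs time-locked to the AI-feedback icon containing
  condition-dependent event-related components: both conditions carry a
  positive central deflection near 376 ms, larger on the rare mismatch
  trials (a P3-like oddball response), and the mismatch template adds a
  small dip near 268 ms.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .erp import DEFAULT_CHANNELS, DEFAULT_REGION_MAP, EpochSet, n_samples_for_window
from .state_space import RatingObservation, map_rating_to_state

__all__ = [
    "SessionConfig",
    "Trial",
    "Session",
    "RatingGeneratorParams",
    "ErpComponent",
    "DEFAULT_ERP_TEMPLATE",
    "generate_session",
    "generate_rating_trajectory",
    "closed_form_rating",
    "generate_epochs",
]

_FEEDBACK_DELAY_S = 0.3  # AI icon appears 0.3 s after the participant's response
_BASELINE_MS = 600.0  # baseline length: 600 ms of fixation before image onset
_RT_TIMEOUT_S = 2.0  # no response within 2 s -> timeout, no AI feedback


@dataclass(frozen=True)
class SessionConfig:
    """Design parameters of one Wizard-of-Oz session."""

    n_blocks: int = 20
    trials_per_block: int = 28
    match_fraction: float = 0.75
    n_real_images: int = 294
    n_fake_images: int = 294
    rt_mean_s: float = 0.7
    rt_sd_s: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        if not 0.0 < self.match_fraction <= 1.0:
            raise ValueError(
                f"match_fraction must lie in (0, 1], got {self.match_fraction}"
            )
        n_match = self.match_fraction * self.trials_per_block
        if abs(n_match - round(n_match)) > 1e-9:
            raise ValueError(
                f"match_fraction x trials_per_block must be an integer, got {n_match}"
            )
        if self.rt_mean_s <= 0 or self.rt_sd_s <= 0:
            raise ValueError("reaction-time distribution parameters must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def matches_per_block(self) -> int:
        return int(round(self.match_fraction * self.trials_per_block))


@dataclass(frozen=True)
class Trial:
    """One interaction: stimulus, responses, condition, timing."""

    block: int
    index_in_block: int
    condition: str  # 'match' | 'mismatch' (designed agreement)
    stimulus_id: str
    stimulus_class: str  # 'real' | 'fake'
    participant_response: str  # 'real' | 'fake' | 'timeout'
    ai_response: str | None  # None on timeout (no feedback shown)
    reaction_time_s: float  # NaN on timeout

    def __post_init__(self) -> None:
        if self.participant_response in ("real", "fake") and self.ai_response is not None:
            agrees = self.ai_response == self.participant_response
            if agrees != (self.condition == "match"):
                raise ValueError(
                    "condition must be 'match' exactly when the AI response "
                    "equals the participant response"
                )


@dataclass
class Session:
    """A full generated session: config, trials, and the stimulus manifest."""

    config: SessionConfig
    trials: list[Trial]
    manifest: pd.DataFrame  # columns: stimulus_id, stimulus_class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [t.block for t in self.trials],
                "index_in_block": [t.index_in_block for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "stimulus_id": [t.stimulus_id for t in self.trials],
                "stimulus_class": [t.stimulus_class for t in self.trials],
                "participant_response": [t.participant_response for t in self.trials],
                "ai_response": [t.ai_response or "" for t in self.trials],
                "reaction_time_s": [t.reaction_time_s for t in self.trials],
            }
        )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # mean/sd of the lognormal itself -> (mu, sigma) of the underlying normal
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_session(config: SessionConfig) -> Session:
    """Generate one session with exact per-block condition counts.

    Each block holds exactly ``match_fraction x trials_per_block`` match
    trials in a seeded random order.  Stimuli are drawn without replacement
    from the manifest with a 50/50 real/fake presentation balance; reaction
    times are lognormal, truncated at 2 s (slower draws become timeouts
    with no AI feedback).
    """
    rng = np.random.default_rng(config.seed)
    n_trials = config.n_trials

    manifest = pd.DataFrame(
        {
            "stimulus_id": [f"real_{i:03d}" for i in range(config.n_real_images)]
            + [f"fake_{i:03d}" for i in range(config.n_fake_images)],
            "stimulus_class": ["real"] * config.n_real_images
            + ["fake"] * config.n_fake_images,
        }
    )
    half = n_trials // 2
    n_real_needed, n_fake_needed = half, n_trials - half
    if n_real_needed > config.n_real_images or n_fake_needed > config.n_fake_images:
        raise ValueError(
            f"manifest too small: need {n_real_needed} real and {n_fake_needed} fake "
            f"images for {n_trials} trials"
        )
    real_ids = rng.permutation(config.n_real_images)[:n_real_needed]
    fake_ids = rng.permutation(config.n_fake_images)[:n_fake_needed]
    stimuli = [(f"real_{i:03d}", "real") for i in real_ids] + [
        (f"fake_{i:03d}", "fake") for i in fake_ids
    ]
    order = rng.permutation(n_trials)

    mu, sigma = _lognormal_params(config.rt_mean_s, config.rt_sd_s)

    trials: list[Trial] = []
    k = 0
    for block in range(1, config.n_blocks + 1):
        conditions = np.array(
            ["match"] * config.matches_per_block
            + ["mismatch"] * (config.trials_per_block - config.matches_per_block)
        )
        rng.shuffle(conditions)
        for idx in range(config.trials_per_block):
            stim_id, stim_class = stimuli[order[k]]
            rt = float(rng.lognormal(mu, sigma))
            if rt > _RT_TIMEOUT_S:
                trials.append(
                    Trial(
                        block=block,
                        index_in_block=idx,
                        condition=str(conditions[idx]),
                        stimulus_id=stim_id,
                        stimulus_class=stim_class,
                        participant_response="timeout",
                        ai_response=None,
                        reaction_time_s=float("nan"),
                    )
                )
            else:
                resp = "real" if rng.random() < 0.5 else "fake"
                if conditions[idx] == "match":
                    ai = resp
                else:
                    ai = "fake" if resp == "real" else "real"
                trials.append(
                    Trial(
                        block=block,
                        index_in_block=idx,
                        condition=str(conditions[idx]),
                        stimulus_id=stim_id,
                        stimulus_class=stim_class,
                        participant_response=resp,
                        ai_response=ai,
                        reaction_time_s=rt,
                    )
                )
            k += 1
    return Session(config=config, trials=trials, manifest=manifest)


@dataclass(frozen=True)
class RatingGeneratorParams:
    """Damped-cosine generator for the per-block reliability ratings.

    rating(b) = asymptote
                + (start_rating - asymptote
                   + oscillation_amplitude * cos(2 pi b / period))
                  * exp(-damping_rate * b)
                + noise,                       clipped to [0, 100],

    where b counts elicitations: b = 0 is the pre-practice rating, b = 1 the
    post-practice rating, b = k + 1 the rating after block k.
    """

    start_rating: float = 48.9
    asymptote: float = 75.0
    oscillation_amplitude: float = 15.0
    oscillation_period_blocks: float = 6.0
    damping_rate: float = 0.15
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("start_rating", "asymptote"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.oscillation_period_blocks <= 0:
            raise ValueError("oscillation_period_blocks must be positive")
        if self.damping_rate < 0 or self.noise_sd < 0:
            raise ValueError("damping_rate and noise_sd must be >= 0")


def closed_form_rating(params: RatingGeneratorParams, b: float) -> float:
    """Noise-free generator value at elicitation index ``b`` (unclipped)."""
    osc = params.oscillation_amplitude * np.cos(
        2.0 * np.pi * b / params.oscillation_period_blocks
    )
    return float(
        params.asymptote
        + (params.start_rating - params.asymptote + osc) * np.exp(-params.damping_rate * b)
    )


def generate_rating_trajectory(
    params: RatingGeneratorParams, n_blocks: int = 20
) -> list[RatingObservation]:
    """One rating per block plus the pre- and post-practice ratings.

    Returns ``n_blocks + 2`` observations with block_index -1
    (pre-practice), 0 (post-practice), and 1..n_blocks; each carries the
    raw percent rating and its mapped 11-level state.
    """
    rng = np.random.default_rng(params.seed)
    observations = []
    for b in range(n_blocks + 2):
        value = closed_form_rating(params, b) + rng.normal(0.0, params.noise_sd)
        value = float(np.clip(value, 0.0, 100.0))
        observations.append(
            RatingObservation(
                block_index=b - 1,
                raw_rating=value,
                state=map_rating_to_state(value),
            )
        )
    return observations


@dataclass(frozen=True)
class ErpComponent:
    """One Gaussian-bump ERP component projected onto a scalp region."""

    latency_ms: float
    width_ms: float  # Gaussian standard deviation
    amplitude_uv: float
    region: str


#: Default per-condition templates: a shared early visual response over
#: occipital channels and a central positive deflection at 376 ms that is
#: twice as large on mismatch trials, which additionally show a small dip
#: near 268 ms — mirroring the reported oddball morphology.
DEFAULT_ERP_TEMPLATE: dict[str, tuple[ErpComponent, ...]] = {
    "match": (
        ErpComponent(120.0, 25.0, 3.0, "occipital"),
        ErpComponent(376.0, 55.0, 4.0, "central"),
    ),
    "mismatch": (
        ErpComponent(120.0, 25.0, 3.0, "occipital"),
        ErpComponent(268.0, 30.0, -2.0, "central"),
        ErpComponent(376.0, 55.0, 8.0, "central"),
    ),
}


def generate_epochs(
    session: Session,
    erp_template: dict[str, tuple[ErpComponent, ...]] | None = None,
    noise_sd_uv: float = 5.0,
    sampling_rate: float = 250.0,
    tmin_ms: float = -1300.0,
    tmax_ms: float = 950.0,
    seed: int = 0,
    channel_labels: list[str] | None = None,
    region_map: dict[str, list[str]] | None = None,
) -> EpochSet:
    """Synthesize feedback-locked EEG epochs for a session's responded trials.

    Each epoch is the sum of its condition's Gaussian-bump components
    (placed on the channels of each component's scalp region) plus white
    noise.  Timeout trials produce no feedback event and are skipped.

    The per-trial baseline window is derived from the trial's simulated
    event latencies: the image appeared ``reaction_time + 0.3 s`` before
    the feedback event, and the baseline is the 600 ms of fixation directly
    before the image, clipped to the epoch support.  Slow trials whose
    baseline lies entirely left of the epoch get a NaN window (they are
    dropped later by baseline correction).
    """
    erp_template = erp_template if erp_template is not None else DEFAULT_ERP_TEMPLATE
    channel_labels = channel_labels if channel_labels is not None else list(DEFAULT_CHANNELS)
    region_map = region_map if region_map is not None else DEFAULT_REGION_MAP
    if noise_sd_uv < 0:
        raise ValueError("noise_sd_uv must be >= 0")

    label_to_idx = {ch: i for i, ch in enumerate(channel_labels)}
    for cond, components in erp_template.items():
        for comp in components:
            if not tmin_ms <= comp.latency_ms <= tmax_ms:
                raise ValueError(
                    f"{cond} component at {comp.latency_ms} ms lies outside the "
                    f"epoch window {tmin_ms}..{tmax_ms} ms"
                )
            if comp.region not in region_map:
                raise ValueError(f"unknown scalp region {comp.region!r}")
            unknown = [ch for ch in region_map[comp.region] if ch not in label_to_idx]
            if unknown:
                raise ValueError(
                    f"region {comp.region!r} names channels missing from the "
                    f"montage: {unknown}"
                )

    rng = np.random.default_rng(seed)
    n_ch = len(channel_labels)
    n_samp = n_samples_for_window(tmin_ms, tmax_ms, sampling_rate)
    times = tmin_ms + 1000.0 / sampling_rate * np.arange(n_samp)

    responded = [t for t in session.trials if t.participant_response != "timeout"]
    data = np.empty((n_ch, n_samp, len(responded)))
    meta_rows = []
    for j, trial in enumerate(responded):
        epoch = rng.normal(0.0, noise_sd_uv, size=(n_ch, n_samp)) if noise_sd_uv > 0 else np.zeros((n_ch, n_samp))
        for comp in erp_template[trial.condition]:
            bump = comp.amplitude_uv * np.exp(
                -((times - comp.latency_ms) ** 2) / (2.0 * comp.width_ms**2)
            )
            for ch in region_map[comp.region]:
                epoch[label_to_idx[ch]] += bump
        data[:, :, j] = epoch

        image_onset_ms = -(trial.reaction_time_s + _FEEDBACK_DELAY_S) * 1000.0
        lo = max(image_onset_ms - _BASELINE_MS, tmin_ms)
        hi = image_onset_ms
        if hi - lo < 3 * 1000.0 / sampling_rate:  # too little fixation inside the epoch
            lo, hi = float("nan"), float("nan")
        meta_rows.append(
            {
                "condition": trial.condition,
                "reaction_time_s": trial.reaction_time_s,
                "baseline_start_ms": lo,
                "baseline_end_ms": hi,
                "block": trial.block,
                "index_in_block": trial.index_in_block,
            }
        )

    return EpochSet(
        data=data,
        trial_meta=pd.DataFrame(meta_rows),
        sampling_rate=sampling_rate,
        tmin_ms=tmin_ms,
        tmax_ms=tmax_ms,
        channel_labels=channel_labels,
    )
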