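import numpy as np
import pandas as pd
import pytest

from trustwalk import (
    average_by_condition,
    baseline_correct,
    peak_latency,
    reject_trials,
)
from trustwalk.erp import DEFAULT_REGION_MAP, EpochSet, n_samples_for_window


def times_of(epochs):
    return epochs.times_ms


class TestRejectTrials:
    def test_large_voltage_swing_removed(self, constant_epochs):
        epochs = constant_epochs([5.0, 5.0, 5.0], ["match", "match", "mismatch"])
        epochs.data[1, 100, 1] = 80.0  # 150 uV peak-to-peak swing on one channel
        epochs.data[1, 200, 1] = -70.0
        kept, log = reject_trials(epochs)
        assert kept.n_trials == 2
        assert list(log["trial"]) == [1]
        assert "voltage" in log["reason"][0]

    def test_quiet_fast_trials_all_survive(self, constant_epochs):
        epochs = constant_epochs([10.0, -10.0, 5.0], ["match"] * 3, rts=[0.5] * 3)
        kept, log = reject_trials(epochs)
        assert kept.n_trials == 3 and log.empty

    def test_slow_and_missing_responses_removed(self, constant_epochs):
        epochs = constant_epochs(
            [0.0, 0.0, 0.0], ["match"] * 3, rts=[0.5, 2.5, float("nan")]
        )
        kept, log = reject_trials(epochs)
        assert kept.n_trials == 1
        assert set(log["trial"]) == {1, 2}

    def test_engineered_fixture_counts(self, constant_epochs):
        epochs = constant_epochs([0.0] * 5, ["match"] * 5)
        for trial in (1, 3):
            epochs.data[0, 50, trial] = 120.0  # above the 100 uV rule
        kept, _ = reject_trials(epochs)
        assert kept.n_trials == 3

    def test_survivors_samples_untouched(self, constant_epochs):
        epochs = constant_epochs([3.0, 4.0], ["match", "mismatch"])
        epochs.data[0, 10, 0] = 500.0
        before = epochs.data[:, :, 1].copy()
        kept, _ = reject_trials(epochs)
        assert np.array_equal(kept.data[:, :, 0], before)

    def test_absolute_mode(self, constant_epochs):
        # a flat 80 uV offset passes peak-to-peak but fails absolute amplitude
        epochs = constant_epochs([80.0], ["match"])
        kept_ptp, _ = reject_trials(epochs, mode="peak_to_peak")
        kept_abs, _ = reject_trials(epochs, voltage_limit_uv=60.0, mode="absolute")
        assert kept_ptp.n_trials == 1
        assert kept_abs.n_trials == 0


class TestBaselineCorrect:
    def test_constant_trial_becomes_zero(self, constant_epochs):
        epochs = constant_epochs([5.0], ["match"])
        corrected, log = baseline_correct(epochs)
        assert log.empty
        assert np.allclose(corrected.data, 0.0)

    def test_bump_preserved_baseline_zeroed(self, constant_epochs):
        epochs = constant_epochs([2.0], ["match"])
        t = times_of(epochs)
        bump = (t >= 300) & (t <= 400)
        epochs.data[0, bump, 0] += 7.0
        corrected, _ = baseline_correct(epochs)
        base = (t >= -1300) & (t <= -700)
        assert np.allclose(corrected.data[0, base, 0], 0.0, atol=1e-12)
        assert corrected.data[0, bump, 0] == pytest.approx(7.0)

    def test_idempotent(self, constant_epochs):
        rng = np.random.default_rng(0)
        epochs = constant_epochs([1.0, 2.0], ["match", "mismatch"])
        epochs.data += rng.normal(size=epochs.data.shape)
        once, _ = baseline_correct(epochs)
        twice, _ = baseline_correct(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_unusable_window_drops_trial_with_warning(self, constant_epochs):
        epochs = constant_epochs([1.0, 2.0], ["match", "mismatch"])
        epochs.trial_meta.loc[1, "baseline_start_ms"] = float("nan")
        epochs.trial_meta.loc[1, "baseline_end_ms"] = float("nan")
        with pytest.warns(UserWarning, match="baseline"):
            corrected, log = baseline_correct(epochs)
        assert corrected.n_trials == 1
        assert list(log["trial"]) == [1]


class TestAverageByCondition:
    def test_identical_conditions_give_zero_difference(self, constant_epochs):
        epochs = constant_epochs([4.0, 4.0], ["match", "mismatch"])
        result = average_by_condition(epochs, region_map={})
        assert np.allclose(result.erp_difference, 0.0)

    def test_constant_offset_appears_in_difference(self, constant_epochs):
        epochs = constant_epochs([1.0, 1.0, 4.0], ["match", "match", "mismatch"])
        result = average_by_condition(epochs, region_map={})
        assert np.allclose(result.erp_difference, -3.0)

    def test_means_equal_hand_computed_averages(self, constant_epochs):
        epochs = constant_epochs([1.0, 3.0, 10.0, 20.0], ["match", "match", "mismatch", "mismatch"])
        result = average_by_condition(epochs, region_map={})
        assert np.allclose(result.erp_match, 2.0)
        assert np.allclose(result.erp_mismatch, 15.0)
        assert result.n_trials_used == {"match": 2, "mismatch": 2}

    def test_region_average_is_mean_of_member_channels(self, constant_epochs):
        epochs = constant_epochs([0.0, 0.0], ["match", "mismatch"], n_channels=3)
        epochs.data[0, :, 0] = 6.0  # ch0, match trial
        epochs.data[1, :, 0] = 2.0  # ch1, match trial
        result = average_by_condition(epochs, region_map={"front": ["ch0", "ch1"]})
        assert np.allclose(result.region_averages["front"]["match"], 4.0)

    def test_missing_condition_raises(self, constant_epochs):
        epochs = constant_epochs([1.0, 2.0], ["match", "match"])
        with pytest.raises(ValueError, match="mismatch"):
            average_by_condition(epochs, region_map={})

    def test_permutation_invariance(self, constant_epochs):
        epochs = constant_epochs([1.0, 5.0, 2.0, 8.0], ["match", "mismatch", "match", "mismatch"])
        shuffled = epochs.subset(np.array([3, 0, 2, 1]))
        a = average_by_condition(epochs, region_map={})
        b = average_by_condition(shuffled, region_map={})
        assert np.allclose(a.erp_match, b.erp_match)
        assert np.allclose(a.erp_difference, b.erp_difference)

    def test_pipeline_linearity(self, constant_epochs):
        rng = np.random.default_rng(3)
        epochs = constant_epochs([0.0] * 6, ["match", "mismatch"] * 3)
        epochs.data += rng.normal(size=epochs.data.shape)
        scaled = epochs.subset(np.arange(6))
        scaled.data *= 2.5
        a = average_by_condition(epochs, region_map={})
        b = average_by_condition(scaled, region_map={})
        assert np.allclose(b.erp_match, 2.5 * a.erp_match)
        assert np.allclose(b.erp_difference, 2.5 * a.erp_difference)

    def test_against_mne_condition_averages(self, constant_epochs):
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(9)
        conditions = ["match", "mismatch"] * 10
        epochs = constant_epochs([0.0] * 20, conditions, n_channels=4)
        epochs.data += rng.normal(size=epochs.data.shape)
        result = average_by_condition(epochs, region_map={})

        info = mne.create_info(epochs.channel_labels, epochs.sampling_rate, "eeg")
        arr = np.transpose(epochs.data, (2, 0, 1)) * 1e-6  # to volts
        events = np.column_stack(
            [np.arange(20), np.zeros(20, int), [1 if c == "match" else 2 for c in conditions]]
        )
        mne_epochs = mne.EpochsArray(
            arr, info, events=events, event_id={"match": 1, "mismatch": 2},
            tmin=epochs.tmin_ms / 1000.0, baseline=None, verbose="error",
        )
        for cond, ours in (("match", result.erp_match), ("mismatch", result.erp_mismatch)):
            theirs = mne_epochs[cond].average().data * 1e6
            assert np.allclose(ours, theirs, atol=1e-9)


class TestPeakLatency:
    def test_gaussian_bump_recovered_to_one_sample(self, constant_epochs):
        epochs = constant_epochs([0.0], ["match"])
        t = times_of(epochs)
        wave = 6.0 * np.exp(-((t - 376.0) ** 2) / (2 * 40.0**2))
        peak = peak_latency(wave, t, (300.0, 500.0), "positive")
        assert abs(peak.latency_ms - 376.0) <= 4.0
        assert peak.amplitude_uv == pytest.approx(6.0, abs=0.01)

    def test_monotone_ramp_peaks_at_window_edge(self, constant_epochs):
        epochs = constant_epochs([0.0], ["match"])
        t = times_of(epochs)
        peak = peak_latency(t.copy(), t, (300.0, 500.0), "positive")
        assert peak.latency_ms == t[(t >= 300) & (t <= 500)][-1]

    def test_negative_polarity_mirrors_positive(self, constant_epochs):
        epochs = constant_epochs([0.0], ["match"])
        t = times_of(epochs)
        wave = 6.0 * np.exp(-((t - 376.0) ** 2) / (2 * 40.0**2))
        pos = peak_latency(wave, t, (300.0, 500.0), "positive")
        neg = peak_latency(-wave, t, (300.0, 500.0), "negative")
        assert pos.latency_ms == neg.latency_ms
        assert neg.amplitude_uv == -pos.amplitude_uv

    def test_flat_waveform_flagged(self, constant_epochs):
        epochs = constant_epochs([0.0], ["match"])
        t = times_of(epochs)
        peak = peak_latency(np.zeros_like(t), t, (300.0, 500.0))
        assert peak.flat
        assert peak.latency_ms == t[(t >= 300) & (t <= 500)][0]

    def test_too_short_window_rejected(self, constant_epochs):
        epochs = constant_epochs([0.0], ["match"])
        t = times_of(epochs)
        with pytest.raises(ValueError):
            peak_latency(t.copy(), t, (300.0, 304.0))


class TestEpochSetValidation:
    def test_sample_grid_snaps_published_window(self):
        # -1300..+950 ms at 250 Hz: 563 samples, last one at +948 ms
        assert n_samples_for_window(-1300.0, 950.0, 250.0) == 563

    def test_wrong_sample_count_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            EpochSet(
                data=np.zeros((2, 100, 1)),
                trial_meta=pd.DataFrame(
                    {
                        "condition": ["match"],
                        "reaction_time_s": [0.5],
                        "baseline_start_ms": [-1300.0],
                        "baseline_end_ms": [-700.0],
                    }
                ),
                channel_labels=["a", "b"],
            )

    def test_region_map_covers_default_montage(self):
        from trustwalk.erp import DEFAULT_CHANNELS

        members = [ch for chans in DEFAULT_REGION_MAP.values() for ch in chans]
        assert set(members) <= set(DEFAULT_CHANNELS)
        assert len(members) == len(set(members))
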