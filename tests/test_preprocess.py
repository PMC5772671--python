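"""Preprocessing chain: filtering, labelling, exclusion, epoching, baseline
and robust averaging."""

import numpy as np
import pytest
from scipy import signal

import bistream as bs
from bistream.preprocess import AMBIGUOUS
from bistream.synth import BUTTON_CODES


def _recording_from_array(data, fs=600.0, onsets=None, button=None):
    n = data.shape[1]
    if onsets is None:
        onsets = np.arange(0, n - 359, 360)
    if button is None:
        button = np.full(n, BUTTON_CODES["gallop"], dtype=np.int8)
    return bs.Recording(
        data=data,
        fs_hz=fs,
        channel_pos=np.zeros((data.shape[0], 3)),
        stim_onsets=np.asarray(onsets),
        button_stream=button,
        meta={},
    )


class TestFilterDownsample:
    def test_dc_removed_by_highpass(self):
        rec = _recording_from_array(np.full((1, 60_000), 7.0))
        out = bs.filter_downsample(rec)
        steady = out.data[0, 5000:-5000]
        assert np.abs(steady).max() < 0.01 * 7.0

    def test_passband_sine_preserved(self):
        t = np.arange(120_000) / 600.0
        rec = _recording_from_array(np.sin(2 * np.pi * 10 * t)[None, :])
        out = bs.filter_downsample(rec)
        steady = out.data[0, 10_000:-10_000]
        assert abs(np.abs(steady).max() - 1.0) < 0.02

    def test_stopband_sine_attenuated(self):
        t = np.arange(120_000) / 600.0
        rec = _recording_from_array(np.sin(2 * np.pi * 90 * t)[None, :])
        out = bs.filter_downsample(rec)
        assert np.abs(out.data[0, 10_000:-10_000]).max() < 0.01

    def test_output_length_and_event_rescaling(self):
        rec = _recording_from_array(np.zeros((2, 36_000)))  # 60 s at 600 Hz
        out = bs.filter_downsample(rec)
        assert out.data.shape == (2, 18_000)  # 60 s x 300 Hz
        assert out.fs_hz == 300.0
        np.testing.assert_array_equal(out.stim_onsets, rec.stim_onsets // 2)
        assert out.button_stream.shape == (18_000,)

    def test_nyquist_precondition(self):
        rec = _recording_from_array(np.zeros((1, 1000)), fs=50.0, onsets=[0])
        with pytest.raises(ValueError):
            bs.filter_downsample(rec)


class TestLabelTrials:
    def _rec(self, stream):
        return _recording_from_array(
            np.zeros((1, len(stream))), fs=300.0,
            onsets=np.arange(0, len(stream) - 179, 180), button=np.asarray(stream, np.int8),
        )

    def test_constant_stream_labels_all_trials(self):
        rec = self._rec(np.full(900, BUTTON_CODES["gallop"]))
        assert list(bs.label_trials(rec)) == ["gallop"] * 5

    def test_both_and_none_are_ambiguous(self):
        stream = np.full(900, BUTTON_CODES["segregated"])
        stream[180:360] = BUTTON_CODES["both"]
        stream[360:540] = BUTTON_CODES["none"]
        rec = self._rec(stream)
        assert list(bs.label_trials(rec)) == [
            "segregated", AMBIGUOUS, AMBIGUOUS, "segregated", "segregated",
        ]

    def test_mid_trial_switch_is_ambiguous(self):
        stream = np.full(540, BUTTON_CODES["gallop"])
        stream[180 + 90 :] = BUTTON_CODES["segregated"]  # switch at 300 ms of trial 2
        rec = self._rec(stream)
        assert list(bs.label_trials(rec)) == ["gallop", AMBIGUOUS, "segregated"]


class TestExcludeSwitchAdjacent:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["gallop"] * 4, [True] * 4),
            (
                ["gallop", "gallop", "gallop", "segregated", "segregated", "segregated"],
                [True, True, False, False, True, True],
            ),
            (["gallop", "segregated", "gallop"], [False, False, False]),
            (
                ["gallop", AMBIGUOUS, "segregated"],
                [False, False, False],  # switch across the ambiguous gap
            ),
        ],
    )
    def test_rule_by_hand(self, labels, expected):
        assert list(bs.exclude_switch_adjacent(np.array(labels))) == expected

    def test_n_exclude_two_drops_wider_margin(self):
        labels = np.array(["gallop"] * 4 + ["segregated"] * 4)
        mask = bs.exclude_switch_adjacent(labels, n_exclude=2)
        assert list(mask) == [True, True, False, False, False, False, True, True]

    def test_conservation(self, small_recording):
        filtered = bs.filter_downsample(small_recording)
        labels = bs.label_trials(filtered)
        mask = bs.exclude_switch_adjacent(labels)
        assert mask.sum() + (~mask).sum() == len(filtered.stim_onsets)


class TestEpoch:
    def test_epoch_is_identity_slice_at_onset_zero(self):
        data = np.arange(2 * 720, dtype=float).reshape(2, 720)
        rec = _recording_from_array(
            data, fs=300.0, onsets=[0, 180, 360],
            button=np.full(720, BUTTON_CODES["gallop"], np.int8),
        )
        ep = bs.epoch(rec)
        assert ep.data.shape == (3, 2, 180)
        np.testing.assert_array_equal(ep.data[0], data[:, :180])

    def test_trial_past_end_dropped(self):
        rec = _recording_from_array(
            np.zeros((1, 400)), fs=300.0, onsets=[0, 180, 350],
            button=np.full(400, BUTTON_CODES["gallop"], np.int8),
        )
        ep = bs.epoch(rec)
        assert ep.n_trials == 2

    def test_retained_bookkeeping(self, small_recording):
        ep = bs.preprocess_recording(small_recording)
        assert ep.data.shape[2] == 180
        assert ep.n_retained == ep.retained.sum()
        data, labels = ep.select()
        assert data.shape[0] == ep.n_retained
        assert set(labels) <= {"gallop", "segregated"}

    def test_empty_retained_raises(self):
        rec = _recording_from_array(
            np.zeros((1, 720)), fs=300.0, onsets=[0, 180],
            button=np.full(720, BUTTON_CODES["none"], np.int8),
        )
        with pytest.raises(ValueError):
            bs.epoch(rec)


class TestBaseline:
    def test_default_window_zeroes_trial_means(self, small_epochs):
        means = small_epochs.data.mean(axis=2)
        np.testing.assert_allclose(means, 0.0, atol=1e-10)

    def test_constant_offset_removed_shape_preserved(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((3, 2, 180))
        base -= base.mean(axis=2, keepdims=True)
        ep = bs.EpochSet(
            data=base + 5.0,
            fs_hz=300.0,
            window_ms=(0.0, 600.0),
            labels=np.array(["gallop"] * 3),
            retained=np.ones(3, bool),
            trial_onset_samples=np.arange(3) * 180,
        )
        out = bs.baseline_correct(ep)
        np.testing.assert_allclose(out.data, base, atol=1e-10)
        # idempotent on already zero-mean data
        out2 = bs.baseline_correct(out)
        np.testing.assert_allclose(out2.data, out.data, atol=1e-12)


class TestRobustAverage:
    def test_identical_trials_equal_plain_mean_with_unit_weights(self):
        trial = np.sin(np.linspace(0, 6, 180))[None, :]
        data = np.repeat(trial[None, :, :], 8, axis=0)
        est, w = bs.robust_average(data)
        np.testing.assert_allclose(est, trial, atol=1e-12)
        np.testing.assert_array_equal(w, 1.0)

    def test_gross_outlier_downweighted(self):
        clean = np.sin(np.linspace(0, 6, 180))
        data = np.repeat(clean[None, None, :], 21, axis=0)
        t_bad = 90
        data = data.copy()
        data[20, 0, t_bad] += 100.0
        est, w = bs.robust_average(data)
        assert w[20, 0, t_bad] < 0.01
        assert abs(est[0, t_bad] - clean[t_bad]) < 0.01 * abs(clean[t_bad]) + 1e-9

    def test_average_is_convex_combination(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((10, 3, 40))
        est, _ = bs.robust_average(data)
        assert np.all(est <= data.max(axis=0) + 1e-12)
        assert np.all(est >= data.min(axis=0) - 1e-12)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            bs.robust_average(np.zeros((1, 2, 10)))


class TestNoiselessRecovery:
    def test_evoked_difference_matches_filtered_ground_truth(self, small_cfg):
        """With zero noise the pipeline's evoked difference equals the
        planted source difference passed through the same filters (the 30 Hz
        low-pass itself reshapes the 17 ms boxcar, so the comparison is
        against the filtered waveform)."""
        a = 3.0
        proc = bs.PerceptProcess(mu_log=np.log(5.0), sigma_log=0.3, seed=6)
        eff = bs.SourceEffect(
            positions=[[54.0, -14.0, 11.0]], effect_amplitude=a,
            button_latency_sd_ms=0.0, button_latency_mean_ms=0.0,
        )
        rec = bs.generate_dataset(
            small_cfg, proc, eff, seed=6, n_sensors=12, n_background_sources=4,
            noise_sd=0.0, ambiguous_none_prob=0.0, ambiguous_both_prob=0.0,
        )
        ep = bs.preprocess_recording(rec)
        pair = bs.evoked_pair(ep)
        diff = pair.evoked_segregated - pair.evoked_gallop

        # ground truth difference, identically filtered and decimated
        lead_col = rec.lead_field[:, 0]
        box = np.zeros(rec.n_samples)
        lo = int(round(0.250 * small_cfg.fs_hz))
        hi = int(round(0.267 * small_cfg.fs_hz))
        box[10 * small_cfg.samples_per_trial + lo : 10 * small_cfg.samples_per_trial + hi] = a
        sos_hp = signal.butter(5, 0.1, "highpass", fs=small_cfg.fs_hz, output="sos")
        sos_lp = signal.butter(5, 30, "lowpass", fs=small_cfg.fs_hz, output="sos")
        ref = signal.sosfiltfilt(sos_lp, signal.sosfiltfilt(sos_hp, box))[::2]
        ref_trial = ref[10 * 180 : 11 * 180]
        # per-sensor scaling by the lead-field column; baseline offsets differ
        expected = np.outer(lead_col, ref_trial - ref_trial.mean())
        err = np.abs(diff - (diff.mean(axis=1, keepdims=True) - 0) - expected)
        assert err.max() < 0.05 * a
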