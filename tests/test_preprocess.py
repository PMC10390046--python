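"""Tests of the envelope preprocessing chain and cycle selection."""

import numpy as np
import pytest
from scipy import signal as sps

import locomod as lm
from locomod.errors import DataError, InsufficientDataError, ParameterError
from locomod.preprocess import Cycle, moving_median_smooth, moving_median_window

from conftest import make_event_stream


def naive_sliding_median(x: np.ndarray, window: int) -> np.ndarray:
    """Independent shrinking-window sliding median (centered-left)."""
    n = len(x)
    left = window // 2
    right = window - 1 - left
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        out[i] = np.median(x[lo:hi])
    return out


def naive_two_segment_resample(env, rate, cycle, t0=0.0):
    """Independent per-phase linear interpolation onto the 200-point grid."""
    t = t0 + np.arange(len(env)) / rate
    flex = [cycle.bhf_start + k / 79 * (cycle.bhe - cycle.bhf_start) for k in range(80)]
    ext = [cycle.bhe + k / 120 * (cycle.bhf_end - cycle.bhe) for k in range(1, 121)]
    targets = np.array(flex + ext)
    out = np.empty(200)
    for k, tt in enumerate(targets):
        j = np.searchsorted(t, tt)
        if j == 0:
            out[k] = env[0]
        elif j >= len(t):
            out[k] = env[-1]
        else:
            w = (tt - t[j - 1]) / (t[j] - t[j - 1])
            out[k] = (1 - w) * env[j - 1] + w * env[j]
    return out


class TestHighpassRectify:
    def test_dc_component_is_rejected(self):
        rec = lm.EMGRecording(np.full((4000, 2), 3.0), 2000.0, ["a", "b"])
        out = lm.highpass_rectify(rec)
        core = out.signal[500:-500]
        assert core.max() < 1e-6 * 3.0
        assert out.signal.min() >= 0.0

    def test_rms_ratio_matches_designed_frequency_response(self):
        fs = 2000.0
        t = np.arange(0, 10.0, 1 / fs)
        sig = np.stack([np.sin(2 * np.pi * 5 * t), np.sin(2 * np.pi * 200 * t)], axis=1)
        out = lm.highpass_rectify(lm.EMGRecording(sig, fs, ["low", "high"]))
        core = out.signal[4000:-4000]
        measured = np.sqrt((core**2).mean(axis=0))
        sos = sps.butter(4, 40.0, btype="highpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=np.array([5.0, 200.0]), fs=fs)
        gain = np.abs(h) ** 2  # forward-backward filtering squares the magnitude
        assert measured[1] / measured[0] == pytest.approx(gain[1] / gain[0], rel=0.05)

    def test_output_is_nonnegative_for_arbitrary_input(self, rng):
        rec = lm.EMGRecording(rng.standard_normal((2000, 3)), 1000.0, list("abc"))
        assert lm.highpass_rectify(rec).signal.min() >= 0.0

    def test_rate_at_or_below_twice_corner_raises(self):
        rec = lm.EMGRecording(np.zeros((100, 2)), 80.0, ["a", "b"])
        with pytest.raises(ParameterError):
            lm.highpass_rectify(rec)


class TestMovingMedian:
    @pytest.mark.parametrize(
        "group,expected", [("newborn", 400), ("three_months", 200), ("toddler", 100)]
    )
    def test_window_scales_with_age_group(self, group, expected):
        assert moving_median_window(group) == expected

    def test_unknown_age_group_raises(self):
        with pytest.raises(ParameterError):
            moving_median_window("adult")

    def test_constant_signal_is_unchanged(self):
        x = np.full(500, 2.5)
        np.testing.assert_array_equal(moving_median_smooth(x, 11), x)

    def test_isolated_spike_is_removed(self):
        x = np.zeros(200)
        x[100] = 100.0
        assert moving_median_smooth(x, 11).max() == 0.0

    @pytest.mark.parametrize("window", [4, 5, 100])
    def test_matches_naive_sliding_median(self, rng, window):
        x = rng.standard_normal(300)
        np.testing.assert_allclose(
            moving_median_smooth(x, window), naive_sliding_median(x, window), atol=1e-14
        )

    def test_two_dimensional_input_is_smoothed_per_channel(self, rng):
        x = rng.standard_normal((200, 3))
        out = moving_median_smooth(x, 7)
        for ch in range(3):
            np.testing.assert_allclose(out[:, ch], naive_sliding_median(x[:, ch], 7))

    def test_window_longer_than_signal_raises(self):
        with pytest.raises(ParameterError):
            moving_median_smooth(np.zeros(10), 11)


class TestSelectAlternatedCycles:
    def test_nine_cycle_alternating_bout_keeps_seven(self):
        ev = make_event_stream(9, phase=0.5)
        retained = lm.select_alternated_cycles(ev, "right")
        assert len(retained) == 7
        # brute-force check of all three rules on the constructed timeline
        all_cycles = [Cycle(2.0 + k, 2.4 + k, 3.0 + k) for k in range(9)]
        for cyc in retained:
            assert any(abs(cyc.bhf_start - c.bhf_start) < 1e-9 for c in all_cycles[1:-1])

    def test_phase_below_ten_percent_excludes_every_cycle(self):
        ev = make_event_stream(9, phase=0.05)
        assert lm.select_alternated_cycles(ev, "right") == []

    def test_phase_band_is_inclusive_at_ten_percent(self):
        ev = make_event_stream(9, phase=0.10)
        assert len(lm.select_alternated_cycles(ev, "right")) == 7

    def test_two_cycle_bout_retains_nothing(self):
        ev = make_event_stream(2, phase=0.5)
        assert lm.select_alternated_cycles(ev, "right") == []

    def test_min_cycles_raises_insufficient_data(self):
        ev = make_event_stream(5, phase=0.5)  # 3 retained
        with pytest.raises(InsufficientDataError):
            lm.select_alternated_cycles(ev, "right", min_cycles=5)


class TestTimeNormalize:
    def _ramp_recording(self, rate=1000.0, total=3.0):
        t = np.arange(0, total, 1 / rate)
        return t, t.copy()  # envelope equal to time

    def test_linear_ramp_stays_linear_within_each_phase(self):
        rate = 1000.0
        t, env = self._ramp_recording(rate)
        cycle = Cycle(0.5, 1.1, 2.0)
        out = lm.time_normalize(env, rate, cycle)
        flex_d = np.diff(out[:80])
        ext_d = np.diff(out[80:])
        np.testing.assert_allclose(flex_d, flex_d[0], atol=1e-9)
        np.testing.assert_allclose(ext_d, ext_d[0], atol=1e-9)

    def test_sample_80_anchors_on_the_bhe_instant(self):
        rate = 1000.0
        t, env = self._ramp_recording(rate)
        cycle = Cycle(0.5, 0.9, 1.5)  # flexion exactly 40% of the cycle
        out = lm.time_normalize(env, rate, cycle)
        assert out[79] == pytest.approx(0.9, abs=1e-9)
        assert out.shape == (200,)

    def test_matches_independent_two_segment_oracle(self, rng):
        rate = 500.0
        env = rng.random(1500)
        cycle = Cycle(0.31, 0.94, 2.17)
        out = lm.time_normalize(env, rate, cycle)
        np.testing.assert_allclose(out, naive_two_segment_resample(env, rate, cycle), atol=1e-10)

    def test_cycle_outside_recording_raises(self):
        with pytest.raises(DataError):
            lm.time_normalize(np.ones(100), 100.0, Cycle(0.1, 0.5, 2.0))


class TestAmplitudeNormalize:
    def test_channel_max_becomes_one(self, rng):
        data = rng.random((5, 200, 3)) * np.array([7.3, 1.0, 0.2])
        out = lm.amplitude_normalize(data, "ensemble")
        np.testing.assert_allclose(out.max(axis=(0, 1)), 1.0, atol=1e-12)

    def test_idempotent_on_normalized_input(self, rng):
        data = lm.amplitude_normalize(rng.random((5, 200, 2)), "ensemble")
        np.testing.assert_allclose(lm.amplitude_normalize(data, "ensemble"), data, atol=1e-15)

    def test_ensemble_scope_dominates_whole_signal_scope(self, rng):
        data = rng.random((5, 200, 2))
        whole = np.concatenate([data.reshape(-1, 2), 2.0 * np.ones((10, 2))])
        ens = lm.amplitude_normalize(data, "ensemble")
        whl = lm.amplitude_normalize(data, "whole_signal", whole_signal_envelope=whole)
        assert (ens >= whl - 1e-15).all()

    def test_zero_channel_names_the_muscle(self):
        data = np.zeros((5, 200, 2))
        data[:, :, 0] = 1.0
        with pytest.raises(DataError, match="TA"):
            lm.amplitude_normalize(data, "ensemble", muscle_labels=["RF", "TA"])


class TestCrosstalkScreen:
    def test_channel_against_itself_is_flagged(self, rng):
        sig = rng.standard_normal((1000, 2))
        rec = lm.EMGRecording(sig, 1000.0, ["a", "b"])
        res = lm.crosstalk_screen(rec, [("a", "a")])
        assert res[0]["r"] == pytest.approx(1.0) and res[0]["flagged"]

    def test_independent_noise_is_rarely_flagged(self):
        flags = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            rec = lm.EMGRecording(g.standard_normal((4000, 2)), 1000.0, ["a", "b"])
            flags += lm.crosstalk_screen(rec, [("a", "b")])[0]["flagged"]
        assert flags / 100 < 0.05

    def test_correlation_exactly_at_threshold_is_not_flagged(self):
        t = np.arange(4000)
        u = np.sin(2 * np.pi * 8 * t / 4000)
        v = np.cos(2 * np.pi * 8 * t / 4000)
        y = 0.2 * u + np.sqrt(1 - 0.04) * v
        rec = lm.EMGRecording(np.stack([u, y], 1), 1000.0, ["a", "b"])
        res = lm.crosstalk_screen(rec, [("a", "b")])
        assert res[0]["r"] == pytest.approx(0.2, abs=1e-9)
        assert not res[0]["flagged"]

    def test_constant_channel_reports_nan_with_warning(self):
        sig = np.stack([np.ones(100), np.arange(100.0)], 1)
        rec = lm.EMGRecording(sig, 1000.0, ["a", "b"])
        res = lm.crosstalk_screen(rec, [("a", "b")])
        assert np.isnan(res[0]["r"]) and res[0]["warning"] and not res[0]["flagged"]


class TestFullChain:
    def test_round_trip_recovers_ground_truth_envelopes(self):
        spec = lm.SynthSpec(
            n_spatial=3, n_temporal=3, n_cycles=7, activation_jitter=0.3,
            spatial_sparsity=0.5, temporal_peak_width=0.3, noise_sd=0.0, seed=5,
        )
        gt = lm.generate_ground_truth(spec)
        g = np.random.default_rng(1)
        durations = 1.5 * g.uniform(0.95, 1.05, 7)
        rec, ev = lm.render_raw_recording(gt, 2000.0, durations, np.full(7, 0.4))
        env = lm.preprocess_envelope(rec, "newborn")
        cycles = lm.select_alternated_cycles(ev, "right")
        assert len(cycles) == 5  # 7 rendered, 2 lost to edge exclusion
        ens = lm.build_ensemble(env, rec.rate, cycles, muscle_labels=rec.muscle_labels)
        truth = lm.render_ensemble(gt)[1:6]
        for m in range(10):
            r = np.corrcoef(ens.data[:, :, m].ravel(), truth[:, :, m].ravel())[0, 1]
            assert r > 0.9

    def test_pipeline_output_shape_and_nonnegativity(self):
        spec = lm.SynthSpec(n_spatial=2, n_temporal=2, n_cycles=7, spatial_sparsity=0.1, seed=3)
        gt = lm.generate_ground_truth(spec)
        rec, ev = lm.render_raw_recording(
            gt, 2000.0, np.full(7, 1.0), np.full(7, 0.4)
        )
        env = lm.preprocess_envelope(rec, "toddler")
        cycles = lm.select_alternated_cycles(ev, "right")
        ens = lm.build_ensemble(env, rec.rate, cycles[:5])
        assert ens.data.shape == (5, 200, 10)
        assert np.isfinite(ens.data).all() and ens.data.min() >= 0.0
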