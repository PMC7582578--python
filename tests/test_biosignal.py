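"""PPG filtering, heart-rate estimation, Hampel cleaning, core-temperature arithmetic."""

import numpy as np
import pytest

from heatwatch import (
    SignalTrace,
    bandpass_ppg,
    body_part_alpha,
    estimate_core_temperature,
    estimate_heart_rate,
    generate_ppg,
    generate_skin_temp,
    hampel_filter_temp,
    threshold_filter_ppg,
)


def _sine(freq, fs=50.0, duration=30.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return SignalTrace(values=amp * np.sin(2 * np.pi * freq * t), fs=fs)


class TestBandpass:
    def test_dc_removed(self):
        trace = SignalTrace(values=np.full(2000, 5.0), fs=50.0)
        out = bandpass_ppg(trace)
        assert len(out) == len(trace)
        assert np.abs(out.values[200:-200]).max() < 1e-6 * 5.0

    @pytest.mark.parametrize(
        "freq,lo,hi", [(1.5, 0.9, 1.1), (2.5, 0.9, 1.1), (10.0, 0.0, 0.1), (0.05, 0.0, 0.1)]
    )
    def test_amplitude_response(self, freq, lo, hi):
        # steady-state amplitude ratio measured away from the edges
        out = bandpass_ppg(_sine(freq))
        amp = np.abs(out.values[len(out) // 4 : -len(out) // 4]).max()
        assert lo <= amp <= hi

    def test_linearity(self):
        x, y = _sine(1.0), _sine(2.0)
        combo = SignalTrace(values=2.0 * x.values + 3.0 * y.values, fs=50.0)
        lhs = bandpass_ppg(combo).values
        rhs = 2.0 * bandpass_ppg(x).values + 3.0 * bandpass_ppg(y).values
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError):
            bandpass_ppg(SignalTrace(values=np.zeros(100), fs=8.0))


class TestThresholdFilter:
    def test_all_in_band_identity(self):
        trace = _sine(1.5)
        out = threshold_filter_ppg(trace, -2.0, 2.0)
        assert out.mask.all()
        assert np.array_equal(out.values, trace.values)

    def test_single_spike_masked(self):
        v = np.zeros(100)
        v[40] = 10.0
        out = threshold_filter_ppg(SignalTrace(values=v, fs=50.0), -2.0, 2.0)
        assert not out.mask[40]
        assert out.mask.sum() == 99

    def test_injected_clipping_artifacts_masked(self):
        trace, _, artifact = generate_ppg(
            [(0.0, 72.0)], duration_s=60.0, snr_db=20.0, artifact_frac=0.05, seed=7
        )
        out = threshold_filter_ppg(trace, -2.5, 2.5)
        caught = (~out.mask)[artifact].mean()
        assert caught >= 0.95

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            threshold_filter_ppg(_sine(1.0), 2.0, -2.0)


class TestHeartRate:
    @pytest.mark.parametrize("bpm", [72.0, 180.0])
    def test_recovers_clean_rate(self, bpm):
        trace, _, _ = generate_ppg([(0.0, bpm)], duration_s=60.0, snr_db=30.0, seed=3)
        series = estimate_heart_rate(bandpass_ppg(trace))
        est = series.hr[series.valid]
        assert len(est) > 0
        assert np.all(np.abs(est - bpm) <= 2.0)

    def test_flat_trace_flagged_invalid(self):
        series = estimate_heart_rate(SignalTrace(values=np.zeros(1000), fs=50.0))
        assert not series.valid.any()
        assert np.isnan(series.hr).all()

    def test_rejects_empty_trace(self):
        with pytest.raises(ValueError):
            estimate_heart_rate(SignalTrace(values=np.array([]), fs=50.0))

    def test_rejects_short_window(self):
        with pytest.raises(ValueError):
            estimate_heart_rate(_sine(1.0), window_s=2.0)


class TestHampel:
    def test_single_spike_replaced(self):
        v = np.full(50, 36.0)
        v[20] = 45.0
        out = hampel_filter_temp(SignalTrace(values=v, fs=1 / 60))
        assert out.values[20] == 36.0
        assert np.array_equal(np.delete(out.values, 20), np.delete(v, 20))

    def test_linear_drift_untouched(self):
        v = np.linspace(33.0, 36.0, 120)
        out = hampel_filter_temp(SignalTrace(values=v, fs=1 / 60))
        assert np.allclose(out.values, v)

    def test_injected_spike_correction(self):
        trace, spikes = generate_skin_temp(
            480, spike_rate=0.02, spike_mag_c=4.0, seed=11
        )
        out = hampel_filter_temp(trace)
        corrected = np.abs(out.values[spikes] - trace.values[spikes]) > 1.0
        assert corrected.mean() >= 0.95
        clean = np.setdiff1d(np.arange(len(trace)), spikes)
        altered = out.values[clean] != trace.values[clean]
        assert altered.mean() < 0.01

    def test_idempotent(self):
        trace, _ = generate_skin_temp(240, spike_rate=0.02, spike_mag_c=4.0, seed=5)
        once = hampel_filter_temp(trace)
        twice = hampel_filter_temp(once)
        assert np.allclose(once.values, twice.values)

    def test_short_trace_warns_and_passes_through(self):
        v = np.array([36.0, 36.1, 36.2])
        with pytest.warns(UserWarning):
            out = hampel_filter_temp(SignalTrace(values=v, fs=1 / 60), half_window=5)
        assert np.array_equal(out.values, v)

    def test_validates_parameters(self):
        trace = SignalTrace(values=np.zeros(50), fs=1.0)
        with pytest.raises(ValueError):
            hampel_filter_temp(trace, half_window=0)
        with pytest.raises(ValueError):
            hampel_filter_temp(trace, k=0.0)


class TestCoreTemperature:
    def test_zero_gradient_identity(self):
        for part in ("rectal", "head", "torso", "hand", "foot"):
            assert estimate_core_temperature(36.0, 36.0, part) == 36.0

    @pytest.mark.parametrize(
        "part,expected", [("hand", 40.599), ("foot", 49.0842)]
    )
    def test_direct_substitution(self, part, expected):
        assert estimate_core_temperature(36.0, 30.0, part) == pytest.approx(expected)

    def test_default_part_is_hand(self):
        assert body_part_alpha("hand") == 0.7665
        assert estimate_core_temperature(36.0, 30.0) == estimate_core_temperature(
            36.0, 30.0, "hand"
        )

    def test_monotone_in_skin_and_ambient(self):
        base = estimate_core_temperature(36.0, 30.0, "torso")
        assert estimate_core_temperature(36.5, 30.0, "torso") > base
        assert estimate_core_temperature(36.0, 30.5, "torso") < base

    def test_rejects_unknown_part(self):
        with pytest.raises(ValueError):
            estimate_core_temperature(36.0, 30.0, "elbow")
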