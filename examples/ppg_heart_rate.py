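"""Heart rate from a raw, noisy PPG trace with known ground truth.

Synthesises two minutes of photoplethysmogram at 10 dB SNR with 3 %
saturation artifacts while the wearer's rate ramps from 70 to 150 bpm,
then runs the cleaning chain (0.5-4 Hz band-pass, amplitude threshold,
windowed peak detection) and compares the estimates with the generator's
target.
"""

import numpy as np

from heatwatch import bandpass_ppg, estimate_heart_rate, generate_ppg, threshold_filter_ppg

trace, beat_times, artifact = generate_ppg(
    hr_profile=[(0.0, 70.0), (1.0, 150.0)],
    duration_s=120.0,
    fs=50.0,
    snr_db=10.0,
    artifact_frac=0.03,
    seed=3,
)
print(f"raw trace: {len(trace)} samples at {trace.fs:g} Hz, "
      f"{artifact.mean():.1%} artifact samples, {len(beat_times)} true beats")

filtered = threshold_filter_ppg(bandpass_ppg(trace), -2.5, 2.5)
series = estimate_heart_rate(filtered, window_s=10.0)

# ground-truth rate per window from the generator's beat times
print("\nwindow(s)  estimate(bpm)  truth(bpm)")
errors = []
for t, hr, ok in zip(series.times_s, series.hr, series.valid):
    in_win = (beat_times >= t - 5) & (beat_times <= t + 5)
    truth = 60.0 * (in_win.sum() - 1) / np.ptp(beat_times[in_win])
    if ok:
        errors.append(abs(hr - truth))
        print(f"{t:7.0f} {hr:12.1f} {truth:12.1f}")
    else:
        print(f"{t:7.0f}      invalid")

within = sum(e <= 2.0 for e in errors)
print(f"\n{within}/{len(errors)} windows within 2 bpm of ground truth "
      f"(worst {max(errors):.1f} bpm — at 10 dB SNR the occasional window "
      "picks up a spurious noise peak)")
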