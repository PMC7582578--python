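"""Seeded generators for device streams, weather traces and treadmill sessions.

Everything downstream of the sensors is testable offline: these generators
emulate the raw signals a wrist-worn monitor produces — a pulsatile PPG with
baseline wander, white noise and clipping artifacts; slowly drifting skin
temperature with occasional spike outliers; a diurnal weather trace — and
return the ground truth (beat times, outlier positions, target heart rates)
alongside, so every estimator can be scored exactly.

All generators are pure functions of their arguments and a seed.  Morphology
realism is a non-goal: the PPG pulse is an asymmetric raised cosine (fast
systolic rise, slow decay), adequate for rate estimation, not for waveform
analytics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biosignal import SignalTrace

__all__ = [
    "ScenarioConfig",
    "generate_ppg",
    "generate_skin_temp",
    "generate_weather_day",
    "generate_balke_session",
    "generate_scenario",
]


@dataclass
class ScenarioConfig:
    """A complete monitoring scenario: workers, physiology targets, weather.

    ``hr_profile`` and ``skin_profile`` are piecewise-constant targets as
    (start_minute, value) pairs; physiological series relax toward the
    current target with time constant ``relax_min``.
    """

    seed: int = 0
    n_workers: int = 3
    duration_min: int = 60
    cadence_min: float = 1.0  # device reporting period
    hr_profile: tuple[tuple[float, float], ...] = ((0.0, 70.0),)
    skin_profile: tuple[tuple[float, float], ...] = ((0.0, 34.0),)
    relax_min: float = 3.0
    hr_noise_bpm: float = 1.0
    skin_noise_c: float = 0.05
    skin_spike_rate: float = 0.0
    skin_spike_mag_c: float = 4.0
    ppg_fs: float = 50.0
    ppg_snr_db: float = 20.0
    ppg_artifact_frac: float = 0.0
    weather_ta_mean: float = 30.0
    weather_ta_amp: float = 5.0
    weather_rh_mean: float = 60.0
    weather_rh_amp: float = 15.0
    weather_noise: float = 0.3
    start: str = "2020-07-15T08:00:00+09:00"
    roster_ages: tuple[float, ...] = (32.0, 41.0, 50.0)
    work_intensity: str = "medium"


def _piecewise_relaxed(targets, t_min: np.ndarray, relax_min: float) -> np.ndarray:
    """Piecewise-constant targets relaxed first-order with time constant relax_min."""
    targets = sorted(targets)
    target = np.full_like(t_min, targets[0][1], dtype=float)
    for start, value in targets:
        target[t_min >= start] = value
    if relax_min <= 0 or len(t_min) < 2:
        return target
    out = np.empty_like(target)
    out[0] = target[0]
    for i in range(1, len(t_min)):
        dt = t_min[i] - t_min[i - 1]
        f = 1.0 - np.exp(-dt / relax_min)
        out[i] = out[i - 1] + f * (target[i] - out[i - 1])
    return out


def generate_ppg(
    hr_profile,
    duration_s: float,
    fs: float = 50.0,
    snr_db: float = 20.0,
    artifact_frac: float = 0.0,
    relax_min: float = 0.5,
    seed: int = 0,
) -> tuple[SignalTrace, np.ndarray, np.ndarray]:
    """Synthesise a PPG trace; return (trace, beat_times_s, artifact_mask).

    ``hr_profile`` is a sequence of (start_minute, bpm) targets in [40, 220].
    The waveform is one asymmetric raised-cosine pulse per beat (peak at 25 %
    of the beat interval), plus sub-0.5 Hz baseline wander and white Gaussian
    noise at ``snr_db`` relative to the pulse power.  ``artifact_frac`` of
    samples are overwritten, in short bursts, with saturation values; the
    boolean artifact mask (True = artifact) is returned as ground truth.
    """
    for _, bpm in hr_profile:
        if not (40 <= bpm <= 220):
            raise ValueError(f"heart-rate target {bpm} bpm outside [40, 220]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    hr_inst = _piecewise_relaxed(hr_profile, t / 60.0, relax_min)
    # beat times: integrate the instantaneous rate, beats at integer phase
    phase = np.cumsum(hr_inst / 60.0) / fs
    n_beats = int(np.floor(phase[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), phase, t)

    clean = np.zeros(n)
    bounds = np.concatenate([[0.0], beat_times, [duration_s + 1.0]])
    for i in range(1, len(bounds) - 1):
        t_b = bounds[i]
        ibi = min(bounds[i + 1] - t_b, 1.5)  # cap the pulse span at 1.5 s
        i0, i1 = int(np.ceil(t_b * fs)), min(n, int(np.floor((t_b + ibi) * fs)) + 1)
        if i1 <= i0:
            continue
        phi = (t[i0:i1] - t_b) / ibi
        peak = 0.25
        pulse = np.where(
            phi < peak,
            0.5 * (1 - np.cos(np.pi * phi / peak)),
            0.5 * (1 + np.cos(np.pi * (phi - peak) / (1 - peak))),
        )
        clean[i0:i1] += pulse

    wander = 0.3 * np.sin(2 * np.pi * 0.15 * t + rng.uniform(0, 2 * np.pi)) + 0.2 * np.sin(
        2 * np.pi * 0.35 * t + rng.uniform(0, 2 * np.pi)
    )
    p_signal = np.mean(clean**2)
    noise_sd = np.sqrt(p_signal / 10 ** (snr_db / 10.0)) if p_signal > 0 else 0.0
    values = clean + wander + rng.normal(0.0, noise_sd, n)

    artifact = np.zeros(n, dtype=bool)
    if artifact_frac > 0:
        burst = max(1, int(round(0.3 * fs)))  # ~300 ms saturation bursts
        n_bursts = max(1, int(round(artifact_frac * n / burst)))
        for start in rng.integers(0, max(1, n - burst), n_bursts):
            artifact[start : start + burst] = True
        values[artifact] = 3.0 * rng.choice([-1.0, 1.0], artifact.sum())

    return SignalTrace(values=values, fs=fs), beat_times, artifact


def generate_skin_temp(
    duration_min: float,
    baseline_c: float = 34.0,
    drift_c: float = 0.3,
    spike_rate: float = 0.0,
    spike_mag_c: float = 4.0,
    cadence_min: float = 1.0,
    seed: int = 0,
) -> tuple[SignalTrace, np.ndarray]:
    """Skin-temperature series (1 sample per ``cadence_min``) with labeled spikes.

    Baseline plus a mean-reverting random walk of scale ``drift_c``;
    ``spike_rate`` of samples are displaced by +-``spike_mag_c`` and their
    indices returned as ground-truth outlier labels.
    """
    if not (30.0 <= baseline_c <= 40.0):
        raise ValueError(f"baseline {baseline_c} degC outside [30, 40]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_min / cadence_min))
    walk = np.zeros(n)
    for i in range(1, n):
        walk[i] = 0.95 * walk[i - 1] + rng.normal(0.0, drift_c * 0.1)
    values = baseline_c + walk
    spike_idx = np.array([], dtype=int)
    if spike_rate > 0 and n > 2:
        k = int(round(spike_rate * n))
        # isolated spikes only (no adjacent pairs), so labels stay unambiguous
        candidates = rng.permutation(np.arange(1, n - 1))
        chosen: list[int] = []
        taken = np.zeros(n, dtype=bool)
        for c in candidates:
            if len(chosen) >= k:
                break
            if not taken[max(0, c - 1) : c + 2].any():
                chosen.append(int(c))
                taken[c] = True
        spike_idx = np.sort(np.array(chosen, dtype=int))
        values[spike_idx] += spike_mag_c * rng.choice([-1.0, 1.0], len(spike_idx), p=[0.2, 0.8])
    fs = 1.0 / (cadence_min * 60.0)
    return SignalTrace(values=values, fs=fs), spike_idx


def generate_weather_day(
    date: str = "2020-07-15",
    ta_mean: float = 30.0,
    ta_amp: float = 5.0,
    rh_mean: float = 60.0,
    rh_amp: float = 15.0,
    noise: float = 0.3,
    tz: str = "+09:00",
    seed: int = 0,
) -> pd.DataFrame:
    """Hourly diurnal weather trace: columns ``timestamp, ta_c, rh_pct``.

    Temperature peaks mid-afternoon (15 h); humidity runs in anti-phase.
    """
    if not (-10.0 <= ta_mean - ta_amp and ta_mean + ta_amp <= 45.0):
        raise ValueError("temperature curve outside [-10, 45] degC")
    rng = np.random.default_rng(seed)
    hours = np.arange(24)
    ta = ta_mean + ta_amp * np.cos(2 * np.pi * (hours - 15) / 24) + rng.normal(0, noise, 24)
    rh = rh_mean - rh_amp * np.cos(2 * np.pi * (hours - 15) / 24) + rng.normal(0, noise, 24)
    rh = np.clip(rh, 10.0, 100.0)
    ts = pd.to_datetime([f"{date}T{h:02d}:00:00{tz}" for h in hours])
    return pd.DataFrame({"timestamp": ts, "ta_c": ta, "rh_pct": rh})


def generate_balke_session(
    rest_hr: float = 85.0, n_stages: int = 8, jitter: bool = True, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (reference, device) heart rates for a graded treadmill test.

    Emulates a modified Balke protocol session (fixed speed, slope +2.5 % per
    stage): the reference series rises monotonically from the resting rate —
    a large first jump then steady increments — and the device series equals
    the reference plus integer jitter in {-1, 0, +1}, the discrepancy
    magnitude observed between a chest-strap reference and the wearable.
    """
    rng = np.random.default_rng(seed)
    increments = np.concatenate(
        [[rng.integers(20, 29)], rng.integers(4, 14, n_stages - 1)]
    )
    reference = rest_hr + np.concatenate([[0], np.cumsum(increments)]).astype(float)
    device = reference.copy()
    if jitter:
        device = reference + rng.integers(-1, 2, n_stages + 1)
    return reference, device


def generate_scenario(config: ScenarioConfig) -> dict[str, pd.DataFrame]:
    """Generate a full scenario: ``weather``, ``roster`` and device ``stream`` tables.

    The stream is at the device cadence with derived heart rate
    (``hr_bpm``) and skin temperature per row, the dialect the monitoring
    pipeline ingests.  Per-worker randomness is decorrelated by offsetting
    the seed with the worker index.
    """
    weather = generate_weather_day(
        date=config.start[:10],
        ta_mean=config.weather_ta_mean,
        ta_amp=config.weather_ta_amp,
        rh_mean=config.weather_rh_mean,
        rh_amp=config.weather_rh_amp,
        noise=config.weather_noise,
        tz=config.start[-6:],
        seed=config.seed,
    )
    roster_rows = []
    for i in range(config.n_workers):
        roster_rows.append(
            {
                "worker_id": f"W{i + 1:03d}",
                "name": f"Worker {i + 1}",
                "age": config.roster_ages[i % len(config.roster_ages)],
                "height_cm": 170.0,
                "weight_kg": 75.0,
                "blood_type": "O",
                "resting_hr": 60.0,
                "work_intensity": config.work_intensity,
                "device_id": f"PWB-{i + 1:03d}",
                "sensor_body_part": "hand",
            }
        )
    roster = pd.DataFrame(roster_rows)

    t0 = pd.Timestamp(config.start)
    n = int(round(config.duration_min / config.cadence_min))
    t_min = np.arange(n) * config.cadence_min
    stream_rows = []
    for i in range(config.n_workers):
        rng = np.random.default_rng(config.seed + 1000 * (i + 1))
        hr = _piecewise_relaxed(config.hr_profile, t_min, config.relax_min)
        hr = hr + rng.normal(0, config.hr_noise_bpm, n)
        skin = _piecewise_relaxed(config.skin_profile, t_min, config.relax_min)
        skin = skin + rng.normal(0, config.skin_noise_c, n)
        if config.skin_spike_rate > 0:
            k = max(1, int(round(config.skin_spike_rate * n)))
            idx = rng.choice(np.arange(1, n - 1), size=min(k, n - 2), replace=False)
            skin[idx] += config.skin_spike_mag_c
        lat = 37.2 + rng.normal(0, 1e-4, n).cumsum() * 0.01
        lon = 127.0 + rng.normal(0, 1e-4, n).cumsum() * 0.01
        for j in range(n):
            stream_rows.append(
                {
                    "timestamp": t0 + pd.Timedelta(minutes=float(t_min[j])),
                    "worker_id": f"W{i + 1:03d}",
                    "hr_bpm": round(float(hr[j]), 1),
                    "skin_temp_c": round(float(skin[j]), 2),
                    "lat": round(float(lat[j]), 6),
                    "lon": round(float(lon[j]), 6),
                    "acc_x": 0.0,
                    "acc_y": 0.0,
                    "acc_z": 1.0,
                }
            )
    stream = pd.DataFrame(stream_rows)
    return {"weather": weather, "roster": roster, "stream": stream}


#: scenario presets: a quiet resting crew and a scripted heat-strain episode
PRESETS = {
    "resting": ScenarioConfig(
        hr_profile=((0.0, 70.0),),
        skin_profile=((0.0, 33.8),),
        weather_ta_mean=30.0,
        weather_ta_amp=2.0,
    ),
    "heat_strain": ScenarioConfig(
        duration_min=60,
        hr_profile=((0.0, 80.0), (10.0, 175.0)),
        skin_profile=((0.0, 34.5), (10.0, 39.5)),
        weather_ta_mean=33.0,
        weather_ta_amp=4.0,
        weather_rh_mean=65.0,
    ),
}
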