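"""Per-worker stream monitoring: signal cleaning -> risk inference -> alerting.

Orchestrates the individual side of the platform.  For each worker the
device stream (heart rate or raw PPG, skin temperature, position) is
cleaned, the core temperature is estimated against the matched weather
observation, the duration of any abnormal physiological status is tracked,
and every sample is pushed through the personalised Mamdani risk engine.
An alert is opened at the first Attention/Danger assessment of a contiguous
episode and closed when the category falls back to Concern or below.

Also provides the indoor graded-exercise-test (GXT) error report: per-stage
absolute percentage error between a treadmill reference and the wearable,
summarised per subject and overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biosignal import (
    SignalTrace,
    bandpass_ppg,
    estimate_core_temperature,
    estimate_heart_rate,
    hampel_filter_temp,
    threshold_filter_ppg,
)
from .fuzzy import (
    FuzzySystem,
    RiskCategory,
    RiskInput,
    Rule,
    WorkerProfile,
    build_fuzzy_system,
    mamdani_infer,
)

__all__ = [
    "WorkerRecord",
    "Alert",
    "ErrorReport",
    "ingest_stream",
    "track_abnormal_duration",
    "evaluate_worker",
    "stage_errors",
    "gxt_error_report",
]

#: maximum tolerated gap when matching a device sample to a weather observation
WEATHER_MATCH_TOLERANCE = pd.Timedelta(minutes=90)


@dataclass(frozen=True)
class WorkerRecord:
    """Roster entry for one registered worker."""

    worker_id: str
    name: str = ""
    age: float = 40.0
    height_cm: float = float("nan")
    weight_kg: float = float("nan")
    blood_type: str = ""
    resting_hr: float = 60.0
    work_intensity: str = "medium"
    device_id: str = ""
    sensor_body_part: str = "hand"

    def profile(self) -> WorkerProfile:
        return WorkerProfile(
            age=self.age, resting_hr=self.resting_hr, work_intensity=self.work_intensity
        )


@dataclass(frozen=True)
class Alert:
    """One alert episode, opened at the first Attention/Danger assessment."""

    worker_id: str
    timestamp: pd.Timestamp
    category: RiskCategory
    rl: float
    reason: str


@dataclass(frozen=True)
class ErrorReport:
    """GXT validation errors: per-stage |device - reference| / reference * 100."""

    per_subject_errors: Mapping[str, np.ndarray]
    per_subject_mean: Mapping[str, float]
    per_subject_max: Mapping[str, float]
    overall_mean: float
    overall_max: float

    def to_dict(self) -> dict:
        return {
            "per_subject_errors": {k: list(v) for k, v in self.per_subject_errors.items()},
            "per_subject_mean": dict(self.per_subject_mean),
            "per_subject_max": dict(self.per_subject_max),
            "overall_mean": self.overall_mean,
            "overall_max": self.overall_max,
        }


_REQUIRED_STREAM_FIELDS = ("timestamp", "worker_id")


def ingest_stream(
    stream: pd.DataFrame, roster: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, int]:
    """Split a raw device stream into per-worker time-ordered tables.

    Returns ``(per_worker, rejects, n_malformed)``: rows whose worker_id is
    not in the roster go to ``rejects``; rows missing a timestamp or
    worker_id are counted as malformed and dropped (not fatal).
    """
    import warnings

    if stream.empty:
        warnings.warn("empty device stream", stacklevel=2)
        return {}, stream.copy(), 0
    df = stream.copy()
    malformed = df["timestamp"].isna() | df["worker_id"].isna()
    n_malformed = int(malformed.sum())
    df = df[~malformed]
    known = set(roster["worker_id"])
    rejects = df[~df["worker_id"].isin(known)]
    df = df[df["worker_id"].isin(known)]
    per_worker = {
        wid: g.sort_values("timestamp", kind="stable").reset_index(drop=True)
        for wid, g in df.groupby("worker_id", sort=True)
    }
    return per_worker, rejects.reset_index(drop=True), n_malformed


def track_abnormal_duration(
    timestamps: Sequence[pd.Timestamp], abnormal: Sequence[bool]
) -> np.ndarray:
    """Minutes the current abnormal status has persisted, per sample.

    ``abnormal`` is True when either the heart-rate or core-temperature
    dominant set is not Normal.  The counter is the elapsed time since the
    start of the current abnormal episode and resets to 0 on any normal
    sample.
    """
    timestamps = pd.DatetimeIndex(timestamps)
    t_min = np.zeros(len(timestamps))
    episode_start = None
    for i, (ts, bad) in enumerate(zip(timestamps, abnormal)):
        if not bad:
            episode_start = None
        else:
            if episode_start is None:
                episode_start = ts
            t_min[i] = (ts - episode_start).total_seconds() / 60.0
    return t_min


def _match_ambient(
    sample_times: pd.DatetimeIndex, weather: pd.DataFrame
) -> np.ndarray:
    """Ambient temperature per sample from the nearest weather observation."""
    w = weather.sort_values("timestamp")
    merged = pd.merge_asof(
        pd.DataFrame({"timestamp": sample_times}),
        w[["timestamp", "ta_c"]],
        on="timestamp",
        direction="nearest",
        tolerance=WEATHER_MATCH_TOLERANCE,
    )
    if merged["ta_c"].isna().any():
        bad = sample_times[merged["ta_c"].isna().to_numpy()]
        raise ValueError(
            f"no weather observation within {WEATHER_MATCH_TOLERANCE} of samples "
            f"spanning {bad.min()} .. {bad.max()}"
        )
    return merged["ta_c"].to_numpy()


def derive_hr_from_ppg(
    ppg: SignalTrace,
    timestamps: pd.DatetimeIndex,
    window_s: float = 10.0,
    amplitude_bounds: tuple[float, float] = (-2.5, 2.5),
) -> np.ndarray:
    """Heart rate per target timestamp from a raw PPG trace.

    Band-pass -> amplitude threshold -> windowed peak detection, then the
    windowed estimates are interpolated (nearest valid window) onto the
    requested timestamps.
    """
    filtered = bandpass_ppg(ppg)
    filtered = threshold_filter_ppg(filtered, *amplitude_bounds)
    series = estimate_heart_rate(filtered, window_s=window_s)
    ok = series.valid
    if not ok.any():
        raise ValueError("no valid heart-rate window in PPG trace")
    t0 = timestamps[0] if ppg.t0 is None else pd.Timestamp(ppg.t0)
    target_s = (timestamps - t0).total_seconds().to_numpy(dtype=float)
    return np.interp(target_s, series.times_s[ok], series.hr[ok])


def evaluate_worker(
    samples: pd.DataFrame,
    worker: WorkerRecord,
    weather: pd.DataFrame,
    rules: Sequence[Rule] | None = None,
    system: FuzzySystem | None = None,
    hampel_half_window: int = 5,
    hampel_k: float = 3.0,
) -> tuple[pd.DataFrame, list[Alert]]:
    """Assess one worker's stream sample by sample.

    ``samples`` must carry ``timestamp``, ``skin_temp_c`` and either
    ``hr_bpm`` or a raw PPG trace delivered separately (see
    :func:`derive_hr_from_ppg`).  Returns the assessment table
    (``timestamp, worker_id, hr, core_temp, T_min, rl, category, alert``)
    and the list of alert episodes.
    """
    if samples.empty:
        raise ValueError("empty sample table")
    df = samples.sort_values("timestamp", kind="stable").reset_index(drop=True)
    times = pd.DatetimeIndex(df["timestamp"])
    if "hr_bpm" not in df.columns or df["hr_bpm"].isna().all():
        raise ValueError(
            "sample table has no hr_bpm column; derive heart rate from the raw "
            "PPG first (derive_hr_from_ppg)"
        )
    hr = df["hr_bpm"].to_numpy(dtype=float)

    cadence_s = np.median(np.diff(times.asi8)) / 1e9 if len(times) > 1 else 60.0
    skin_trace = SignalTrace(
        values=df["skin_temp_c"].to_numpy(dtype=float), fs=1.0 / max(cadence_s, 1e-9)
    )
    skin = hampel_filter_temp(skin_trace, half_window=hampel_half_window, k=hampel_k).values

    ambient = _match_ambient(times, weather)
    core = estimate_core_temperature(skin, ambient, worker.sensor_body_part)

    if system is None:
        system = build_fuzzy_system(worker.profile(), rules=rules)
    w_value = worker.profile().intensity_value
    hr_var, ct_var = system.inputs["heart_rate"], system.inputs["core_temp"]
    abnormal = [
        hr_var.dominant(h) != "normal" or ct_var.dominant(c) != "normal"
        for h, c in zip(hr, core)
    ]
    t_min = track_abnormal_duration(times, abnormal)

    records, alerts = [], []
    open_alert = False
    for i in range(len(df)):
        assessment = mamdani_infer(system, RiskInput(h=hr[i], ct=core[i], w=w_value, t=t_min[i]))
        if assessment.alert and not open_alert:
            open_alert = True
            alerts.append(
                Alert(
                    worker_id=worker.worker_id,
                    timestamp=times[i],
                    category=assessment.category,
                    rl=assessment.rl,
                    reason=(
                        f"hr={hr[i]:.0f} bpm, core={core[i]:.1f} C, "
                        f"abnormal for {t_min[i]:.0f} min"
                    ),
                )
            )
        elif not assessment.alert:
            open_alert = False
        records.append(
            {
                "timestamp": times[i],
                "worker_id": worker.worker_id,
                "hr": hr[i],
                "core_temp": core[i],
                "T_min": t_min[i],
                "rl": assessment.rl,
                "category": assessment.category.value,
                "alert": assessment.alert,
            }
        )
    return pd.DataFrame(records), alerts


def stage_errors(reference: Sequence[float], device: Sequence[float]) -> np.ndarray:
    """Per-stage absolute percentage errors |device - reference| / reference * 100."""
    reference = np.asarray(reference, dtype=float)
    device = np.asarray(device, dtype=float)
    if reference.shape != device.shape:
        raise ValueError(
            f"length mismatch: reference {reference.shape} vs device {device.shape}"
        )
    return np.abs(device - reference) / reference * 100.0


def gxt_error_report(
    pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]]
) -> ErrorReport:
    """Validation error report over subjects: ``{subject: (reference, device)}``."""
    per_err = {s: stage_errors(r, d) for s, (r, d) in pairs.items()}
    per_mean = {s: float(e.mean()) for s, e in per_err.items()}
    per_max = {s: float(e.max()) for s, e in per_err.items()}
    all_err = np.concatenate(list(per_err.values()))
    return ErrorReport(
        per_subject_errors=per_err,
        per_subject_mean=per_mean,
        per_subject_max=per_max,
        overall_mean=float(all_err.mean()),
        overall_max=float(all_err.max()),
    )
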