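"""Wearable biosignal processing: PPG filtering, heart-rate and core-temperature estimation.

A wrist/arm-worn device reports a raw photoplethysmogram (PPG), skin
temperature, position and acceleration.  On a work site both optical and
thermal channels are heavily contaminated — motion artifacts, sensor
saturation, sweat — so before any physiology can be read off:

* the PPG is band-passed to the cardiac band (0.5–4 Hz, i.e. 30–240 bpm),
  amplitude-thresholded to mask saturated segments, and peak-picked to
  obtain a windowed heart-rate series;
* the skin-temperature series is cleaned with a Hampel (sliding
  median/MAD) filter, then converted to a core-temperature estimate with a
  body-part-specific gradient coefficient:
  ``Tcore = Tskin + alpha * (Tskin - Tambient)``.

The gradient coefficients (``alpha``) per sensor location ship as packaged
data; the default location is the hand/arm (alpha = 0.7665).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from ._resources import packaged_data_path

__all__ = [
    "SignalTrace",
    "HeartRateSeries",
    "body_part_alpha",
    "BODY_PARTS",
    "bandpass_ppg",
    "threshold_filter_ppg",
    "estimate_heart_rate",
    "hampel_filter_temp",
    "estimate_core_temperature",
]

#: refractory period between detected beats: one period of the 250 bpm ceiling
REFRACTORY_S = 60.0 / 250.0


@dataclass
class SignalTrace:
    """A uniformly sampled sensor series.

    ``mask`` flags valid samples (True = keep); artifact-rejection steps
    clear entries rather than dropping samples so that timing is preserved.
    """

    values: np.ndarray
    fs: float
    t0: datetime | None = None
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask must match values in length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.values) / self.fs

    def valid_mask(self) -> np.ndarray:
        return np.ones(len(self.values), dtype=bool) if self.mask is None else self.mask


@dataclass
class HeartRateSeries:
    """Windowed heart-rate estimates; ``valid`` flags windows with enough beats."""

    times_s: np.ndarray  # window-centre offsets from trace start, seconds
    hr: np.ndarray  # bpm, NaN where invalid
    valid: np.ndarray


@lru_cache(maxsize=1)
def _alpha_table() -> dict[str, float]:
    out: dict[str, float] = {}
    for line in packaged_data_path("body_part_alpha.csv").read_text().splitlines()[1:]:
        part, alpha = line.split(",")
        out[part] = float(alpha)
    return out


def body_part_alpha(part: str) -> float:
    """Core-temperature gradient coefficient for a sensor location."""
    try:
        return _alpha_table()[part]
    except KeyError:
        raise ValueError(
            f"unknown body part {part!r}; expected one of {sorted(_alpha_table())}"
        ) from None


BODY_PARTS = ("rectal", "head", "torso", "hand", "foot")


def bandpass_ppg(trace: SignalTrace, low_hz: float = 0.5, high_hz: float = 4.0) -> SignalTrace:
    """Zero-phase band-pass of a PPG trace to the cardiac band.

    A 4th-order Butterworth filter is applied forward and backward
    (``sosfiltfilt``), which removes DC and baseline wander below
    ``low_hz`` and motion/noise above ``high_hz`` without phase distortion,
    preserving beat timing.  Requires ``fs`` >= 10 Hz so the upper band
    edge is resolvable.
    """
    if trace.fs < 10.0:
        raise ValueError(f"sampling rate {trace.fs} Hz too low; need >= 10 Hz for a 4 Hz band")
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=trace.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.values)
    return replace(trace, values=filtered)


def threshold_filter_ppg(trace: SignalTrace, lo: float, hi: float) -> SignalTrace:
    """Mask samples outside the amplitude band [lo, hi] as artifacts.

    Retained sample values are unchanged; the returned trace's mask is the
    AND of any existing mask with the in-band condition.  Masked samples are
    excluded from beat detection downstream.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo!r}, hi={hi!r}")
    in_band = (trace.values >= lo) & (trace.values <= hi)
    return replace(trace, mask=trace.valid_mask() & in_band)


def estimate_heart_rate(
    trace: SignalTrace,
    window_s: float = 10.0,
    prominence_factor: float = 0.3,
    guard_s: float = 0.3,
) -> HeartRateSeries:
    """Windowed heart rate from a band-passed PPG trace by peak picking.

    Within each non-overlapping window, local maxima are detected with a
    240 ms refractory period and a prominence threshold of
    ``prominence_factor`` times the window's standard deviation; peaks on or
    within ``guard_s`` of masked (artifact) samples are discarded — the
    guard absorbs band-pass ringing that spreads a saturation burst beyond
    its flagged samples.  The window's rate is
    ``60 * (n_beats - 1) / span_seconds`` over the first-to-last beat; a
    window with fewer than two beats is flagged invalid.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if window_s < 5.0:
        raise ValueError(f"window must be >= 5 s, got {window_s!r}")
    n_win = int(window_s * trace.fs)
    if n_win < 2:
        raise ValueError("window shorter than two samples")
    mask = trace.valid_mask()
    if not mask.all() and guard_s > 0:
        guard = int(round(guard_s * trace.fs))
        invalid = np.convolve(~mask, np.ones(2 * guard + 1), mode="same") > 0
        mask = mask & ~invalid
    starts = range(0, len(trace) - n_win + 1, n_win)
    if len(trace) < n_win:
        starts = range(1)  # single short window
        n_win = len(trace)
    times, rates, valid = [], [], []
    distance = max(1, int(round(REFRACTORY_S * trace.fs)))
    for s in starts:
        seg = trace.values[s : s + n_win]
        seg_mask = mask[s : s + n_win]
        sd = seg[seg_mask].std() if seg_mask.any() else 0.0
        if sd > 0:
            peaks, _ = sps.find_peaks(seg, distance=distance, prominence=prominence_factor * sd)
            peaks = peaks[seg_mask[peaks]]
        else:
            peaks = np.array([], dtype=int)
        times.append((s + n_win / 2) / trace.fs)
        if len(peaks) < 2:
            rates.append(np.nan)
            valid.append(False)
        else:
            span = (peaks[-1] - peaks[0]) / trace.fs
            rates.append(60.0 * (len(peaks) - 1) / span)
            valid.append(True)
    return HeartRateSeries(
        times_s=np.array(times), hr=np.array(rates), valid=np.array(valid, dtype=bool)
    )


def hampel_filter_temp(
    trace: SignalTrace,
    half_window: int = 5,
    k: float = 3.0,
    min_sigma: float = 0.05,
) -> SignalTrace:
    """Hampel (sliding median/MAD) outlier correction for skin temperature.

    A sample deviating from the median of its ``2*half_window + 1``-sample
    neighbourhood by more than ``k * sigma`` — with the robust scale
    ``sigma = max(1.4826 * MAD, min_sigma)`` — is replaced by that median;
    all other samples pass unchanged.  Edges are handled by reflection.

    The ``min_sigma`` floor (default 0.05 degC, on the order of the sensor's
    quantisation/noise floor) guards the degenerate case where the windowed
    MAD collapses to ~0 on flat stretches and the bare rule would reject
    arbitrarily many clean samples.  On smooth, monotone drift the filter is
    the identity; on isolated spikes it is idempotent.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if not k > 0:
        raise ValueError("k must be positive")
    if min_sigma < 0:
        raise ValueError("min_sigma must be >= 0")
    x = trace.values
    w = 2 * half_window + 1
    if len(x) < w:
        import warnings

        warnings.warn(f"trace of {len(x)} samples shorter than Hampel window {w}; unchanged",
                      stacklevel=2)
        return replace(trace, values=x.copy())
    padded = np.pad(x, half_window, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, w)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    sigma = np.maximum(1.4826 * mad, min_sigma)
    out = np.where(np.abs(x - med) > k * sigma, med, x)
    return replace(trace, values=out)


def estimate_core_temperature(
    t_skin: float | np.ndarray,
    t_ambient: float | np.ndarray,
    part: str = "hand",
) -> float | np.ndarray:
    """Core temperature (degC) from skin and ambient temperature.

    ``Tcore = Tskin + alpha * (Tskin - Tambient)`` with the location-specific
    gradient coefficient ``alpha``; strictly increasing in skin temperature
    and decreasing in ambient temperature.
    """
    alpha = body_part_alpha(part)
    t_skin = np.asarray(t_skin, dtype=float)
    t_ambient = np.asarray(t_ambient, dtype=float)
    if not (np.all(np.isfinite(t_skin)) and np.all(np.isfinite(t_ambient))):
        raise ValueError("temperatures must be finite")
    out = t_skin + alpha * (t_skin - t_ambient)
    return float(out) if out.ndim == 0 else out
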