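# Methods

`heatwatch` implements the analytics of an IoT heat-stress monitoring
platform for outdoor workers: a group-level weather-driven heat index with
staged work/rest guidance, and an individual-level pipeline that turns
wearable sensor streams into a fuzzy-logic risk level with alerting.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not establish.

## Thermal comfort index (OHS)

The group-level index is a wet-bulb-globe-temperature derivative computed
from routine observations, in three steps.

**Wet-bulb temperature.** The Stull (2011) single-equation fit

```
Tw = Ta·atan(0.151977·√(RH + 8.313659)) + atan(Ta + RH) − atan(RH − 1.676331)
     + 0.00391838·RH^1.5·atan(0.023101·RH) − 4.686035
```

with `Ta` in °C and `RH` in percent.  The fit is stated for roughly
−20…50 °C (a warning is emitted outside); it reproduces the canonical
worked example (20 °C, 50 % → 13.70 °C) and is monotone increasing in
humidity, approaching `Ta` at saturation.

**Raw index.** `TCI = −0.24418 + 0.553991·Tw + 0.455346·Ta − 0.00217·Tw² +
0.002782·Tw·Ta`, evaluated exactly.

**Correction and staging.** A time-of-day, environment-specific correction
(packaged table `tci_weights.csv`: seven environments × eight 3-hour slots)
is applied **additively** to the raw index.  Additive is the only coherent
reading: the table contains a negative entry (children at 18 h, −0.9),
which is impossible as a multiplier.  Hours map to the nearest slot, ties
rounding up.  The weighted index is classified with upper-closed half-open
intervals: Severe (30, ∞), Warning (28, 30], Caution (25, 28], Concern
(21, 25], Attention (−∞, 21] — the published ranges overlap at their
endpoints, and this convention puts the work-stoppage boundary strictly
above 30.  The lowest stage carries no action text.

## Biosignal processing

**PPG band-pass.** 4th-order Butterworth, 0.5–4 Hz (30–240 bpm cardiac
band), applied forward–backward (`sosfiltfilt`) so beat timing is
phase-true.  Requires fs ≥ 10 Hz.

**Threshold filter.** Samples outside a configurable amplitude band
(default ±2.5 in normalised pulse units) are masked as saturation
artifacts; values are never modified, only flagged, so timing is preserved.

**Heart rate.** Non-overlapping windows (default 10 s, minimum 5 s); local
maxima with a 240 ms refractory period (= one period at the 250 bpm
ceiling) and prominence ≥ 0.3 × the window standard deviation; rate is
`60·(n−1)/span` over the first-to-last peak.  Peaks within 0.3 s of a
masked sample are discarded — band-pass ringing spreads a saturation burst
beyond its flagged samples, and without this guard artifact-adjacent
windows overestimate the rate.  Windows with fewer than two accepted peaks
are flagged invalid rather than emitting a number.

**Skin-temperature cleaning.** Hampel filter: a sample deviating from its
11-sample (half-window 5) windowed median by more than `k·σ` (k = 3) is
replaced by that median, with the robust scale `σ = max(1.4826·MAD,
0.05 °C)`.  The 0.05 °C floor is deliberate: on flat stretches of quantised
temperature data the windowed MAD collapses toward zero and the bare rule
rejects unbounded numbers of clean samples; 0.05 °C is the order of the
device thermometer's quantisation/noise floor (its stated accuracy is
±0.3 °C).  With the floor the filter corrects ≥ 95 % of injected ≥ 3 °C
spikes while altering < 1 % of clean samples, and is idempotent.

**Core temperature.** `Tcore = Tskin + α·(Tskin − Tambient)` with a
body-part-specific gradient coefficient α (packaged `body_part_alpha.csv`):
rectal 0.0699, head 0.3094, torso 0.5067, hand 0.7665 (default — the device
is arm-worn), foot 2.1807.  The printed equation is ambiguous about
parenthesisation; `α·(Tskin − Tambient)` is the only reading under which
the body-part coefficients act as skin-to-core gradients.  Ambient
temperature is taken from the nearest weather observation within 90 min;
farther gaps are an error naming the uncovered span.

## Fuzzy risk engine (PMS)

Four inputs — heart rate `H` (bpm), core temperature `CT` (°C), work
intensity `W`, abnormal-status duration `T` (min) — one output, risk level
`RL` on [0, 40].

**Memberships.** Inputs use pi-shaped functions (quadratic smoothstep
ramps; value 0.5 exactly at ramp midpoints; plateaus at published band
edges).  Where adjacent published bands leave a gap (CT 32–33 and 35–36 °C,
T 14–15 and 29–30 min) the ramp spans the gap; where they share a breakpoint
(CT 38 and 40 °C, T 5 min) the ramp is centred on it with half-width
0.5 °C / 0.5 min, so membership is exactly 0.5 at the shared breakpoint.
Edge sets are shouldered to the universe bounds and out-of-universe inputs
are clamped, so every universe point keeps max membership ≥ 0.5.

**Personalised heart-rate sets.** Normal plateau up to 99 bpm; the caution
band starts at the Karvonen target `(HRmax − HRrest)·W + HRrest` with
`HRmax = 207 − 0.7·age`; the danger plateau starts at HRmax.  Work
intensity uses the published inverse class values light/medium/high =
0.75/0.5/0.25.  For high intensity (0.25) the Karvonen target can fall
below 99 bpm, and for extreme profiles it can collide with HRmax; anchors
are clamped into strict order `99 < caution target < HRmax` (at most 1 bpm
from the offending bound) so the three sets always form a valid partition.

**Core-temperature sets.** Five statuses (too-low ≤ 32, low 33–35, normal
36–38, high 38–40, too-high ≥ 40 °C).  The narrative "four sets" conflicts
with the five published statuses; five is the more specific source and is
implemented.

**Duration sets.** Safe ≤ 5, concern 5–14, attention 15–29, danger ≥ 30
min, plus a cumulative `prolonged` set (S-ramp across 14–15 min, shouldered
right).  `prolonged` exists because escalation must be monotone in `T`: the
union attention ∨ danger dips to 0.5 at the 29–30 min crossover, which
would make risk non-monotone in duration.

**Rule base.** Shipped as editable YAML (`default_rules.yaml`); clauses
combine with AND (min), OR (max within a variable's set list), NOT
(complement).  The design is monotone and auditable: the consequent is the
worse of the heart-rate severity (normal < caution < danger) and the
core-temperature severity (low/normal lowest, too-low one step up as a
sensor/physiology anomaly, high higher, too-high highest), escalated one
level while the episode is `prolonged`; heart rate at/above HRmax and core
temperature above the 40 °C heat-stroke threshold are unconditional danger.
The published rule screenshot is illegible, so this rule base is a
documented reconstruction of the described behaviour, not a transcription.

**Inference and defuzzification.** Mamdani: rule strength min-clips its
triangular output set (safe/concern/attention/danger apexes at 5, 15.5,
25.5, 35.5), clipped sets aggregate by pointwise maximum, and the crisp
risk level is the centroid of the aggregate on a 0.01-resolution grid over
[0, 40].  Categories: Safe [0, 10], Concern (10, 20], Attention (20, 30],
Danger (30, 40]; an alert is raised at Attention or above.  The achievable
centroid range is ≈ [5.2, 35.3], comfortably inside the universe.

## Monitoring pipeline

Per worker: ingest (sort, reject unknown ids, count malformed rows) →
Hampel-clean skin temperature → heart rate (given directly or derived from
raw PPG) → core temperature against matched weather → abnormal-duration
tracking (`T` is minutes since both the heart-rate and core-temperature
dominant sets were last normal; resets on any normal sample) → Mamdani
inference per sample → alerting.  One alert per contiguous
Attention/Danger episode: opened at the first alerting sample, closed when
the category falls to Concern or below.  The pipeline is deterministic:
identical inputs and configuration give byte-identical outputs.

**Validation report.** For graded-exercise-test sessions the error metric
is the per-stage absolute percentage error `|device − reference|/reference
× 100`, summarised as per-subject mean and max and overall mean and max
(both mean and max are reported because the published "< 1 %" claim does
not name its statistic).  On the packaged indoor table the per-subject
means are 0.361 %, 0.426 % and 0.184 % (overall 0.324 %), all below 1 %.

## Synthetic data

Generators are pure functions of (parameters, seed) and return ground
truth alongside the signal.

* **PPG**: one asymmetric raised-cosine pulse per beat (peak at 25 % of the
  beat interval), beats placed by integrating the instantaneous rate of a
  piecewise-constant, first-order-relaxed target profile; plus sub-0.5 Hz
  baseline wander, white noise at a stated SNR, and ~300 ms saturation
  bursts covering a stated fraction of samples.  Defaults: 50 Hz, 20 dB
  SNR.  Morphology (dicrotic notch, respiratory modulation) is not
  emulated, so green tests establish rate recovery, not waveform fidelity.
* **Skin temperature**: baseline (default 34 °C) plus an AR(1)
  mean-reverting walk (innovation 10 % of the drift scale), with isolated
  labelled spikes of stated rate and magnitude; 1 sample/min.
* **Weather**: hourly diurnal sinusoids peaking at 15 h (temperature) with
  humidity in anti-phase, plus Gaussian noise.
* **Treadmill sessions**: a monotone reference series (rest + 8 stages,
  first jump 20–28 bpm then 4–13 bpm increments, matching the scale of the
  packaged sessions) with ±1 bpm integer device jitter.
* **Scenario presets**: `resting` (70 bpm, skin 33.8 °C, ~30 °C ambient —
  core ≈ 37 °C, solidly normal) and `heat_strain` (ramps to 175 bpm and
  39.5 °C skin after 10 min under a 33 °C day).  Three workers aged
  32/41/50, medium intensity, 60 min at 1 sample/min.

These emulate signal statistics, not physiology: there is no
thermoregulation model, no activity-dependent heart-rate dynamics, and no
accelerometer realism.  A green end-to-end test establishes that the
pipeline's plumbing, set construction and alerting logic behave as
specified on signals with known truth — not that the risk levels are
clinically validated.

## Known limitations

* The engine's low-side core-temperature handling (too-low → one severity
  step up) is a design choice for sensor-off/hypothermia anomalies, not a
  published mapping.
* Work intensity influences risk only through the Karvonen anchor; the
  default rules carry no explicit `W` clause (its fuzzy sets are built and
  exported for rule authors).
* The wet-bulb fit ignores pressure and radiant load; the index is a
  humidity-temperature proxy, not a four-component WBGT measurement.
* GPS and acceleration channels are passed through untouched.
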