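# heatwatch

Occupational heat-stress analytics for wearable monitoring of outdoor
workers.  The package implements both sides of an IoT monitoring platform,
fully offline:

* **OHS (overall heat assessment)** — group-level guidance from weather
  data: wet-bulb temperature via the Stull approximation, the thermal
  comfort index `TCI = −0.24418 + 0.553991·Tw + 0.455346·Ta − 0.00217·Tw²
  + 0.002782·Tw·Ta`, an additive environment/time-of-day correction, and
  five response stages (work stops above TCI 30).
* **PMS (personal management system)** — individual risk from wearable
  streams: PPG band-pass (0.5–4 Hz) and peak-picking heart rate, Hampel
  cleaning of skin temperature, core-temperature estimation
  `Tcore = Tskin + α·(Tskin − Tambient)`, and a Mamdani fuzzy engine over
  heart rate, core temperature, work intensity and abnormal-status
  duration, defuzzified by centre of gravity to a risk level in [0, 40]
  with alerting at the Attention level.  Heart-rate sets are personalised
  per worker via `HRmax = 207 − 0.7·age` and the Karvonen target
  `(HRmax − HRrest)·W + HRrest`.
* **Synthetic data** — seeded generators for pulsatile PPG with artifacts,
  drifting skin temperature with labelled spikes, diurnal weather and
  graded-exercise sessions, so every estimator is scored against known
  ground truth without any external data.

See `docs/methods.md` for the models, parameters and numerical choices.

## Worked example

```python
from heatwatch import run_pms, simulate_scenario

tables = simulate_scenario("heat_strain")   # 3 workers, hr -> 175 bpm after 10 min
result = run_pms(tables["roster"], tables["stream"], tables["weather"])
print(result["assessments"]["category"].value_counts().to_dict())
for a in result["alerts"]:
    print(a.timestamp, a.worker_id, a.category.value, round(a.rl, 1), a.reason)
```

prints

```
{'Danger': 147, 'Safe': 30, 'Attention': 3}
2020-07-15 08:10:00+09:00 W001 Attention 25.5 hr=108 bpm, core=39.2 C, abnormal for 0 min
2020-07-15 08:10:00+09:00 W002 Attention 25.5 hr=108 bpm, core=39.2 C, abnormal for 0 min
2020-07-15 08:10:00+09:00 W003 Attention 25.5 hr=106 bpm, core=39.1 C, abnormal for 0 min
```

Each worker starts Safe, crosses into Attention ten minutes in as heart
rate and estimated core temperature climb, and one alert per contiguous
episode is dispatched; sustained strain then escalates the risk level into
Danger (RL > 30).  The `examples/` directory holds one short script per
capability: daily site assessment (`ohs_daily_assessment.py`), heart rate
from raw PPG (`ppg_heart_rate.py`), the fuzzy engine probed across the
strain spectrum (`fuzzy_risk_profile.py`), the full monitoring run
(`pms_end_to_end.py`) and the indoor treadmill validation
(`validate_gxt.py`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole stack from scratch: the indoor graded-exercise-test
validation report (per-subject and overall mean absolute percentage error
between treadmill reference and device heart rates), and both scenario
presets end to end (simulation → heat assessment → personal monitoring →
alerting), printing the computed summaries and writing the results JSON to
`--out`.
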