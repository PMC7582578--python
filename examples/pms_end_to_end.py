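"""Full personal-monitoring run on a scripted heat-strain scenario.

Simulates a three-worker crew whose heart rate and skin temperature climb
after 10 minutes of hot work, ingests the device stream against the roster,
cleans the signals, estimates core temperature from the matched weather,
tracks abnormal-status duration, runs the fuzzy engine per sample and
reports the alert episodes.
"""

from heatwatch import run_pms, simulate_scenario

tables = simulate_scenario("heat_strain")
result = run_pms(tables["roster"], tables["stream"], tables["weather"])

df = result["assessments"]
print(f"{len(df)} assessments for {df['worker_id'].nunique()} workers")
print("\ncategory counts:", df["category"].value_counts().to_dict())

one = df[df["worker_id"] == "W001"]
print("\nworker W001, every 10th minute:")
print(one.iloc[::10][["timestamp", "hr", "core_temp", "T_min", "rl", "category"]]
      .to_string(index=False))

print(f"\n{len(result['alerts'])} alert episode(s):")
for a in result["alerts"]:
    print(f"  {a.timestamp} {a.worker_id} {a.category.value} RL={a.rl:.1f}  ({a.reason})")

# One alert per worker: each crosses into Attention/Danger once and stays
# there, so each contiguous abnormal episode produces exactly one dispatch.
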