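"""Group-level heat assessment: a hot day at a construction site, hour by hour.

Generates a diurnal weather trace, computes the wet-bulb temperature and the
thermal comfort index (with the construction-site time-of-day correction)
for every hour, and prints the staged schedule a site manager would see.
"""

from heatwatch import generate_weather_day, run_ohs

weather = generate_weather_day(ta_mean=31.0, ta_amp=5.0, rh_mean=65.0, seed=7)
assessments = run_ohs(weather, "construction_site")

print("hour  Ta(C)  Tw(C)   TCI  stage      action")
for w, a in zip(weather.itertuples(), assessments.itertuples()):
    print(
        f"{a.timestamp.hour:02d}   {w.ta_c:6.1f} {a.tw_c:6.1f} {a.tci:6.1f}  "
        f"{a.stage:<9} {a.action[:50]}"
    )

# TCI is the weighted heat-stress index: above 30 all work stops (Severe);
# 28-30 Warning, 25-28 Caution, 21-25 Concern, below 21 no action needed.
worst = assessments.loc[assessments["tci"].idxmax()]
print(
    f"\npeak TCI {worst.tci:.1f} at {worst.timestamp.hour:02d}:00 -> {worst.stage}: "
    f"{worst.action or '(no action required)'}"
)
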