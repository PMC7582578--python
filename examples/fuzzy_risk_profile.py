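"""The personalised fuzzy risk engine, probed across the strain spectrum.

Builds the Mamdani system for a 45-year-old at medium work intensity
(HRmax = 207 - 0.7*45 = 175.5 bpm; Karvonen caution threshold
(175.5-60)*0.5 + 60 = 117.75 bpm) and shows the crisp risk level [0, 40]
and category for increasingly strained observations.
"""

from heatwatch import RiskInput, WorkerProfile, build_fuzzy_system, hr_max, mamdani_infer

profile = WorkerProfile(age=45, resting_hr=60, work_intensity="medium")
system = build_fuzzy_system(profile)
print(f"worker: age {profile.age}, HRmax {hr_max(profile.age):.1f} bpm, "
      f"work intensity {profile.intensity_value}")

cases = [
    ("resting, cool", RiskInput(h=70, ct=36.8, w=0.5, t=0)),
    ("brisk work, warm", RiskInput(h=125, ct=37.6, w=0.5, t=5)),
    ("sustained strain", RiskInput(h=150, ct=38.5, w=0.5, t=20)),
    ("near collapse", RiskInput(h=180, ct=40.5, w=0.5, t=40)),
]
print(f"\n{'case':<18} {'H':>5} {'CT':>5} {'T':>4}   {'RL':>5}  category   alert")
for name, x in cases:
    a = mamdani_infer(system, x)
    print(f"{name:<18} {x.h:5.0f} {x.ct:5.1f} {x.t:4.0f}   {a.rl:5.2f}  "
          f"{a.category.value:<9}  {a.alert}")

# RL 0-10 Safe, 10-20 Concern, 20-30 Attention, 30-40 Danger; an alert is
# dispatched to the site manager from Attention upward.
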