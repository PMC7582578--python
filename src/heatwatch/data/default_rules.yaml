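# Default risk rule base for the Mamdani engine.
#
# Schema (one mapping per rule):
#   if:   {variable: set} or {variable: [set, set]}  -- a list is an OR over
#         that variable's sets; clauses across variables are combined with
#         `op` (and = min, or = max).
#   not:  optional list of variables whose clause is negated (1 - membership).
#   then: consequent set of the output variable `risk_level`.
#
# Design: consequent severity is the worse of the heart-rate status and the
# core-temperature status, escalated one level while the abnormal episode has
# persisted into the attention/danger time bands.  Unconditional overrides:
# heart rate at or above HRmax, or core temperature above the heat-stroke
# threshold (40 C), are danger regardless of duration.
rules:
  # heart rate normal
  - {if: {heart_rate: normal, core_temp: too_low, time_interval: prolonged}, not: [time_interval], then: concern}
  - {if: {heart_rate: normal, core_temp: too_low, time_interval: prolonged}, then: attention}
  - {if: {heart_rate: normal, core_temp: low, time_interval: prolonged}, not: [time_interval], then: safe}
  - {if: {heart_rate: normal, core_temp: low, time_interval: prolonged}, then: concern}
  - {if: {heart_rate: normal, core_temp: normal, time_interval: prolonged}, not: [time_interval], then: safe}
  - {if: {heart_rate: normal, core_temp: normal, time_interval: prolonged}, then: concern}
  - {if: {heart_rate: normal, core_temp: high, time_interval: prolonged}, not: [time_interval], then: attention}
  - {if: {heart_rate: normal, core_temp: high, time_interval: prolonged}, then: danger}
  # heart rate in the Karvonen caution band
  - {if: {heart_rate: caution, core_temp: too_low, time_interval: prolonged}, not: [time_interval], then: concern}
  - {if: {heart_rate: caution, core_temp: too_low, time_interval: prolonged}, then: attention}
  - {if: {heart_rate: caution, core_temp: low, time_interval: prolonged}, not: [time_interval], then: concern}
  - {if: {heart_rate: caution, core_temp: low, time_interval: prolonged}, then: attention}
  - {if: {heart_rate: caution, core_temp: normal, time_interval: prolonged}, not: [time_interval], then: concern}
  - {if: {heart_rate: caution, core_temp: normal, time_interval: prolonged}, then: attention}
  - {if: {heart_rate: caution, core_temp: high, time_interval: prolonged}, not: [time_interval], then: attention}
  - {if: {heart_rate: caution, core_temp: high, time_interval: prolonged}, then: danger}
  # unconditional overrides
  - {if: {heart_rate: danger}, then: danger}
  - {if: {core_temp: too_high}, then: danger}
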