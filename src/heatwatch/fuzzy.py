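"""Mamdani fuzzy risk-level engine for individual heat-strain assessment.

Four inputs — heart rate ``H`` (bpm), estimated core temperature ``CT``
(degC), work intensity ``W`` (a dimensionless class value) and the time
``T`` (minutes) for which an abnormal physiological status has persisted —
are fuzzified with pi-shaped membership functions, combined through a rule
base using AND (min), OR (max) and NOT (complement) semantics, clipped into
triangular output sets on the risk-level universe [0, 40] (Mamdani
min-implication, max-aggregation) and reduced to a crisp risk level by the
centre-of-gravity of the aggregated set.

The heart-rate sets are personalised per worker:

* age-predicted maximum heart rate ``HRmax = 207 - 0.7 * age``;
* the caution band starts at the Karvonen target
  ``(HRmax - HRrest) * W + HRrest``, i.e. the fraction ``W`` of the
  heart-rate reserve above rest.

Work-intensity class values follow the published inverse convention:
light = 0.75, medium = 0.5, high = 0.25.  The crisp risk level maps to four
categories — Safe, Concern, Attention, Danger — and an alert is raised at
Attention or above.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._resources import packaged_data_path

__all__ = [
    "PiMembership",
    "TriMembership",
    "FuzzyVariable",
    "WorkerProfile",
    "RiskInput",
    "Rule",
    "FuzzySystem",
    "RiskCategory",
    "RiskAssessment",
    "WORK_INTENSITY",
    "hr_max",
    "caution_threshold",
    "build_fuzzy_system",
    "evaluate_memberships",
    "mamdani_infer",
    "categorize_risk",
    "load_rules",
    "default_rules",
]

#: work-intensity class values (published inverse scale)
WORK_INTENSITY = {"light": 0.75, "medium": 0.5, "high": 0.25}

#: grid step for centroid defuzzification over the risk-level universe
DEFUZZ_RESOLUTION = 0.01


def _smooth_up(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """S-shaped ramp: 0 at/below a, 1 at/above b, quadratic smoothstep between."""
    if b <= a:
        return (x >= a).astype(float)
    t = np.clip((x - a) / (b - a), 0.0, 1.0)
    return np.where(t <= 0.5, 2 * t**2, 1 - 2 * (1 - t) ** 2)


@dataclass(frozen=True)
class PiMembership:
    """Pi-shaped membership: smooth rise [a, b], plateau [b, c], smooth fall [c, d].

    Crossover value 0.5 at the ramp midpoints (a+b)/2 and (c+d)/2.  A shoulder
    (one-sided set) is expressed by collapsing a ramp: ``a == b`` makes the
    left flank a step at the plateau edge, likewise ``c == d`` on the right.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"require a <= b <= c <= d, got {self}")

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        up = _smooth_up(x, self.a, self.b) if self.a < self.b else (x >= self.b).astype(float)
        down = 1 - _smooth_up(x, self.c, self.d) if self.c < self.d else (x <= self.c).astype(float)
        out = np.minimum(up, down)
        # collapsed shoulders: plateau membership is 1 on [b, c]
        out = np.where((x >= self.b) & (x <= self.c), 1.0, out)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TriMembership:
    """Triangular membership with left foot ``a``, apex ``b``, right foot ``c``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c and self.a < self.c):
            raise ValueError(f"require a <= b <= c with a < c, got {self}")

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        left = (x - self.a) / (self.b - self.a) if self.b > self.a else (x >= self.b).astype(float)
        right = (self.c - x) / (self.c - self.b) if self.c > self.b else (x <= self.b).astype(float)
        out = np.clip(np.minimum(left, right), 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FuzzyVariable:
    """A named variable: universe of discourse and its fuzzy sets."""

    name: str
    universe: tuple[float, float]
    sets: Mapping[str, PiMembership | TriMembership]

    def clamp(self, x: float) -> float:
        return min(max(x, self.universe[0]), self.universe[1])

    def membership(self, x: float) -> dict[str, float]:
        xc = self.clamp(x)
        return {name: float(mf(xc)) for name, mf in self.sets.items()}

    def dominant(self, x: float) -> str:
        mu = self.membership(x)
        return max(mu, key=mu.get)  # dict order breaks ties (least severe first)


@dataclass(frozen=True)
class WorkerProfile:
    """Per-worker parameters that personalise the heart-rate sets."""

    age: float
    resting_hr: float = 60.0
    work_intensity: str | float = "medium"

    def __post_init__(self) -> None:
        if not (15 <= self.age <= 80):
            raise ValueError(f"age must be in [15, 80], got {self.age!r}")
        w = self.intensity_value  # validates
        if not (0 < w <= 1):
            raise ValueError(f"work intensity value must be in (0, 1], got {w!r}")

    @property
    def intensity_value(self) -> float:
        if isinstance(self.work_intensity, str):
            try:
                return WORK_INTENSITY[self.work_intensity.lower()]
            except KeyError:
                raise ValueError(
                    f"unknown work intensity {self.work_intensity!r}; "
                    f"expected one of {sorted(WORK_INTENSITY)} or a value in (0, 1]"
                ) from None
        return float(self.work_intensity)


@dataclass(frozen=True)
class RiskInput:
    """One crisp observation fed to the engine."""

    h: float  # heart rate, bpm
    ct: float  # core temperature, degC
    w: float  # work-intensity value
    t: float  # abnormal-status duration, minutes

    def __post_init__(self) -> None:
        for name in ("h", "ct", "w", "t"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.t < 0:
            raise ValueError(f"duration t must be >= 0, got {self.t!r}")


@dataclass(frozen=True)
class Rule:
    """One fuzzy rule: AND/OR over per-variable clauses, optional NOT, one consequent.

    ``clauses`` maps variable name -> tuple of set names; several sets on one
    variable are OR-ed.  Variables listed in ``negate`` have their clause
    complemented (1 - membership).  ``op`` combines clause values across
    variables ("and" = min, "or" = max).
    """

    clauses: Mapping[str, tuple[str, ...]]
    consequent: str
    op: str = "and"
    negate: tuple[str, ...] = ()

    def strength(self, memberships: Mapping[str, Mapping[str, float]]) -> float:
        vals = []
        for var, sets in self.clauses.items():
            mu = max(memberships[var][s] for s in sets)
            if var in self.negate:
                mu = 1.0 - mu
            vals.append(mu)
        return min(vals) if self.op == "and" else max(vals)


class RiskCategory(str, enum.Enum):
    SAFE = "Safe"
    CONCERN = "Concern"
    ATTENTION = "Attention"
    DANGER = "Danger"


@dataclass(frozen=True)
class RiskAssessment:
    """Crisp engine output with provenance for audit."""

    rl: float
    category: RiskCategory
    alert: bool
    fired_rules: tuple[tuple[Rule, float], ...] = ()
    memberships: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class FuzzySystem:
    """Input variables, the risk-level output variable, and the rule base."""

    inputs: Mapping[str, FuzzyVariable]
    output: FuzzyVariable
    rules: tuple[Rule, ...]
    profile: WorkerProfile | None = None

    def __post_init__(self) -> None:
        for rule in self.rules:
            for var, sets in rule.clauses.items():
                if var not in self.inputs:
                    raise ValueError(f"rule references unknown variable {var!r}")
                for s in sets:
                    if s not in self.inputs[var].sets:
                        raise ValueError(f"rule references unknown set {var}.{s!r}")
            if rule.consequent not in self.output.sets:
                raise ValueError(f"rule consequent {rule.consequent!r} not an output set")


def hr_max(age: float) -> float:
    """Age-predicted maximum heart rate, ``207 - 0.7 * age`` bpm."""
    if not (15 <= age <= 80):
        raise ValueError(f"age must be in [15, 80], got {age!r}")
    return 207.0 - 0.7 * age


def caution_threshold(hrmax: float, normal_hb: float, w: float) -> float:
    """Karvonen target heart rate: ``(HRmax - HRrest) * W + HRrest``.

    The fraction ``w`` of the heart-rate reserve above the resting rate
    ``normal_hb``; the start of the personalised caution band.
    """
    if normal_hb >= hrmax:
        raise ValueError(f"resting rate {normal_hb} must be below HRmax {hrmax}")
    if not (0 < w <= 1):
        raise ValueError(f"work intensity must be in (0, 1], got {w!r}")
    return (hrmax - normal_hb) * w + normal_hb


# plateau edges of the published core-temperature and duration bands
_CT_BREAKS = dict(too_low_hi=32.0, low=(33.0, 35.0), normal=(36.0, 38.0),
                  high=(38.0, 40.0), too_high_lo=40.0)
_CT_RAMP_HALF = 0.5  # degC, ramp half-width where adjacent bands share a breakpoint
_T_RAMP_HALF = 0.5  # minutes, likewise (the 5-minute breakpoint is shared)

H_UNIVERSE = (30.0, 230.0)
CT_UNIVERSE = (28.0, 44.0)
W_UNIVERSE = (0.0, 1.0)
T_UNIVERSE = (0.0, 60.0)
RL_UNIVERSE = (0.0, 40.0)

#: upper edge of the normal heart-rate band, bpm
H_NORMAL_HI = 99.0
#: lower edge of the normal heart-rate band, bpm (informational; the normal
#: set is left-shouldered so that sub-resting rates stay covered)
H_NORMAL_LO = 60.0


def _heart_rate_variable(profile: WorkerProfile) -> FuzzyVariable:
    hrmax = hr_max(profile.age)
    hc = caution_threshold(hrmax, profile.resting_hr, profile.intensity_value)
    # keep the anchors strictly ordered: 99 < caution target < HRmax
    hc = min(max(hc, H_NORMAL_HI + 1.0), hrmax - 1.0)
    lo, hi = H_UNIVERSE
    return FuzzyVariable(
        "heart_rate",
        H_UNIVERSE,
        {
            "normal": PiMembership(lo, lo, H_NORMAL_HI, hc),
            "caution": PiMembership(H_NORMAL_HI, hc, hc, hrmax),
            "danger": PiMembership(hc, hrmax, hi, hi),
        },
    )


def _core_temp_variable() -> FuzzyVariable:
    lo, hi = CT_UNIVERSE
    h = _CT_RAMP_HALF
    return FuzzyVariable(
        "core_temp",
        CT_UNIVERSE,
        {
            "too_low": PiMembership(lo, lo, 32.0, 33.0),
            "low": PiMembership(32.0, 33.0, 35.0, 36.0),
            "normal": PiMembership(35.0, 36.0, 38.0 - h, 38.0 + h),
            "high": PiMembership(38.0 - h, 38.0 + h, 40.0 - h, 40.0 + h),
            "too_high": PiMembership(40.0 - h, 40.0 + h, hi, hi),
        },
    )


def _work_intensity_variable() -> FuzzyVariable:
    lo, hi = W_UNIVERSE
    return FuzzyVariable(
        "work_intensity",
        W_UNIVERSE,
        {
            "high": PiMembership(lo, lo, 0.25, 0.5),
            "medium": TriMembership(0.25, 0.5, 0.75),
            "light": PiMembership(0.5, 0.75, hi, hi),
        },
    )


def _time_interval_variable() -> FuzzyVariable:
    lo, hi = T_UNIVERSE
    h = _T_RAMP_HALF
    return FuzzyVariable(
        "time_interval",
        T_UNIVERSE,
        {
            "safe": PiMembership(lo, lo, 5.0 - h, 5.0 + h),
            "concern": PiMembership(5.0 - h, 5.0 + h, 14.0, 15.0),
            "attention": PiMembership(14.0, 15.0, 29.0, 30.0),
            "danger": PiMembership(29.0, 30.0, hi, hi),
            # cumulative "has persisted into the attention band or beyond";
            # used by escalation rules so their strength is monotone in T
            # (the union attention|danger dips to 0.5 at the 29-30 crossover)
            "prolonged": PiMembership(14.0, 15.0, hi, hi),
        },
    )


def _risk_level_variable() -> FuzzyVariable:
    return FuzzyVariable(
        "risk_level",
        RL_UNIVERSE,
        {
            "safe": TriMembership(0.0, 5.0, 10.5),
            "concern": TriMembership(10.5, 15.5, 20.5),
            "attention": TriMembership(20.5, 25.5, 30.5),
            "danger": TriMembership(30.5, 35.5, 40.0),
        },
    )


def load_rules(path) -> tuple[Rule, ...]:
    """Load a rule base from a YAML rules file (see the packaged default for schema)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules = []
    for entry in doc["rules"]:
        clauses = {
            var: tuple([sets] if isinstance(sets, str) else sets)
            for var, sets in entry["if"].items()
        }
        rules.append(
            Rule(
                clauses=clauses,
                consequent=entry["then"],
                op=entry.get("op", "and"),
                negate=tuple(entry.get("not", ())),
            )
        )
    return tuple(rules)


def default_rules() -> tuple[Rule, ...]:
    """The packaged default rule base."""
    return load_rules(packaged_data_path("default_rules.yaml"))


def build_fuzzy_system(
    profile: WorkerProfile, rules: Sequence[Rule] | None = None
) -> FuzzySystem:
    """Construct the personalised engine for one worker.

    Heart-rate sets are anchored at 60/99 bpm, the worker's Karvonen caution
    target and age-predicted HRmax; core-temperature, work-intensity and
    duration sets use the published fixed breakpoints.
    """
    return FuzzySystem(
        inputs={
            "heart_rate": _heart_rate_variable(profile),
            "core_temp": _core_temp_variable(),
            "work_intensity": _work_intensity_variable(),
            "time_interval": _time_interval_variable(),
        },
        output=_risk_level_variable(),
        rules=tuple(rules) if rules is not None else default_rules(),
        profile=profile,
    )


def evaluate_memberships(
    system: FuzzySystem, x: RiskInput
) -> dict[str, dict[str, float]]:
    """Membership degree of every input set at ``x`` (inputs clamped to universes)."""
    crisp = {"heart_rate": x.h, "core_temp": x.ct, "work_intensity": x.w, "time_interval": x.t}
    return {name: var.membership(crisp[name]) for name, var in system.inputs.items()}


def categorize_risk(rl: float) -> RiskCategory:
    """Crisp risk level -> category: Safe [0,10], Concern (10,20], Attention (20,30], Danger (30,40]."""
    if not (0.0 <= rl <= 40.0):
        raise ValueError(f"risk level must be in [0, 40], got {rl!r}")
    if rl <= 10:
        return RiskCategory.SAFE
    if rl <= 20:
        return RiskCategory.CONCERN
    if rl <= 30:
        return RiskCategory.ATTENTION
    return RiskCategory.DANGER


def mamdani_infer(
    system: FuzzySystem, x: RiskInput, resolution: float = DEFUZZ_RESOLUTION
) -> RiskAssessment:
    """Evaluate the rule base at ``x`` and defuzzify by centre of gravity.

    Rule strengths use min/max/complement connective semantics; each rule
    min-clips its consequent set; clipped sets are aggregated by pointwise
    maximum over the risk-level universe and the centroid of the aggregate
    is the crisp risk level.
    """
    memberships = evaluate_memberships(system, x)
    strengths = [(rule, rule.strength(memberships)) for rule in system.rules]
    fired = tuple((r, s) for r, s in strengths if s > 0)
    if not fired:
        raise RuntimeError("no rule fired: rule base does not cover the input space")
    lo, hi = system.output.universe
    grid = np.arange(lo, hi + resolution / 2, resolution)
    agg = np.zeros_like(grid)
    for rule, s in fired:
        np.maximum(agg, np.minimum(s, system.output.sets[rule.consequent](grid)), out=agg)
    rl = float(np.sum(grid * agg) / np.sum(agg))
    category = categorize_risk(rl)
    return RiskAssessment(
        rl=rl,
        category=category,
        alert=category in (RiskCategory.ATTENTION, RiskCategory.DANGER),
        fired_rules=fired,
        memberships=memberships,
    )
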