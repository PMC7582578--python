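"""Thermal comfort index (TCI) assessment for outdoor work sites.

The TCI is a wet-bulb-globe-temperature-derived heat-stress index used to
schedule rest for groups of outdoor workers.  It is computed from routine
weather observations (dry-bulb temperature and relative humidity) in three
steps:

1. the wet-bulb temperature ``Tw`` is approximated from ``Ta`` and ``RH``
   with the Stull (2011) single-equation psychrometric fit;
2. the raw index is the bilinear polynomial
   ``TCI = -0.24418 + 0.553991*Tw + 0.455346*Ta - 0.00217*Tw**2
   + 0.002782*Tw*Ta``;
3. an additive correction that depends on the work environment (construction
   site, road, greenhouse, ...) and the time of day is applied, and the
   weighted index is classified into five response stages, each with a
   recommended action for the site manager.

Stage boundaries use half-open intervals closed on the upper end; the
work-stoppage ("Severe") stage is entered strictly above a TCI of 30.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from datetime import datetime
from functools import lru_cache

import pandas as pd

from ._resources import packaged_data_path

__all__ = [
    "WeatherSample",
    "SiteEnvironment",
    "Stage",
    "TCIAssessment",
    "wet_bulb_temperature",
    "tci_raw",
    "time_of_day_weight",
    "classify_stage",
    "ohs_assess",
    "STAGE_ACTIONS",
]


class SiteEnvironment(str, enum.Enum):
    """Work environments with distinct time-of-day TCI corrections."""

    CHILDREN = "children"
    HEAT_VULNERABLE_AREA = "heat_vulnerable_area"
    FARMING_AREA = "farming_area"
    GREENHOUSE = "greenhouse"
    ROAD = "road"
    CONSTRUCTION_SITE = "construction_site"
    SHIPYARD = "shipyard"


class Stage(str, enum.Enum):
    """Heat-stress response stages, most severe first."""

    SEVERE = "Severe"
    WARNING = "Warning"
    CAUTION = "Caution"
    CONCERN = "Concern"
    ATTENTION = "Attention"


#: Recommended actions per stage for outdoor work environments
#: (road, construction site, shipyard).  The lowest stage carries no action.
STAGE_ACTIONS: dict[Stage, str] = {
    Stage.SEVERE: (
        "All workers should stop working immediately and rest in a cool "
        "environment until further notice"
    ),
    Stage.WARNING: "All workers should preferably stop working as soon as it is possible",
    Stage.CAUTION: "Need to reduce work time or workload and take breaks frequently",
    Stage.CONCERN: "Attention should be given to those who are vulnerable to heat dissipation",
    Stage.ATTENTION: "",
}


@dataclass(frozen=True)
class WeatherSample:
    """One weather observation: dry-bulb temperature (degC) and RH (%)."""

    timestamp: datetime
    ta: float
    rh: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rh <= 100.0):
            raise ValueError(f"relative humidity must be in [0, 100] %, got {self.rh!r}")
        if not (-40.0 <= self.ta <= 60.0):
            raise ValueError(f"air temperature {self.ta!r} degC outside plausible [-40, 60]")


@dataclass(frozen=True)
class TCIAssessment:
    """Full record of one TCI evaluation, intermediate values included."""

    timestamp: datetime
    tw: float
    tci_raw: float
    weight: float
    tci: float
    stage: Stage
    action: str


def wet_bulb_temperature(ta: float, rh: float) -> float:
    """Wet-bulb temperature (degC) via the Stull (2011) approximation.

    Parameters
    ----------
    ta : dry-bulb air temperature, degC.
    rh : relative humidity, percent in [0, 100].

    The fit is stated for roughly ``ta`` in [-20, 50] degC; a warning is
    emitted outside that region.
    """
    if not math.isfinite(ta) or not math.isfinite(rh):
        raise ValueError("ta and rh must be finite")
    if not (0.0 <= rh <= 100.0):
        raise ValueError(f"relative humidity must be in [0, 100] %, got {rh!r}")
    if not (-20.0 <= ta <= 50.0):
        warnings.warn(
            f"ta={ta} degC is outside the stated validity region [-20, 50] of the "
            "wet-bulb approximation",
            stacklevel=2,
        )
    return (
        ta * math.atan(0.151977 * math.sqrt(rh + 8.313659))
        + math.atan(ta + rh)
        - math.atan(rh - 1.676331)
        + 0.00391838 * rh**1.5 * math.atan(0.023101 * rh)
        - 4.686035
    )


def tci_raw(tw: float, ta: float) -> float:
    """Unweighted thermal comfort index from wet-bulb and dry-bulb temperature."""
    if not math.isfinite(tw) or not math.isfinite(ta):
        raise ValueError("tw and ta must be finite")
    return -0.24418 + 0.553991 * tw + 0.455346 * ta - 0.00217 * tw**2 + 0.002782 * tw * ta


@lru_cache(maxsize=1)
def _weight_table() -> pd.DataFrame:
    df = pd.read_csv(packaged_data_path("tci_weights.csv"))
    return df.set_index("hour")


def time_of_day_weight(hour: float, env: SiteEnvironment | str) -> float:
    """Additive TCI correction for ``env`` at the 3-hour slot nearest ``hour``.

    The correction table is published on 3-hour slots (03, 06, ..., 24);
    intermediate hours map to the nearest slot, ties rounding up.  Hour 0
    maps to the 24 h slot.  Corrections may be negative.
    """
    env = SiteEnvironment(env)
    if not (0 <= hour <= 23):
        raise ValueError(f"hour must be in [0, 23], got {hour!r}")
    slot = 3 * math.floor(hour / 3 + 0.5)  # nearest slot, ties up
    if slot == 0:
        slot = 24
    return float(_weight_table().loc[slot, env.value])


def classify_stage(tci: float) -> tuple[Stage, str]:
    """Map a (weighted) TCI value to its response stage and recommended action.

    Partition of the real line (upper-closed):
    Severe (30, inf), Warning (28, 30], Caution (25, 28], Concern (21, 25],
    Attention (-inf, 21].
    """
    if not math.isfinite(tci):
        raise ValueError("tci must be finite")
    if tci > 30:
        stage = Stage.SEVERE
    elif tci > 28:
        stage = Stage.WARNING
    elif tci > 25:
        stage = Stage.CAUTION
    elif tci > 21:
        stage = Stage.CONCERN
    else:
        stage = Stage.ATTENTION
    return stage, STAGE_ACTIONS[stage]


def ohs_assess(sample: WeatherSample, env: SiteEnvironment | str) -> TCIAssessment:
    """Assess one weather sample: wet-bulb -> raw TCI -> weighted TCI -> stage."""
    tw = wet_bulb_temperature(sample.ta, sample.rh)
    raw = tci_raw(tw, sample.ta)
    weight = time_of_day_weight(sample.timestamp.hour, env)
    tci = raw + weight
    stage, action = classify_stage(tci)
    return TCIAssessment(
        timestamp=sample.timestamp,
        tw=tw,
        tci_raw=raw,
        weight=weight,
        tci=tci,
        stage=stage,
        action=action,
    )
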