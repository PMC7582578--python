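import numpy as np
import pandas as pd
import pytest

from heatwatch import ScenarioConfig, WorkerProfile, build_fuzzy_system, generate_scenario


@pytest.fixture(scope="session")
def profile():
    return WorkerProfile(age=30, resting_hr=60, work_intensity="medium")


@pytest.fixture(scope="session")
def system(profile):
    return build_fuzzy_system(profile)


@pytest.fixture(scope="session")
def resting_tables():
    from heatwatch.synthetic import PRESETS

    return generate_scenario(PRESETS["resting"])


@pytest.fixture(scope="session")
def heat_strain_tables():
    from heatwatch.synthetic import PRESETS

    return generate_scenario(PRESETS["heat_strain"])


@pytest.fixture
def small_weather():
    ts = pd.date_range("2020-07-15T08:00:00+09:00", periods=4, freq="h")
    return pd.DataFrame({"timestamp": ts, "ta_c": [29.0, 30.0, 31.0, 31.5], "rh_pct": 60.0})
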