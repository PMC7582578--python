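"""Readers and writers for the platform's file dialects, plus run configuration.

All machine-readable artifacts are plain text: CSV for tabular data
(weather, roster, device stream, assessments), JSON-lines for alerts and
streams, JSON for error reports and run manifests, YAML for scenario and
rule configuration.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._resources import packaged_data_path
from .monitoring import Alert, ErrorReport
from .synthetic import ScenarioConfig

__all__ = [
    "RunConfig",
    "read_weather_csv",
    "write_weather_csv",
    "read_roster_csv",
    "write_roster_csv",
    "read_stream",
    "write_stream",
    "write_assessments_csv",
    "read_assessments_csv",
    "write_alerts_jsonl",
    "read_alerts_jsonl",
    "write_error_report_json",
    "read_error_report_json",
    "load_scenario_yaml",
    "save_scenario_yaml",
    "load_table8",
    "write_manifest",
]

@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    environment: str = "construction_site"
    rules_file: str | None = None
    hampel_half_window: int = 5
    hampel_k: float = 3.0
    ppg_window_s: float = 10.0
    ppg_amplitude_bounds: tuple[float, float] = (-2.5, 2.5)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "ta_c", "rh_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV {path} missing columns {sorted(missing)}")
    return df


def write_weather_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S%z")


def read_roster_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_roster_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_stream(path) -> pd.DataFrame:
    """Device stream from CSV or JSON-lines (chosen by file extension)."""
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        df = pd.read_json(path, lines=True, convert_dates=["timestamp"])
    else:
        df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_stream(df: pd.DataFrame, path) -> None:
    path = Path(path)
    out = df.copy()
    if path.suffix in (".jsonl", ".ndjson"):
        out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
        out.to_json(path, orient="records", lines=True)
    else:
        out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S%z")


def write_assessments_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S%z")


def read_assessments_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


def write_alerts_jsonl(alerts: list[Alert], path) -> None:
    with open(path, "w") as fh:
        for a in alerts:
            fh.write(
                json.dumps(
                    {
                        "worker_id": a.worker_id,
                        "timestamp": a.timestamp.isoformat(),
                        "category": a.category.value,
                        "rl": round(a.rl, 4),
                        "reason": a.reason,
                    }
                )
                + "\n"
            )


def read_alerts_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_error_report_json(report: ErrorReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def read_error_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_scenario_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    for key in ("hr_profile", "skin_profile", "roster_ages"):
        if key in raw:
            raw[key] = tuple(tuple(p) if isinstance(p, list) else p for p in raw[key])
    return ScenarioConfig(**raw)


def save_scenario_yaml(config: ScenarioConfig, path) -> None:
    raw = dataclasses.asdict(config)
    for key in ("hr_profile", "skin_profile", "roster_ages"):
        value = raw[key]
        raw[key] = [list(p) if isinstance(p, tuple) else p for p in value]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def load_table8(path=None) -> pd.DataFrame:
    """The packaged indoor GXT validation table (long format)."""
    return pd.read_csv(path if path is not None else packaged_data_path("gxt_indoor_results.csv"))


def write_manifest(out_dir, *, seed: int, config: dict, inputs: dict | None = None) -> Path:
    """Record everything needed to reproduce a run byte-identically."""
    from . import __version__

    manifest = {
        "package": "heatwatch",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config,
        "inputs": inputs or {},
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
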