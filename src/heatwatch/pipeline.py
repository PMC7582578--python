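"""High-level entry points: one function per platform workflow.

These compose the modules end to end and are what the example scripts call:

* :func:`run_ohs` — weather table -> per-hour TCI assessments;
* :func:`simulate_scenario` — scenario config -> weather/roster/stream files;
* :func:`run_pms` — roster + stream + weather -> per-worker risk
  assessments and alert episodes;
* :func:`validate_table8` — indoor treadmill validation error report.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as hio
from .fuzzy import Rule, load_rules
from .monitoring import Alert, ErrorReport, evaluate_worker, gxt_error_report, ingest_stream, WorkerRecord
from .synthetic import PRESETS, ScenarioConfig, generate_scenario
from .tci import SiteEnvironment, WeatherSample, ohs_assess

__all__ = ["run_ohs", "run_pms", "simulate_scenario", "validate_table8"]


def run_ohs(
    weather: pd.DataFrame, env: SiteEnvironment | str, out: str | Path | None = None
) -> pd.DataFrame:
    """Assess every weather sample; columns ``timestamp,tw_c,tci_raw,weight,tci,stage,action``."""
    rows = []
    for rec in weather.itertuples(index=False):
        sample = WeatherSample(timestamp=rec.timestamp, ta=rec.ta_c, rh=rec.rh_pct)
        a = ohs_assess(sample, env)
        rows.append(
            {
                "timestamp": a.timestamp,
                "tw_c": a.tw,
                "tci_raw": a.tci_raw,
                "weight": a.weight,
                "tci": a.tci,
                "stage": a.stage.value,
                "action": a.action,
            }
        )
    result = pd.DataFrame(rows)
    if out is not None:
        hio.write_assessments_csv(result, out)
    return result


def simulate_scenario(
    config: ScenarioConfig | str = "resting", out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Generate a scenario (by preset name or config) and optionally write its files."""
    if isinstance(config, str):
        config = PRESETS[config]
    tables = generate_scenario(config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        hio.write_weather_csv(tables["weather"], out_dir / "weather.csv")
        hio.write_roster_csv(tables["roster"], out_dir / "roster.csv")
        hio.write_stream(tables["stream"], out_dir / "stream.csv")
        hio.write_manifest(
            out_dir,
            seed=config.seed,
            config={"scenario": config.__dict__},
            inputs={},
        )
    return tables


def run_pms(
    roster: pd.DataFrame,
    stream: pd.DataFrame,
    weather: pd.DataFrame,
    rules: list[Rule] | str | Path | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    hampel_half_window: int = 5,
    hampel_k: float = 3.0,
) -> dict:
    """Run the personal monitoring pipeline for every rostered worker.

    Returns ``{"assessments": DataFrame, "alerts": [Alert], "rejects":
    DataFrame, "n_malformed": int}`` and, when ``out_dir`` is given, writes
    ``assessments.csv``, ``alerts.jsonl`` and ``manifest.json``.
    """
    if isinstance(rules, (str, Path)):
        rules = list(load_rules(rules))
    per_worker, rejects, n_malformed = ingest_stream(stream, roster)
    assessments: list[pd.DataFrame] = []
    alerts: list[Alert] = []
    for row in roster.itertuples(index=False):
        wid = row.worker_id
        if wid not in per_worker:
            continue
        worker = WorkerRecord(**{k: getattr(row, k) for k in WorkerRecord.__dataclass_fields__
                                 if hasattr(row, k)})
        df, worker_alerts = evaluate_worker(
            per_worker[wid],
            worker,
            weather,
            rules=rules,
            hampel_half_window=hampel_half_window,
            hampel_k=hampel_k,
        )
        assessments.append(df)
        alerts.extend(worker_alerts)
    result = {
        "assessments": pd.concat(assessments, ignore_index=True)
        if assessments
        else pd.DataFrame(),
        "alerts": alerts,
        "rejects": rejects,
        "n_malformed": n_malformed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        hio.write_assessments_csv(result["assessments"], out_dir / "assessments.csv")
        hio.write_alerts_jsonl(alerts, out_dir / "alerts.jsonl")
        hio.write_manifest(
            out_dir,
            seed=seed,
            config={"hampel_half_window": hampel_half_window, "hampel_k": hampel_k},
            inputs={"n_workers": len(roster), "n_samples": len(stream)},
        )
    return result


def validate_table8(path: str | Path | None = None, out: str | Path | None = None) -> ErrorReport:
    """Reference-vs-device error report on the indoor GXT table (packaged by default)."""
    table = hio.load_table8(path)
    pairs = {
        str(subject): (g["reference_bpm"].to_numpy(), g["device_bpm"].to_numpy())
        for subject, g in table.groupby("subject", sort=True)
    }
    report = gxt_error_report(pairs)
    if out is not None:
        hio.write_error_report_json(report, out)
    return report
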