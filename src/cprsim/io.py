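"""Configuration loading, tidy CSV writers and the run manifest.

Configs are YAML or JSON mappings; every key has a default, so an empty file
plus a scenario id is a valid configuration.  Outputs are long-format CSVs
(one row per run x tick x agent for trajectories) with floats printed at 9
significant digits so re-runs diff cleanly across platforms, plus a
``manifest.json`` recording the package version, a reproducible hash of the
effective configuration, the base seed and the written files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .agents import BehaviorParams
from .analysis import classify_run
from .resource import RegenerationTable, build_default_table, load_table_csv
from .simulation import RunResult, ScenarioConfig, scenario

__all__ = [
    "ConfigError",
    "load_config",
    "config_hash",
    "trajectories_frame",
    "summary_frame",
    "classification_frame",
    "write_outputs",
    "write_manifest",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.9g"

_PARAM_FIELDS = {f.name for f in dataclasses.fields(BehaviorParams)}
_RUN_KEYS = {
    "scenario",
    "robustness",
    "replications",
    "base_seed",
    "n_ticks",
    "uninformed_range",
    "trust_range",
    "params",
    "table_csv",
}


class ConfigError(ValueError):
    """Invalid configuration; ``problems`` lists every violated field."""

    def __init__(self, problems: list[str]):
        super().__init__("; ".join(problems))
        self.problems = problems


def _parse_mapping(path: str | Path) -> dict:
    text = Path(path).read_text()
    if not text.strip():
        return {}
    data = yaml.safe_load(text)  # YAML is a JSON superset, so .json loads too
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigError([f"{path}: expected a mapping at top level"])
    return dict(data)


def load_config(
    path: str | Path | None = None, **overrides: Any
) -> tuple[ScenarioConfig, BehaviorParams, RegenerationTable, list[str]]:
    """Load and validate a run configuration.

    Returns (scenario config, behavior params, regeneration table, warnings).
    All invariant violations are collected and raised together as a
    :class:`ConfigError`, so a bad file reports every problem at once.
    Unknown keys warn rather than fail.
    """
    data = _parse_mapping(path) if path is not None else {}
    data.update(overrides)

    warnings = [f"unknown key {k!r} ignored" for k in data if k not in _RUN_KEYS]
    problems: list[str] = []

    sid = data.get("scenario")
    if sid is None:
        problems.append("a scenario id (1..7) must be named")
    elif not (isinstance(sid, int) and 1 <= sid <= 7):
        problems.append(f"scenario must be an integer 1..7, got {sid!r}")

    raw_params = dict(data.get("params") or {})
    for k in list(raw_params):
        if k not in _PARAM_FIELDS:
            warnings.append(f"unknown behavior parameter {k!r} ignored")
            raw_params.pop(k)
    try:
        params = BehaviorParams(**raw_params)
    except ValueError as err:
        problems.append(f"params: {err}")
        params = BehaviorParams()

    try:
        table = (
            load_table_csv(data["table_csv"]) if data.get("table_csv") else build_default_table()
        )
    except (OSError, ValueError) as err:
        problems.append(f"table_csv: {err}")
        table = build_default_table()

    uninformed = tuple(data.get("uninformed_range", (10, 24)))
    if len(uninformed) != 2 or uninformed[0] > uninformed[1]:
        problems.append(f"uninformed_range {uninformed!r} must be (lo, hi) with lo <= hi")
        uninformed = (10, 24)

    trust_range = data.get("trust_range")
    if trust_range is not None:
        trust_range = tuple(trust_range)
        if len(trust_range) != 2 or trust_range[0] > trust_range[1]:
            problems.append(
                f"trust_range {trust_range!r} must be (lo, hi) with lo <= hi"
            )
            trust_range = None

    config = None
    if not problems:
        config = scenario(
            sid,
            robustness=bool(data.get("robustness", False)),
            replications=int(data.get("replications", 5000)),
            base_seed=int(data.get("base_seed", 0)),
            uninformed_range=uninformed,  # type: ignore[arg-type]
        )
        if trust_range is not None:
            config = dataclasses.replace(
                config,
                agent_specs=tuple(
                    dataclasses.replace(s, trust_range=trust_range)
                    for s in config.agent_specs
                ),
            )
        if "n_ticks" in data:
            config = dataclasses.replace(config, n_ticks=int(data["n_ticks"]))
        problems.extend(config.validate())
    if problems:
        raise ConfigError(problems)
    assert config is not None
    return config, params, table, warnings


def config_hash(
    config: ScenarioConfig, params: BehaviorParams, table: RegenerationTable
) -> str:
    """Stable hash identifying the effective inputs of a run."""
    payload = json.dumps(
        {
            "config": dataclasses.asdict(config),
            "params": dataclasses.asdict(params),
            "table": dataclasses.asdict(table),
        },
        sort_keys=True,
        default=list,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def trajectories_frame(results: list[RunResult]) -> pd.DataFrame:
    """Long format: one row per run x tick x agent."""
    rows = []
    for ri, r in enumerate(results):
        for ti, t in enumerate(r.ticks):
            for ai in range(len(t.knowledge)):
                rows.append(
                    {
                        "run": ri,
                        "seed": r.seed,
                        "tick": ti + 1,
                        "agent": ai,
                        "stock_before": t.stock_before,
                        "group_knowledge": np.nan
                        if t.group_knowledge is None
                        else t.group_knowledge,
                        "group_share": t.group_share,
                        "knowledge": t.knowledge[ai],
                        "confidence": t.confidence[ai],
                        "trust": t.trust[ai],
                        "spoke": bool(t.spoke[ai]),
                        "chose_group": bool(t.chose_group[ai]),
                        "chosen_extraction": t.chosen_extraction[ai],
                        "realized_extraction": t.realized_extraction[ai],
                        "expected_stock": t.expected_stock[ai],
                        "reported_stock": t.reported_stock,
                    }
                )
    return pd.DataFrame(rows)


def summary_frame(results: list[RunResult]) -> pd.DataFrame:
    """Per-tick mean stock and extraction across runs."""
    reported = np.vstack([r.reported_stock for r in results])
    post = np.vstack([r.post_harvest_stock for r in results])
    extraction = np.vstack([r.total_extraction for r in results])
    return pd.DataFrame(
        {
            "tick": np.arange(1, reported.shape[1] + 1),
            "mean_reported_stock": reported.mean(axis=0),
            "mean_post_harvest_stock": post.mean(axis=0),
            "mean_total_extraction": extraction.mean(axis=0),
        }
    )


def classification_frame(
    results: list[RunResult], table: RegenerationTable, config_id: str = ""
) -> pd.DataFrame:
    """One row per run: cooperation flag, exploitation class, learning slope."""
    rows = []
    for ri, r in enumerate(results):
        c = classify_run(r, table)
        rows.append(
            {
                "config_id": config_id or r.config.scenario_id,
                "run": ri,
                "seed": r.seed,
                "cooperative": c.run_cooperative,
                "exploitation_class": c.exploitation_class,
                "learning_slope": c.learning_trend,
            }
        )
    return pd.DataFrame(rows)


def write_manifest(
    out_dir: Path,
    config_digest: str,
    base_seed: int,
    files: list[str],
) -> Path:
    from . import __version__

    manifest = {
        "version": __version__,
        "config_hash": config_digest,
        "base_seed": base_seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "files": sorted(files),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def write_outputs(
    out_dir: str | Path,
    results: list[RunResult],
    table: RegenerationTable,
    config: ScenarioConfig,
    params: BehaviorParams,
) -> list[Path]:
    """Write trajectories, summary, classification CSVs and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = {
        "trajectories.csv": trajectories_frame(results),
        "summary.csv": summary_frame(results),
        "classification.csv": classification_frame(results, table),
    }
    written = []
    for name, frame in frames.items():
        path = out / name
        frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        written.append(path)
    written.append(
        write_manifest(
            out, config_hash(config, params, table), config.base_seed, list(frames)
        )
    )
    return written
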