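"""Configuration, results and report writers.

Conventions: configs are YAML mirroring the nested dictionary returned by
:func:`ymhsim.default_config`; trajectories are CSV with one row per time
point and one column per series (time in ISO-style decimal years); every
results file is accompanied by a JSON run manifest recording the command,
a hash of the configuration, scenario names, seeds, dt, package version
and timestamp, so that identical manifest inputs reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .engine import Trajectory
from .scenarios import INDICATORS, OutcomeSummary

__all__ = [
    "load_config",
    "save_config",
    "config_hash",
    "write_trajectory",
    "read_trajectory",
    "RunManifest",
    "write_summaries",
    "write_report",
]

#: fixed indicator order used by every report
REPORT_ORDER = ("cum_years_disorder", "cum_ed_presentations", "cum_selfharm_hosp")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return cfg


def save_config(config: dict, path, header: str | None = None) -> None:
    text = yaml.safe_dump(config, sort_keys=True, default_flow_style=False)
    with open(path, "w") as fh:
        if header:
            fh.write("".join(f"# {line}\n" for line in header.splitlines()))
        fh.write(text)


def config_hash(config: dict) -> str:
    """Stable content hash of a configuration (order-insensitive)."""
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, float_format="%.10g")


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="time")


@dataclass
class RunManifest:
    """Reproducibility record accompanying every output file."""

    command: str
    config_hash: str
    scenarios: list[str]
    seeds: list[int]
    dt: float
    outputs: list[str]
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_summaries(summaries: list[OutcomeSummary], csv_path=None, json_path=None) -> pd.DataFrame:
    """OutcomeSummary list -> tidy table (and optional CSV/JSON files)."""
    rows = []
    for s in summaries:
        for ind in REPORT_ORDER:
            rows.append(
                {
                    "scenario": s.scenario,
                    "indicator": ind,
                    "baseline": s.baseline[ind],
                    "scenario_value": s.value[ind],
                    "reduction_pct": s.reduction_pct[ind],
                }
            )
    frame = pd.DataFrame(rows)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False, float_format="%.10g")
    if json_path is not None:
        payload = {
            s.scenario: {ind: {"baseline": s.baseline[ind],
                               "value": s.value[ind],
                               "reduction_pct": round(s.reduction_pct[ind], 1)}
                         for ind in REPORT_ORDER}
            for s in summaries
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return frame


def write_report(summaries, bands=None, path=None) -> pd.DataFrame:
    """Scenario x indicator table of mean percent reductions (with 95% UIs).

    ``summaries`` may mix plain :class:`OutcomeSummary` objects
    (deterministic runs; empty UI cell) and
    :class:`~ymhsim.sensitivity.EnsembleBands` (mean and 95% UI).
    Indicator order is fixed: years with disorder, ED presentations,
    self-harm hospitalisations.
    """
    if not summaries:
        raise ValueError("need at least one summary to report")
    rows = []
    for s in summaries:
        row = {"scenario": s.scenario}
        for ind in REPORT_ORDER:
            if hasattr(s, "reduction_mean"):  # ensemble
                lo, hi = s.reduction_ui95[ind]
                row[ind] = f"{s.reduction_mean[ind]:.1f}% ({lo:.1f} to {hi:.1f})"
            else:
                row[ind] = f"{s.reduction_pct[ind]:.1f}%"
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("scenario")
    if path is not None:
        frame.to_csv(path)
    return frame
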