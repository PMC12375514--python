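"""Calibration targets, a synthetic-target generator, and the constrained optimiser.

No unit-record data are deposited for the catchment this model describes;
what is public is an aggregate surface of regional statistics (population
size and age share, disorder prevalence, service coverage, ED and
self-harm rates, service-session volumes).  :func:`default_targets`
encodes that surface as a calibration-target table.

Because the true data-generating process is unavailable,
:func:`generate_synthetic_targets` provides the testable stand-in: it
simulates the model at known "true" parameters and emits the same target
table with multiplicative lognormal observation noise, so parameter
recovery can be verified end to end.

:func:`calibrate` minimises a weighted sum of squared *relative* errors
(person counts, fractions and rates are thereby commensurable) over
box-bounded free parameters, using a seeded population-based global search
(differential evolution) followed by a local polish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .defaults import default_config
from .engine import SimulationSettings, simulate
from .model import build_model

__all__ = [
    "CalibrationTargets",
    "CalibrationProblem",
    "CalibrationResult",
    "default_targets",
    "generate_synthetic_targets",
    "calibrate",
    "get_config_path",
    "set_config_path",
]

_COLUMNS = ("series", "time", "value", "weight", "unit")


def get_config_path(config: dict, path: str):
    """Read a dotted path (e.g. ``services.channels.gp.capacity``) from a config."""
    node = config
    for part in path.split("."):
        node = node[part]
    return node


def set_config_path(config: dict, path: str, value) -> None:
    """Set a dotted path in a nested config dict."""
    parts = path.split(".")
    node = config
    for part in parts[:-1]:
        node = node[part]
    if parts[-1] not in node:
        raise KeyError(f"unknown config path {path!r}")
    node[parts[-1]] = value


@dataclass
class CalibrationTargets:
    """Named observations: (series, time, value, weight, unit) rows."""

    frame: pd.DataFrame
    window: tuple[float, float] = (2011.0, 2024.0)

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"target table missing columns {sorted(missing)}")
        if (self.frame["weight"] <= 0).any():
            raise ValueError("target weights must be > 0")
        lo, hi = self.window
        t = self.frame["time"]
        if ((t < lo - 1e-9) | (t > hi + 1e-9)).any():
            raise ValueError("target times must lie within the calibration window")

    @classmethod
    def from_records(cls, records, window=(2011.0, 2024.0)) -> "CalibrationTargets":
        return cls(pd.DataFrame(records, columns=list(_COLUMNS)), window)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, window=(2011.0, 2024.0)) -> "CalibrationTargets":
        return cls(pd.read_csv(path), window)


def default_targets() -> CalibrationTargets:
    """The printed regional statistics as a calibration-target table."""
    rows = [
        ("total_population", 2021.0, 1.1e6, 1.0, "persons"),
        ("share_under_25", 2021.0, 0.335, 1.0, "fraction"),
        ("prevalence_disorder_15_24", 2023.0, 0.31, 1.0, "fraction"),
        ("coverage_consult_15_24", 2023.0, 0.193, 1.0, "fraction/yr"),
        ("coverage_digital_15_24", 2023.0, 0.079, 1.0, "fraction/yr"),
        ("ed_rate_quarterly_12_24", 2024.0, 500.0, 1.0, "per 100k per quarter"),
        ("selfharm_rate_quarterly_15_24", 2024.0, 119.0, 1.0, "per 100k per quarter"),
        ("sessions_psychological", 2021.5, 83000.0, 1.0, "sessions/yr"),
        ("sessions_headspace", 2021.5, 10400.0, 1.0, "sessions/yr"),
        ("sessions_early_psychosis", 2021.5, 21300.0, 1.0, "sessions/yr"),
    ]
    return CalibrationTargets.from_records(rows)


def _simulate_series(config: dict, names, upto: float):
    settings = SimulationSettings(
        config["simulation"]["start"],
        max(upto, config["simulation"]["start"] + 1.0),
        config["simulation"]["dt"],
    )
    graph = build_model(config)
    return simulate(graph, settings)


def generate_synthetic_targets(
    true_params: dict[str, float] | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
    config: dict | None = None,
    template: CalibrationTargets | None = None,
) -> CalibrationTargets:
    """Simulate at known parameters and emit noisy target observations.

    ``true_params`` maps dotted config paths to values; ``noise_cv`` is the
    coefficient of variation of mean-one multiplicative lognormal noise.
    Seeded and reproducible; ``noise_cv = 0`` returns the simulated values
    exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if config is None:
        config = default_config()
    else:
        import copy

        config = copy.deepcopy(config)
    for path, value in (true_params or {}).items():
        set_config_path(config, path, value)
    if template is None:
        template = default_targets()
    frame = template.frame.copy()
    traj = _simulate_series(config, frame["series"], float(frame["time"].max()))
    values = np.array([traj.at(row.series, row.time) for row in frame.itertuples()])
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(values))
        values = values * noise
    frame["value"] = values
    return CalibrationTargets(frame, template.window)


@dataclass
class CalibrationProblem:
    """Bounded least-squares fit of free config parameters to targets."""

    free: list[tuple[str, float, float]]  # (dotted path, lower, upper)
    targets: CalibrationTargets
    config: dict = field(default_factory=default_config)

    def __post_init__(self) -> None:
        for path, lo, hi in self.free:
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"free parameter {path!r} needs finite bounds lo < hi")
            get_config_path(self.config, path)  # must resolve

    def apply(self, values) -> dict:
        import copy

        cfg = copy.deepcopy(self.config)
        for (path, _lo, _hi), v in zip(self.free, values):
            set_config_path(cfg, path, float(v))
        return cfg

    def residuals(self, values) -> np.ndarray:
        """Weighted relative errors, one per target (ordering-invariant loss)."""
        cfg = self.apply(values)
        frame = self.targets.frame
        traj = _simulate_series(cfg, frame["series"], float(frame["time"].max()))
        res = np.empty(len(frame))
        for i, row in enumerate(frame.itertuples()):
            sim = traj.at(row.series, row.time)
            res[i] = math.sqrt(row.weight) * (sim - row.value) / row.value
        return res

    def loss(self, values) -> float:
        try:
            return float(np.sum(self.residuals(values) ** 2))
        except Exception:
            return float("inf")


@dataclass
class CalibrationResult:
    parameters: dict[str, float]
    loss: float
    trace: list[float]
    success: bool
    message: str


def calibrate(
    problem: CalibrationProblem,
    seed: int = 0,
    maxiter: int = 40,
    popsize: int = 12,
    tol: float = 1e-8,
) -> CalibrationResult:
    """Seeded global-then-local bounded minimisation of the calibration loss."""
    bounds = [(lo, hi) for _p, lo, hi in problem.free]
    x0 = np.array([(lo + hi) / 2 for lo, hi in bounds])
    if not math.isfinite(problem.loss(x0)):
        mid_ok = False
        rng = np.random.default_rng(seed)
        for _ in range(20):
            x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
            if math.isfinite(problem.loss(x0)):
                mid_ok = True
                break
        if not mid_ok:
            raise RuntimeError("loss is non-finite at all sampled initial points")

    trace: list[float] = []

    def record(xk, convergence=None):  # noqa: ANN001 - scipy callback signature
        trace.append(problem.loss(xk))

    de = optimize.differential_evolution(
        problem.loss,
        bounds,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=tol,
        init="sobol",
        polish=False,
        callback=record,
        updating="deferred",
    )
    # local polish with the smooth least-squares structure
    ls = optimize.least_squares(
        problem.residuals,
        np.clip(de.x, [b[0] for b in bounds], [b[1] for b in bounds]),
        bounds=([b[0] for b in bounds], [b[1] for b in bounds]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    best_x, best_loss = (
        (ls.x, float(np.sum(ls.fun**2)))
        if np.sum(ls.fun**2) <= de.fun
        else (de.x, float(de.fun))
    )
    trace.append(best_loss)
    params = {path: float(v) for (path, _lo, _hi), v in zip(problem.free, best_x)}
    return CalibrationResult(
        parameters=params,
        loss=best_loss,
        trace=trace,
        success=bool(de.success or ls.success),
        message=str(de.message),
    )
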