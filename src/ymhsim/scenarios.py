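"""Named policy scenarios and outcome-comparison arithmetic.

Nine built-in experiments cover two policy families, all intervening from
2025 on a 2025-2035 evaluation window:

capacity growth
    doubling the capacity growth rate of all services, of specialized
    services alone, of headspace alone, doubling referrals to online
    services alone, and the three combined (``combo3``);
digital interventions
    doubling online referrals plus technology-enabled integrated care
    (``digital``), digital interventions under specialized-care degrowth
    (a three-fold reversal of the historical growth trend), and digital
    interventions with the specialized doubling delayed to January 2028.

Outcomes are cumulative over the window: years lived with symptomatic
mental disorder (person-years of the with-disorder state, ages 15-24),
MH-related ED presentations, and self-harm hospitalisations.  Reductions
are percentages relative to baseline; positive means improvement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .defaults import default_config
from .engine import ModelGraph, Override, SimulationSettings, Trajectory, simulate
from .model import build_model, channels_from_config, intervention_from_config, settings_from_config
from .services import (
    TREATMENT_CHANNELS,
    InterventionEffect,
    apply_tech_enabled_care,
    double_online_referrals,
)

__all__ = [
    "INDICATORS",
    "Scenario",
    "OutcomeSummary",
    "builtin_scenarios",
    "digital_intervention_overrides",
    "cumulative_indicator",
    "compare",
    "run_scenario",
]

#: indicator name -> (trajectory series, integrand meaning)
INDICATORS = {
    "cum_years_disorder": "disorder_15_24",
    "cum_ed_presentations": "ed_presentations_15_24",
    "cum_selfharm_hosp": "selfharm_hosp_15_24",
}

#: "3-fold reduction in the historic growth rate": growth multiplier -3
DEGROWTH_MULTIPLIER = -3.0


@dataclass
class Scenario:
    """A named, time-dated set of parameter overrides."""

    name: str
    description: str = ""
    overrides: list[Override] = field(default_factory=list)

    def start_time(self) -> float:
        """Earliest intervention start (inf for the baseline)."""
        return min((o.start for o in self.overrides), default=math.inf)


def digital_intervention_overrides(
    config: dict,
    effect: InterventionEffect | None = None,
    start_time: float | None = None,
) -> list[Override]:
    """Digital interventions: doubled online referrals + tech-enabled care.

    Also re-derives the online channel's recovery probabilities and
    treatment duration from the effect parameters, so a sensitivity draw of
    the online odds ratios or duration propagates into the scenario run.
    """
    if effect is None:
        effect = intervention_from_config(config)
    if start_time is None:
        start_time = config["intervention"].get("start", 2025.0)
    channels = channels_from_config(config, effect)
    online = next(c for c in channels if c.name == "online")
    routing = config["services"]["routing"]
    ov = [
        Override("svc_prec_mod_online", "set", online.p_recovery_mod, start_time),
        Override("svc_prec_dis_online", "set", online.p_recovery_dis, start_time),
        Override("svc_dur_online", "set", online.duration_years, start_time),
    ]
    ov += double_online_referrals(channels, routing, start_time)
    ov += apply_tech_enabled_care(effect, channels, routing, start_time)
    return ov


def builtin_scenarios(
    config: dict | None = None,
    effect: InterventionEffect | None = None,
    start_time: float = 2025.0,
) -> dict[str, Scenario]:
    """The nine built-in experiments, resolved against a configuration."""
    if config is None:
        config = default_config()
    channels = channels_from_config(config, effect)
    routing = config["services"]["routing"]

    def gmult(channel: str, value: float, t0: float = start_time) -> Override:
        return Override(f"svc_gmult_{channel}", "set", value, t0)

    def double_growth(names, t0=start_time):
        return [gmult(c, 2.0, t0) for c in names]

    online_ref = double_online_referrals(channels, routing, start_time)
    digital = digital_intervention_overrides(config, effect, start_time)

    scenarios = {
        "baseline": Scenario("baseline", "business as usual; no interventions", []),
        "double_all": Scenario(
            "double_all",
            "double the capacity growth rate of all services from 2025",
            double_growth(TREATMENT_CHANNELS),
        ),
        "double_specialized": Scenario(
            "double_specialized",
            "double the specialized-services capacity growth rate from 2025",
            double_growth(["specialized"]),
        ),
        "double_online_referrals": Scenario(
            "double_online_referrals",
            "double the rate of referrals to online services from 2025",
            list(online_ref),
        ),
        "double_headspace": Scenario(
            "double_headspace",
            "double the headspace capacity growth rate from 2025",
            double_growth(["headspace"]),
        ),
        "combo3": Scenario(
            "combo3",
            "double specialized and headspace growth and online referrals, combined",
            double_growth(["specialized", "headspace"]) + list(online_ref),
        ),
        "digital": Scenario(
            "digital",
            "double online referrals plus technology-enabled integrated care",
            list(digital),
        ),
        "degrowth_specialized_with_digital": Scenario(
            "degrowth_specialized_with_digital",
            "digital interventions while specialized capacity growth reverses 3-fold",
            list(digital) + [gmult("specialized", DEGROWTH_MULTIPLIER)],
        ),
        "digital_plus_specialized_2028": Scenario(
            "digital_plus_specialized_2028",
            "digital interventions from 2025; specialized doubling delayed to 2028",
            list(digital) + double_growth(["specialized"], 2028.0),
        ),
    }
    return scenarios


def cumulative_indicator(
    traj: Trajectory, indicator: str, window: tuple[float, float] = (2025.0, 2035.0)
) -> float:
    """Time-integral of an indicator's annual flow/headcount over the window.

    ``cum_years_disorder`` integrates a headcount into person-years; the
    event indicators integrate annual event flows into event counts.
    Trapezoid rule on the simulation grid.
    """
    series_name = INDICATORS.get(indicator, indicator)
    if series_name not in traj.series:
        raise KeyError(f"indicator series {series_name!r} not in trajectory")
    t0, t1 = window
    if t0 < traj.time[0] - 1e-9 or t1 > traj.time[-1] + 1e-9:
        raise ValueError(f"window {window} outside simulated horizon "
                         f"({traj.time[0]:.2f}, {traj.time[-1]:.2f})")
    mask = (traj.time >= t0 - 1e-9) & (traj.time <= t1 + 1e-9)
    return float(np.trapezoid(traj[series_name][mask], traj.time[mask]))


@dataclass
class OutcomeSummary:
    """Baseline-vs-scenario cumulative outcomes with percent reductions."""

    scenario: str
    window: tuple[float, float]
    baseline: dict[str, float]
    value: dict[str, float]
    reduction_pct: dict[str, float]

    def contribution_share(self, reference: "OutcomeSummary") -> dict[str, float]:
        """This scenario's reduction as a percentage of a reference scenario's."""
        out = {}
        for k, r in self.reduction_pct.items():
            ref = reference.reduction_pct[k]
            out[k] = 100.0 * r / ref if ref != 0 else math.nan
        return out


def compare(
    baseline_traj: Trajectory,
    scenario_traj: Trajectory,
    scenario_name: str = "scenario",
    window: tuple[float, float] = (2025.0, 2035.0),
) -> OutcomeSummary:
    """Percent reduction per cumulative indicator (positive = improvement)."""
    if not np.array_equal(baseline_traj.time, scenario_traj.time):
        raise ValueError("baseline and scenario trajectories must share a grid")
    base, val, red = {}, {}, {}
    for ind in INDICATORS:
        b = cumulative_indicator(baseline_traj, ind, window)
        s = cumulative_indicator(scenario_traj, ind, window)
        if b == 0:
            raise ValueError(f"zero baseline cumulative for {ind!r}")
        base[ind], val[ind] = b, s
        red[ind] = 100.0 * (b - s) / b
    return OutcomeSummary(scenario_name, window, base, val, red)


def run_scenario(
    scenario: Scenario,
    config: dict | None = None,
    graph: ModelGraph | None = None,
    settings: SimulationSettings | None = None,
    extra_overrides: list[Override] = (),
) -> Trajectory:
    """Simulate one scenario (building the model from config if needed)."""
    if config is None:
        config = default_config()
    if graph is None:
        graph = build_model(config)
    if settings is None:
        settings = settings_from_config(config)
    return simulate(graph, settings, list(scenario.overrides) + list(extra_overrides))
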