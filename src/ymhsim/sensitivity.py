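"""Latin-hypercube probabilistic sensitivity analysis with uncertainty bands.

Two uncertainty designs are built in, mirroring the two analyses the model
is used for:

``digital_implementation``
    implementation uncertainty of the digital interventions: uptake of
    technology-enabled integrated care (uniform 30-70%), its effect sizes
    on recovery, disengagement and referral to specialized care (lognormal
    around the baseline odds/hazard ratios), and the online channel's
    recovery odds ratios and treatment duration.
``social_determinants``
    uncertainty in the social determinants of youth mental health: shifts
    to the historical trend of social cohesion (uniform -14% to +7%),
    substance-misuse onset (-10% to 0) and raised-SDQ onset (-20% to
    +16%), applied as yearly change-rate multipliers from 2025.

Lognormal parameters are the log-scale (mu, sigma) pairs whose median
e^mu equals the baseline effect size.  Sampling is stratified
inverse-CDF Latin hypercube (one draw per equal-probability stratum per
parameter, independently permuted), seeded and reproducible.  Ensemble
summaries are pointwise empirical percentile bands (50% UI = 25th-75th,
95% UI = 2.5th-97.5th) and, for cumulative reductions, means with 95% UIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .defaults import default_config
from .engine import Override, SimulationError, simulate
from .model import build_model, settings_from_config
from .scenarios import INDICATORS, OutcomeSummary, builtin_scenarios, compare
from .services import InterventionEffect

__all__ = [
    "ParameterDistribution",
    "LHSDesign",
    "EnsembleResult",
    "EnsembleBands",
    "builtin_designs",
    "latin_hypercube",
    "run_ensemble",
    "ui_bands",
]

#: trajectory series whose pointwise bands mirror the reported figures
BAND_SERIES = (
    "prevalence_disorder_15_24",
    "ed_presentations_15_24",
    "selfharm_hosp_15_24",
)

#: sensitivity target -> (kind, payload) used when building per-sample runs
_SHIFT_PARAMS = {
    "shift.social_cohesion": "det_shift_social_cohesion",
    "shift.substance": "sub_shift",
    "shift.sdq": "sdq_trend_shift",
}
_EFFECT_FIELDS = {
    "intervention.uptake": "uptake",
    "intervention.or_recovery": "or_recovery",
    "intervention.hr_disengagement": "hr_disengagement",
    "intervention.or_referral_specialized": "or_referral_specialized",
    "intervention.or_online_recovery_mod": "or_online_recovery_mod",
    "intervention.or_online_recovery_dis": "or_online_recovery_dis",
    "intervention.online_duration_weeks": "online_duration_weeks",
}


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter: lognormal (mu, sigma) or uniform (lower, upper)."""

    name: str
    kind: str  # "lognormal" | "uniform"
    mu: float = 0.0  # log-scale location (lognormal)
    sigma: float = 0.0  # log-scale spread (lognormal)
    lower: float = 0.0
    upper: float = 0.0
    target: str = ""  # semantic parameter path

    def __post_init__(self) -> None:
        if self.kind == "lognormal":
            if self.sigma <= 0:
                raise ValueError("lognormal sigma must be > 0")
        elif self.kind == "uniform":
            # lower == upper is allowed as a degenerate point mass
            if self.lower > self.upper:
                raise ValueError("uniform bounds must satisfy lower <= upper")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    def ppf(self, q):
        if self.kind == "lognormal":
            return stats.lognorm.ppf(q, s=self.sigma, scale=math.exp(self.mu))
        if self.upper == self.lower:
            return np.full_like(np.asarray(q, dtype=float), self.lower)
        return stats.uniform.ppf(q, loc=self.lower, scale=self.upper - self.lower)

    @property
    def median(self) -> float:
        return float(self.ppf(0.5))


def builtin_designs() -> dict[str, list[ParameterDistribution]]:
    """The two built-in uncertainty designs."""
    digital = [
        ParameterDistribution("tech_care_uptake", "uniform", lower=0.30, upper=0.70,
                              target="intervention.uptake"),
        ParameterDistribution("or_recovery", "lognormal", mu=0.16324, sigma=0.24061,
                              target="intervention.or_recovery"),
        ParameterDistribution("hr_disengagement", "lognormal", mu=-0.3285, sigma=0.12506,
                              target="intervention.hr_disengagement"),
        ParameterDistribution("or_referral_specialized", "lognormal", mu=0.23579, sigma=0.40718,
                              target="intervention.or_referral_specialized"),
        ParameterDistribution("or_online_recovery_mod", "lognormal", mu=-0.91629, sigma=0.28552,
                              target="intervention.or_online_recovery_mod"),
        ParameterDistribution("or_online_recovery_dis", "lognormal", mu=-1.687, sigma=0.28552,
                              target="intervention.or_online_recovery_dis"),
        ParameterDistribution("online_duration_weeks", "uniform", lower=2.0, upper=10.0,
                              target="intervention.online_duration_weeks"),
    ]
    determinants = [
        ParameterDistribution("social_cohesion_shift", "uniform", lower=-0.14, upper=0.07,
                              target="shift.social_cohesion"),
        ParameterDistribution("substance_onset_shift", "uniform", lower=-0.10, upper=0.0,
                              target="shift.substance"),
        ParameterDistribution("sdq_onset_shift", "uniform", lower=-0.20, upper=0.16,
                              target="shift.sdq"),
    ]
    return {"digital_implementation": digital, "social_determinants": determinants}


@dataclass
class LHSDesign:
    """An n x k stratified sample over named parameter distributions."""

    n: int
    seed: int
    distributions: list[ParameterDistribution]
    samples: pd.DataFrame

    def __iter__(self):
        return (row._asdict() for row in self.samples.itertuples(index=False))


def latin_hypercube(n: int, distributions: list[ParameterDistribution], seed: int = 0) -> LHSDesign:
    """Stratified inverse-CDF sampling: one draw per equal-probability stratum."""
    if n < 2:
        raise ValueError("n must be >= 2")
    sampler = qmc.LatinHypercube(d=len(distributions), seed=seed)
    unit = sampler.random(n)
    cols = {}
    for j, dist in enumerate(distributions):
        cols[dist.name] = dist.ppf(unit[:, j])
    return LHSDesign(n, seed, list(distributions), pd.DataFrame(cols))


@dataclass
class EnsembleResult:
    """Per-sample outcome summaries plus indicator trajectories."""

    scenario: str
    n: int
    time: np.ndarray
    series: dict[str, np.ndarray]  # name -> (n_success, n_time)
    summaries: list[OutcomeSummary]
    failed: list[int] = field(default_factory=list)

    @property
    def reductions(self) -> pd.DataFrame:
        return pd.DataFrame([s.reduction_pct for s in self.summaries])


def _sample_pieces(sample: dict, config: dict):
    """Split one LHS row into an intervention effect and shift overrides."""
    effect_kwargs = {}
    shifts: list[Override] = []
    start = config["intervention"].get("start", 2025.0)
    name_to_target = sample.pop("_targets")
    for pname, value in sample.items():
        target = name_to_target[pname]
        if target in _EFFECT_FIELDS:
            effect_kwargs[_EFFECT_FIELDS[target]] = float(value)
        elif target in _SHIFT_PARAMS:
            shifts.append(Override(_SHIFT_PARAMS[target], "set", float(value), start))
        else:
            raise KeyError(f"unmapped sensitivity target {target!r}")
    base = config["intervention"]
    effect = InterventionEffect(
        uptake=effect_kwargs.get("uptake", base["uptake"]),
        or_recovery=effect_kwargs.get("or_recovery", base["or_recovery"]),
        hr_disengagement=effect_kwargs.get("hr_disengagement", base["hr_disengagement"]),
        or_referral_specialized=effect_kwargs.get(
            "or_referral_specialized", base["or_referral_specialized"]
        ),
        or_online_recovery_mod=effect_kwargs.get(
            "or_online_recovery_mod", base["or_online_recovery_mod"]
        ),
        or_online_recovery_dis=effect_kwargs.get(
            "or_online_recovery_dis", base["or_online_recovery_dis"]
        ),
        online_duration_weeks=effect_kwargs.get(
            "online_duration_weeks", base["online_duration_weeks"]
        ),
    )
    return effect, shifts, bool(effect_kwargs)


def run_ensemble(
    scenario_name: str,
    design: LHSDesign,
    config: dict | None = None,
    window: tuple[float, float] = (2025.0, 2035.0),
    max_failure_fraction: float = 0.01,
) -> EnsembleResult:
    """Run the full model once per design sample, from-2025 overrides active.

    Shift-type parameters perturb the world itself, so they apply to both
    the baseline and the scenario run of a sample (reductions are computed
    within-sample); intervention-implementation parameters redefine the
    scenario's effect block only.  Failed (non-finite) runs are recorded,
    and the ensemble aborts if more than ``max_failure_fraction`` fail.
    """
    if config is None:
        config = default_config()
    graph = build_model(config)
    settings = settings_from_config(config)
    targets = {d.name: d.target for d in design.distributions}

    default_base = simulate(graph, settings)
    series_acc: dict[str, list[np.ndarray]] = {k: [] for k in BAND_SERIES}
    summaries: list[OutcomeSummary] = []
    failed: list[int] = []

    for i, row in enumerate(design.samples.itertuples(index=False)):
        sample = dict(row._asdict())
        sample["_targets"] = targets
        effect, shifts, has_effect = _sample_pieces(sample, config)
        scen = builtin_scenarios(config, effect=effect if has_effect else None)[scenario_name]
        try:
            base = simulate(graph, settings, shifts) if shifts else default_base
            traj = simulate(graph, settings, list(scen.overrides) + shifts)
        except SimulationError:
            failed.append(i)
            continue
        summaries.append(compare(base, traj, scenario_name, window))
        for k in BAND_SERIES:
            series_acc[k].append(traj[k])

    if len(failed) > max_failure_fraction * design.n:
        raise RuntimeError(
            f"{len(failed)}/{design.n} ensemble runs failed: samples {failed[:10]}..."
        )
    return EnsembleResult(
        scenario=scenario_name,
        n=design.n,
        time=default_base.time,
        series={k: np.vstack(v) for k, v in series_acc.items()},
        summaries=summaries,
        failed=failed,
    )


@dataclass
class EnsembleBands:
    """Pointwise percentile bands and cumulative-reduction summaries."""

    scenario: str
    time: np.ndarray
    bands: dict[str, pd.DataFrame]  # series -> columns median/p25/p75/p2_5/p97_5
    reduction_mean: dict[str, float]
    reduction_ui95: dict[str, tuple[float, float]]


def ui_bands(ensemble: EnsembleResult, levels: tuple[int, ...] = (50, 95)) -> EnsembleBands:
    """Empirical percentile bands; requires at least 20 successful runs."""
    n_ok = len(ensemble.summaries)
    if n_ok < 20:
        raise ValueError(f"need >= 20 successful runs for bands, got {n_ok}")
    qs: dict[str, float] = {"median": 50.0}
    for lv in levels:
        qs[f"p{(50 - lv / 2):g}".replace(".", "_")] = 50.0 - lv / 2.0
        qs[f"p{(50 + lv / 2):g}".replace(".", "_")] = 50.0 + lv / 2.0
    bands = {}
    for name, matrix in ensemble.series.items():
        cols = {
            label: np.percentile(matrix, q, axis=0, method="linear")
            for label, q in qs.items()
        }
        bands[name] = pd.DataFrame(cols, index=pd.Index(ensemble.time, name="time"))
    red = ensemble.reductions
    mean = {k: float(red[k].mean()) for k in INDICATORS}
    ui = {
        k: (float(np.percentile(red[k], 2.5)), float(np.percentile(red[k], 97.5)))
        for k in INDICATORS
    }
    return EnsembleBands(ensemble.scenario, ensemble.time, bands, mean, ui)
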