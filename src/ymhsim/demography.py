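"""Population aging chain and social-determinant trend indices.

The population is segmented into six age bands (0-4, 5-11, 12-14, 15-17,
18-24, 25+).  Aging follows the standard first-order system-dynamics chain:
the outflow of a band equals its stock divided by the band width in years.
Births enter the 0-4 band in proportion to the adult (25+) population; net
migration is a per-band proportional rate (overseas and interstate streams
combined), which is what lets the chain sustain balanced exponential growth
such as the ~1.42 %/yr expansion of the 15-24 population that a fast-growing
urban catchment exhibits.

Social determinants of youth mental health (education, labour-market/NEET,
homelessness, justice contact, social cohesion, family and domestic
violence) are represented in reduced form: each is a dimensionless trend
index ``L`` (1.0 = baseline year) evolving as ``dL/dt = r (1 + shift) L``
with a historical change rate ``r`` and a scenario/sensitivity ``shift``.
Each index exports a multiplier ``L^elasticity`` that modulates distress
onset and recovery rates elsewhere in the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .engine import ModelGraph, Override, SimulationSettings, simulate

__all__ = [
    "AGE_BANDS",
    "BAND_WIDTHS",
    "DETERMINANT_NAMES",
    "PopulationParams",
    "DeterminantIndex",
    "build_population_chain",
    "build_determinant_index",
    "apply_trend_shift",
    "balanced_population_params",
]

#: ordered age-band labels and widths in years (25+ is unbounded: exit only
#: through mortality, so its "width" is None)
AGE_BANDS: tuple[str, ...] = ("a0_4", "a5_11", "a12_14", "a15_17", "a18_24", "a25p")
BAND_WIDTHS: dict[str, float | None] = {
    "a0_4": 5.0,
    "a5_11": 7.0,
    "a12_14": 3.0,
    "a15_17": 3.0,
    "a18_24": 7.0,
    "a25p": None,
}

DETERMINANT_NAMES = (
    "education",
    "labour_neet",
    "homelessness",
    "justice",
    "social_cohesion",
    "family_violence",
)


@dataclass
class PopulationParams:
    """Demographic rates for the six-band aging chain.

    ``birth_rate`` is births per 25+ person per year; ``net_migration`` is a
    per-band proportional net rate (fraction/yr, negative allowed);
    ``mortality`` is a per-band hazard (/yr).
    """

    initial: dict[str, float]
    birth_rate: float
    net_migration: dict[str, float] = field(default_factory=dict)
    mortality: dict[str, float] = field(default_factory=dict)
    target_youth_growth: float = 0.0142

    def __post_init__(self) -> None:
        for band, count in self.initial.items():
            if band not in BAND_WIDTHS:
                raise ValueError(f"unknown age band {band!r}")
            if count < 0:
                raise ValueError(f"negative initial count for {band!r}")
        if any(m < 0 for m in self.mortality.values()):
            raise ValueError("mortality rates must be >= 0")


@dataclass
class DeterminantIndex:
    """Reduced-form social-determinant trend driver."""

    name: str
    initial_level: float = 1.0
    change_rate: float = 0.0  # baseline fraction/yr from the historical trend
    elasticity_onset: float = 0.0
    elasticity_recovery: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_level <= 0:
            raise ValueError("index level must be > 0")
        for e in (self.elasticity_onset, self.elasticity_recovery):
            if not math.isfinite(e):
                raise ValueError("elasticities must be finite")


def build_population_chain(params: PopulationParams, prefix: str = "pop_") -> ModelGraph:
    """Build the six-band aging chain as a composable model fragment.

    One stock per band; aging outflow of band ``i`` is ``stock_i / width_i``;
    births enter 0-4; migration and mortality act per band.
    """
    g = ModelGraph()
    for band in AGE_BANDS:
        g.add_stock(prefix + band, params.initial.get(band, 0.0), unit="persons")
        g.add_param(prefix + "mig_" + band, params.net_migration.get(band, 0.0), unit="1/yr")
        g.add_param(prefix + "mort_" + band, params.mortality.get(band, 0.0), unit="1/yr")
    g.add_param(prefix + "birth_rate", params.birth_rate, unit="1/yr")

    g.add_flow(
        prefix + "births",
        f"{prefix}birth_rate * {prefix}a25p",
        sink=prefix + "a0_4",
        unit="persons/yr",
    )
    for band, nxt in zip(AGE_BANDS[:-1], AGE_BANDS[1:]):
        width = BAND_WIDTHS[band]
        if width is None or width <= 0:
            raise ValueError(f"nonpositive width for aging band {band!r}")
        g.add_flow(
            prefix + "aging_" + band,
            f"{prefix}{band} / {width}",
            source=prefix + band,
            sink=prefix + nxt,
            unit="persons/yr",
        )
    for band in AGE_BANDS:
        g.add_flow(
            prefix + "migration_" + band,
            f"{prefix}mig_{band} * {prefix}{band}",
            sink=prefix + band,
            unit="persons/yr",
        )
        g.add_flow(
            prefix + "deaths_" + band,
            f"{prefix}mort_{band} * {prefix}{band}",
            source=prefix + band,
            unit="persons/yr",
        )
    g.add_aux(
        prefix + "total",
        " + ".join(prefix + b for b in AGE_BANDS),
        unit="persons",
    )
    g.add_aux(prefix + "youth_15_24", f"{prefix}a15_17 + {prefix}a18_24", unit="persons")
    return g


def build_determinant_index(d: DeterminantIndex, prefix: str = "det_") -> ModelGraph:
    """Trend-index fragment: level stock, drift flow, onset/recovery multipliers."""
    g = ModelGraph()
    level = prefix + d.name
    g.add_stock(level, d.initial_level, unit="index")
    g.add_param(prefix + "rate_" + d.name, d.change_rate, unit="1/yr")
    g.add_param(prefix + "shift_" + d.name, 0.0)
    g.add_param(prefix + "eonset_" + d.name, d.elasticity_onset)
    g.add_param(prefix + "erec_" + d.name, d.elasticity_recovery)
    g.add_flow(
        prefix + "drift_" + d.name,
        f"{prefix}rate_{d.name} * (1 + {prefix}shift_{d.name}) * {level}",
        sink=level,
        unit="index/yr",
    )
    g.add_aux(prefix + "mult_onset_" + d.name, f"pow({level}, {prefix}eonset_{d.name})")
    g.add_aux(prefix + "mult_rec_" + d.name, f"pow({level}, {prefix}erec_{d.name})")
    return g


def apply_trend_shift(
    graph: ModelGraph, index_name: str, shift: float, start_time: float, prefix: str = "det_"
) -> list[Override]:
    """Multiply an index's change rate by ``(1 + shift)`` from ``start_time`` on."""
    param = prefix + "shift_" + index_name
    if param not in graph.params:
        raise ValueError(f"unknown determinant index {index_name!r}")
    return [Override(param, "set", float(shift), start_time, math.inf)]


def balanced_population_params(
    total: float,
    band_shares: dict[str, float],
    youth_growth: float = 0.0142,
    adult_growth: float | None = None,
    overall_growth: float = 0.0175,
    mortality: dict[str, float] | None = None,
    refine: bool = True,
    refine_window: tuple[float, float] = (2025.0, 2035.0),
    start_time: float = 2011.0,
) -> PopulationParams:
    """Construct demographic rates that hold the chain on a balanced growth path.

    Migration rates are solved band-by-band so each youth band initially
    grows at ``youth_growth`` and 25+ at a rate making overall growth equal
    ``overall_growth``.  Because births are tied to the 25+ stock, the
    pipeline drifts slightly over decades; with ``refine=True`` a secant
    iteration on the 15-24 migration rates pins the simulated CAGR over
    ``refine_window`` to ``youth_growth``.
    """
    if abs(sum(band_shares.values()) - 1.0) > 1e-9:
        raise ValueError("band shares must sum to 1")
    mort = dict(mortality or {
        "a0_4": 0.0008,
        "a5_11": 0.0001,
        "a12_14": 0.0002,
        "a15_17": 0.0003,
        "a18_24": 0.0004,
        "a25p": 0.0120,
    })
    counts = {b: total * band_shares[b] for b in AGE_BANDS}
    youth_share = sum(band_shares[b] for b in AGE_BANDS[:-1])
    if adult_growth is None:
        adult_growth = (overall_growth - youth_growth * youth_share) / (1.0 - youth_share)

    birth_rate = (youth_growth + 1.0 / 5.0 + mort["a0_4"]) * counts["a0_4"] / counts["a25p"]
    mig: dict[str, float] = {"a0_4": 0.0}
    prev = "a0_4"
    for band in AGE_BANDS[1:-1]:
        inflow = counts[prev] / BAND_WIDTHS[prev]
        mig[band] = youth_growth + 1.0 / BAND_WIDTHS[band] + mort[band] - inflow / counts[band]
        prev = band
    mig["a25p"] = adult_growth + mort["a25p"] - (counts["a18_24"] / 7.0) / counts["a25p"]

    params = PopulationParams(counts, birth_rate, mig, mort, youth_growth)
    if not refine:
        return params

    def simulated_cagr(p: PopulationParams) -> float:
        g = build_population_chain(p)
        t0, t1 = refine_window
        traj = simulate(g, SimulationSettings(start_time, t1, 1.0 / 12))
        y0 = traj.at("pop_youth_15_24", t0)
        y1 = traj.at("pop_youth_15_24", t1)
        return (y1 / y0) ** (1.0 / (t1 - t0)) - 1.0

    # secant iteration on a common offset to the 15-17 / 18-24 migration rates
    delta = 0.0
    err = simulated_cagr(params) - youth_growth
    step = -err  # unit sensitivity is ~1 by construction
    for _ in range(8):
        if abs(err) < 2e-5:
            break
        trial = delta + step
        mig_t = dict(mig)
        mig_t["a15_17"] += trial
        mig_t["a18_24"] += trial
        cand = PopulationParams(counts, birth_rate, mig_t, mort, youth_growth)
        err_t = simulated_cagr(cand) - youth_growth
        denom = err_t - err
        if denom == 0:
            delta, err = trial, err_t
            break
        step = -err_t * (trial - delta) / denom
        delta, err, params = trial, err_t, cand
    mig["a15_17"] += delta
    mig["a18_24"] += delta
    return PopulationParams(counts, birth_rate, mig, mort, youth_growth)
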