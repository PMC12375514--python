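"""Psychological distress states, early-life (SDQ) risk states, and event flows.

People aged 12+ occupy one of three distress states: low distress (K10
10-15), moderate-to-very-high distress without a 12-month disorder (K10
>= 16), and moderate-to-very-high distress meeting 12-month disorder
criteria.  Children aged 0-11 occupy one of three Strengths-and-
Difficulties (SDQ) risk states: close to average, slightly raised, and
high/very-high; the SDQ mix of children aging into the 12-14 band weights
their entry into the distress chain.

Onset (low -> moderate) is modulated by social-determinant indices and the
SDQ carry-over; escalation (moderate -> disorder) by substance-misuse
prevalence; recovery by both spontaneous remission and service-attributable
flows supplied by the care-pathways module.  Self-harm hospitalisations,
mental-health ED presentations and suicide deaths are modelled as
state-dependent hazards (events per person-year), reported as annual flows
and as rates per 100,000 of the relevant age population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import ModelGraph

__all__ = [
    "DISTRESS_STATES",
    "SDQ_STATES",
    "DistressRates",
    "SDQParams",
    "SubstanceParams",
    "EventHazards",
    "build_distress_chain",
    "build_sdq_chain",
    "build_substance_misuse",
    "event_flow",
]

DISTRESS_STATES = ("low", "mod", "dis")
SDQ_STATES = ("close", "raised", "high")

#: youth bands covered by the distress chain, with widths (years)
DISTRESS_BANDS = (("a12_14", 3.0), ("a15_17", 3.0), ("a18_24", 7.0))


@dataclass
class DistressRates:
    """Transition rates of the three-state distress chain (per band, /yr)."""

    onset: dict[str, float]
    escalation: dict[str, float]
    recovery_mod: dict[str, float]
    recovery_dis: dict[str, float]

    def __post_init__(self) -> None:
        for d in (self.onset, self.escalation, self.recovery_mod, self.recovery_dis):
            if any(v < 0 for v in d.values()):
                raise ValueError("distress transition rates must be >= 0")


@dataclass
class SDQParams:
    """Transition rates of the 0-11 SDQ risk chain and age-12 entry mix."""

    onset: float  # close -> raised, /yr
    escalation: float  # raised -> high, /yr
    recovery_raised: float  # raised -> close, /yr
    recovery_high: float  # high -> raised, /yr
    entry_mod_fraction: float = 0.05  # probability an age-12 entrant starts distressed
    carry_multiplier: float = 1.0  # >1: high/very-high entrants carry extra onset risk

    def __post_init__(self) -> None:
        if min(self.onset, self.escalation, self.recovery_raised, self.recovery_high) < 0:
            raise ValueError("SDQ transition rates must be >= 0")
        if not 0 <= self.entry_mod_fraction <= 1:
            raise ValueError("entry_mod_fraction must be a probability")
        if self.carry_multiplier < 0:
            raise ValueError("carry_multiplier must be >= 0")


@dataclass
class EventHazards:
    """Per-person-year hazards by distress state (low, mod, dis).

    Disorder-state hazards must be at least the no-disorder ones, which in
    turn are at least the low-distress ones.
    """

    selfharm: dict[str, float] = field(default_factory=dict)
    suicide: dict[str, float] = field(default_factory=dict)
    ed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, h in (("selfharm", self.selfharm), ("suicide", self.suicide), ("ed", self.ed)):
            if not h:
                continue
            if any(v < 0 for v in h.values()):
                raise ValueError(f"{name} hazards must be >= 0")
            if not h.get("dis", 0.0) >= h.get("mod", 0.0) >= h.get("low", 0.0):
                raise ValueError(f"{name} hazards must be ordered dis >= mod >= low")


def build_distress_chain(
    rates: DistressRates,
    initial: dict[str, tuple[float, float, float]],
    onset_mult: str = "1",
    escalation_mult: str = "1",
    recovery_mult: str = "1",
    service_recovery_mod: str | None = None,
    service_recovery_dis: str | None = None,
    aging: bool = True,
    age_out_to: str | None = None,
    prefix: str = "dx_",
) -> ModelGraph:
    """Three distress stocks per youth band with onset/escalation/recovery flows.

    ``onset_mult`` / ``escalation_mult`` / ``recovery_mult`` are expressions
    (usually auxiliary names defined elsewhere in the composed model) that
    modulate the corresponding rates; ``service_recovery_*`` name series
    giving the total service-attributable recovery flow (persons/yr), which
    is allocated across bands in proportion to band headcounts.  Aging moves
    people between bands preserving distress state; the oldest band ages out
    of the youth model across the boundary.
    """
    g = ModelGraph()
    bands = [b for b, _ in DISTRESS_BANDS]
    for band, _w in DISTRESS_BANDS:
        low0, mod0, dis0 = initial.get(band, (0.0, 0.0, 0.0))
        g.add_stock(f"{prefix}low_{band}", low0, unit="persons")
        g.add_stock(f"{prefix}mod_{band}", mod0, unit="persons")
        g.add_stock(f"{prefix}dis_{band}", dis0, unit="persons")
        g.add_param(f"{prefix}onset_{band}", rates.onset.get(band, 0.0), unit="1/yr")
        g.add_param(f"{prefix}esc_{band}", rates.escalation.get(band, 0.0), unit="1/yr")
        g.add_param(f"{prefix}recm_{band}", rates.recovery_mod.get(band, 0.0), unit="1/yr")
        g.add_param(f"{prefix}recd_{band}", rates.recovery_dis.get(band, 0.0), unit="1/yr")

    for state in DISTRESS_STATES:
        g.add_aux(
            f"{prefix}{state}_total",
            " + ".join(f"{prefix}{state}_{b}" for b in bands),
            unit="persons",
        )

    for band, _w in DISTRESS_BANDS:
        g.add_flow(
            f"{prefix}onset_flow_{band}",
            f"{prefix}onset_{band} * ({onset_mult}) * {prefix}low_{band}",
            source=f"{prefix}low_{band}",
            sink=f"{prefix}mod_{band}",
        )
        g.add_flow(
            f"{prefix}esc_flow_{band}",
            f"{prefix}esc_{band} * ({escalation_mult}) * {prefix}mod_{band}",
            source=f"{prefix}mod_{band}",
            sink=f"{prefix}dis_{band}",
        )
        g.add_flow(
            f"{prefix}recm_flow_{band}",
            f"{prefix}recm_{band} * ({recovery_mult}) * {prefix}mod_{band}",
            source=f"{prefix}mod_{band}",
            sink=f"{prefix}low_{band}",
        )
        g.add_flow(
            f"{prefix}recd_flow_{band}",
            f"{prefix}recd_{band} * ({recovery_mult}) * {prefix}dis_{band}",
            source=f"{prefix}dis_{band}",
            sink=f"{prefix}mod_{band}",
        )
        if service_recovery_mod is not None:
            g.add_flow(
                f"{prefix}serv_recm_{band}",
                f"({service_recovery_mod}) * {prefix}mod_{band} / max({prefix}mod_total, 1e-9)",
                source=f"{prefix}mod_{band}",
                sink=f"{prefix}low_{band}",
            )
        if service_recovery_dis is not None:
            # successful treatment of the disorder state is remission to low
            # distress; spontaneous recovery only steps down to moderate
            g.add_flow(
                f"{prefix}serv_recd_{band}",
                f"({service_recovery_dis}) * {prefix}dis_{band} / max({prefix}dis_total, 1e-9)",
                source=f"{prefix}dis_{band}",
                sink=f"{prefix}low_{band}",
            )

    if aging:
        for (band, width), (nxt, _w2) in zip(DISTRESS_BANDS[:-1], DISTRESS_BANDS[1:]):
            for state in DISTRESS_STATES:
                g.add_flow(
                    f"{prefix}aging_{state}_{band}",
                    f"{prefix}{state}_{band} / {width}",
                    source=f"{prefix}{state}_{band}",
                    sink=f"{prefix}{state}_{nxt}",
                )
        last, last_w = DISTRESS_BANDS[-1]
        for state in DISTRESS_STATES:
            g.add_flow(
                f"{prefix}aging_out_{state}",
                f"{prefix}{state}_{last} / {last_w}",
                source=f"{prefix}{state}_{last}",
                sink=age_out_to,
            )

    for band, _w in DISTRESS_BANDS:
        g.add_aux(
            f"{prefix}pop_{band}",
            f"{prefix}low_{band} + {prefix}mod_{band} + {prefix}dis_{band}",
            unit="persons",
        )
        g.add_aux(
            f"{prefix}prev_dis_{band}",
            f"{prefix}dis_{band} / max({prefix}pop_{band}, 1e-9)",
        )
    return g


def build_sdq_chain(
    params: SDQParams,
    initial: dict[str, tuple[float, float, float]],
    onset_mult: str = "1",
    exit_to: tuple[str, str] | None = None,
    prefix: str = "sdq_",
) -> ModelGraph:
    """SDQ risk chain for the 0-4 and 5-11 bands.

    ``exit_to = (low_stock, mod_stock)`` wires the 5-11 outflow into the
    distress chain: every entrant starts distressed with probability
    ``entry_mod_fraction``, multiplied by ``carry_multiplier`` (capped at 1)
    for entrants in the high/very-high SDQ state.  With the carry multiplier
    at 1 the entry mix is independent of the SDQ composition.
    """
    g = ModelGraph()
    bands = (("a0_4", 5.0), ("a5_11", 7.0))
    for band, _w in bands:
        c0, r0, h0 = initial.get(band, (0.0, 0.0, 0.0))
        g.add_stock(f"{prefix}close_{band}", c0, unit="persons")
        g.add_stock(f"{prefix}raised_{band}", r0, unit="persons")
        g.add_stock(f"{prefix}high_{band}", h0, unit="persons")
    g.add_param(f"{prefix}onset", params.onset, unit="1/yr")
    g.add_param(f"{prefix}esc", params.escalation, unit="1/yr")
    g.add_param(f"{prefix}rec_raised", params.recovery_raised, unit="1/yr")
    g.add_param(f"{prefix}rec_high", params.recovery_high, unit="1/yr")

    for band, _w in bands:
        g.add_flow(
            f"{prefix}onset_flow_{band}",
            f"{prefix}onset * ({onset_mult}) * {prefix}close_{band}",
            source=f"{prefix}close_{band}",
            sink=f"{prefix}raised_{band}",
        )
        g.add_flow(
            f"{prefix}esc_flow_{band}",
            f"{prefix}esc * ({onset_mult}) * {prefix}raised_{band}",
            source=f"{prefix}raised_{band}",
            sink=f"{prefix}high_{band}",
        )
        g.add_flow(
            f"{prefix}recr_flow_{band}",
            f"{prefix}rec_raised * {prefix}raised_{band}",
            source=f"{prefix}raised_{band}",
            sink=f"{prefix}close_{band}",
        )
        g.add_flow(
            f"{prefix}rech_flow_{band}",
            f"{prefix}rec_high * {prefix}high_{band}",
            source=f"{prefix}high_{band}",
            sink=f"{prefix}raised_{band}",
        )
    for state in SDQ_STATES:
        g.add_flow(
            f"{prefix}aging_{state}",
            f"{prefix}{state}_a0_4 / 5",
            source=f"{prefix}{state}_a0_4",
            sink=f"{prefix}{state}_a5_11",
        )
    g.add_aux(
        f"{prefix}pop_a5_11",
        " + ".join(f"{prefix}{s}_a5_11" for s in SDQ_STATES),
        unit="persons",
    )
    g.add_aux(f"{prefix}share_high", f"{prefix}high_a5_11 / max({prefix}pop_a5_11, 1e-9)")

    if exit_to is not None:
        low_stock, mod_stock = exit_to
        q_base = params.entry_mod_fraction
        q_high = min(1.0, q_base * params.carry_multiplier)
        g.add_param(f"{prefix}entry_mod_frac", q_base)
        g.add_param(f"{prefix}entry_mod_frac_high", q_high)
        for state in SDQ_STATES:
            q = f"{prefix}entry_mod_frac_high" if state == "high" else f"{prefix}entry_mod_frac"
            g.add_flow(
                f"{prefix}exit_{state}_to_low",
                f"(1 - {q}) * {prefix}{state}_a5_11 / 7",
                source=f"{prefix}{state}_a5_11",
                sink=low_stock,
            )
            g.add_flow(
                f"{prefix}exit_{state}_to_mod",
                f"{q} * {prefix}{state}_a5_11 / 7",
                source=f"{prefix}{state}_a5_11",
                sink=mod_stock,
            )
    return g


@dataclass
class SubstanceParams:
    """Substance-misuse prevalence dynamics and its escalation link.

    Twelve-month substance-misuse disorder is a prevalence stock (a
    fraction of the 12-24 population) whose level multiplies the
    moderate-to-disorder escalation rate through a power elasticity; the
    onset rate carries its own historical trend index so that sensitivity
    analysis can shift it.  Closed treatment episodes are tracked as a
    reporting flow only.
    """

    initial_prevalence: float = 0.115
    onset: float = 0.045  # /yr, acts on the non-misusing fraction
    remission: float = 0.30  # /yr
    trend_rate: float = 0.005  # baseline annual change in onset (fraction/yr)
    escalation_elasticity: float = 0.6
    treatment_rate: float = 0.15  # closed treatment episodes per prevalent person-year

    def __post_init__(self) -> None:
        if not 0 < self.initial_prevalence < 1:
            raise ValueError("initial prevalence must be in (0, 1)")
        if min(self.onset, self.remission, self.treatment_rate) < 0:
            raise ValueError("substance rates must be >= 0")


def build_substance_misuse(
    params: SubstanceParams, pool: str = "1", prefix: str = "sub_"
) -> ModelGraph:
    """Substance-misuse fragment exporting the escalation multiplier ``sub_esc_mult``."""
    g = ModelGraph()
    g.add_stock(prefix + "prev", params.initial_prevalence, unit="fraction")
    g.add_stock(prefix + "trend", 1.0, unit="index")
    g.add_param(prefix + "onset", params.onset, unit="1/yr")
    g.add_param(prefix + "remit", params.remission, unit="1/yr")
    g.add_param(prefix + "trend_rate", params.trend_rate, unit="1/yr")
    g.add_param(prefix + "shift", 0.0)
    g.add_param(prefix + "esc_elast", params.escalation_elasticity)
    g.add_param(prefix + "base_prev", params.initial_prevalence)
    g.add_param(prefix + "treat_rate", params.treatment_rate, unit="1/yr")
    g.add_flow(
        prefix + "onset_flow",
        f"{prefix}onset * {prefix}trend * (1 - {prefix}prev)",
        sink=prefix + "prev",
    )
    g.add_flow(
        prefix + "remit_flow",
        f"{prefix}remit * {prefix}prev",
        source=prefix + "prev",
    )
    g.add_flow(
        prefix + "trend_drift",
        f"{prefix}trend_rate * (1 + {prefix}shift) * {prefix}trend",
        sink=prefix + "trend",
    )
    g.add_aux(prefix + "esc_mult", f"pow({prefix}prev / {prefix}base_prev, {prefix}esc_elast)")
    g.add_aux(prefix + "closed_episodes", f"{prefix}treat_rate * {prefix}prev * ({pool})", unit="episodes/yr")
    return g


def event_flow(
    counts: dict[str, float],
    hazards: EventHazards,
    population: float | None = None,
) -> dict[str, float]:
    """Deterministic event flows from state headcounts and hazards.

    Returns annual flows (events/yr) for each configured event type and,
    when ``population`` is given, the matching rates per 100,000 per year.
    """
    if any(v < 0 for v in counts.values()):
        raise ValueError("state counts must be >= 0")
    out: dict[str, float] = {}
    for name, h in (("selfharm", hazards.selfharm), ("suicide", hazards.suicide), ("ed", hazards.ed)):
        if not h:
            continue
        events = sum(h.get(state, 0.0) * counts.get(state, 0.0) for state in DISTRESS_STATES)
        out[name] = events
        if population is not None:
            if population <= 0:
                raise ValueError("population must be positive for per-100k rates")
            out[name + "_per_100k"] = 1e5 * events / population
    return out
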