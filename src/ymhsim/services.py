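"""Capacity-constrained care pathways across eight service channels.

Each treatment channel (general practice, specialized mental-health care,
psychiatric and non-specialized hospital care, community services,
headspace, online services) carries three stocks: a capacity stock
(service episodes deliverable per year, growing at its own historical
trend), a waiting stock, and an in-treatment stock.  Help-seeking demand is
routed to channels by state-specific referral fractions; treatment starts
are capped at capacity (``min`` rule); excess demand accumulates as
waiting, which leaks through disengagement (a hazard on the waiting stock)
and spills partly into emergency-department presentations.  Treatment
completes after a mean duration and splits into recovery — governed by
per-episode, per-state recovery probabilities — and a non-recovered return
to the pool, a slice of which is referred onward to other channels.  The
emergency department is an event channel: presentations are instantaneous
events, so it has no queue.

Intervention effects follow the standard epidemiological conventions: odds
ratios act on per-episode probabilities through the odds transform, hazard
ratios act multiplicatively on rates, and a partial-uptake intervention
applies the uptake-weighted mix ``(1-u)*baseline + u*modified``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .engine import ModelGraph, Override

__all__ = [
    "CHANNEL_NAMES",
    "TREATMENT_CHANNELS",
    "ServiceChannel",
    "InterventionEffect",
    "build_service_pathways",
    "capacity_growth",
    "apply_odds_ratio",
    "apply_hazard_ratio",
    "apply_tech_enabled_care",
    "scale_inbound_referrals",
    "double_online_referrals",
]

CHANNEL_NAMES = (
    "gp",
    "specialized",
    "ed",
    "psychiatric_hospital",
    "nonspecialized_hospital",
    "community",
    "headspace",
    "online",
)
#: channels that deliver scheduled episodes of care (everything but the ED)
TREATMENT_CHANNELS = tuple(c for c in CHANNEL_NAMES if c != "ed")


@dataclass
class ServiceChannel:
    """One care modality: capacity dynamics, throughput, and effect parameters."""

    name: str
    capacity: float  # episodes/yr deliverable at model start
    growth_long: float = 0.0  # capacity trend up to the recent era (fraction/yr)
    growth_recent: float = 0.0  # recent 3-4 yr trend, projected forward (fraction/yr)
    recent_from: float = 2021.0
    duration_weeks: float = 8.0
    p_recovery_mod: float = 0.0  # per-episode recovery probability, no-disorder state
    p_recovery_dis: float = 0.0  # per-episode recovery probability, with-disorder state
    disengagement: float = 0.5  # hazard on the waiting stock (/yr)
    referrals_out: dict[str, float] = field(default_factory=dict)
    sessions_per_episode: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {self.name!r}")
        if self.capacity < 0:
            raise ValueError("capacity must be >= 0")
        if self.duration_weeks <= 0:
            raise ValueError("treatment duration must be positive")
        for p in (self.p_recovery_mod, self.p_recovery_dis):
            if not 0 <= p <= 1:
                raise ValueError("recovery probabilities must be in [0, 1]")
        if self.disengagement < 0:
            raise ValueError("disengagement hazard must be >= 0")
        if sum(self.referrals_out.values()) > 1 + 1e-12:
            raise ValueError(f"referral fractions out of {self.name!r} sum above 1")

    @property
    def duration_years(self) -> float:
        return self.duration_weeks / 52.0


@dataclass
class InterventionEffect:
    """Technology-enabled integrated care + online-service effect parameters."""

    uptake: float = 0.5
    or_recovery: float = 1.177
    hr_disengagement: float = 0.72
    or_referral_specialized: float = 1.266
    or_online_recovery_mod: float = 0.4  # online vs specialized, no disorder
    or_online_recovery_dis: float = 0.18507  # online vs specialized, with disorder
    online_duration_weeks: float = 6.0

    def __post_init__(self) -> None:
        if not 0 <= self.uptake <= 1:
            raise ValueError("uptake must be in [0, 1]")
        for r in (
            self.or_recovery,
            self.hr_disengagement,
            self.or_referral_specialized,
            self.or_online_recovery_mod,
            self.or_online_recovery_dis,
        ):
            if r <= 0:
                raise ValueError("effect ratios must be > 0")
        if self.online_duration_weeks <= 0:
            raise ValueError("online treatment duration must be positive")


def apply_odds_ratio(p: float, odds_ratio: float) -> float:
    """Apply an odds ratio to a probability: ``OR p / (1 - p + OR p)``."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be > 0")
    if p == 1.0:
        return 1.0
    return odds_ratio * p / (1.0 - p + odds_ratio * p)


def apply_hazard_ratio(rate: float, hazard_ratio: float) -> float:
    """Apply a hazard ratio multiplicatively to a rate."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be > 0")
    return rate * hazard_ratio


def capacity_growth(channel: ServiceChannel, t: float, capacity: float, multiplier: float = 1.0) -> float:
    """Instantaneous capacity change dC/dt = g(t) * m * C for one channel."""
    g = channel.growth_recent if t >= channel.recent_from else channel.growth_long
    return g * multiplier * capacity


def build_service_pathways(
    channels: list[ServiceChannel],
    helpseek_mod: float,
    helpseek_dis: float,
    routing: dict[str, dict[str, float]],
    mod_pool: str = "dx_mod_total",
    dis_pool: str = "dx_dis_total",
    start_time: float = 2011.0,
    tau_start: float = 1.0 / 6.0,
    prefix: str = "svc_",
) -> ModelGraph:
    """Wire the service subsystem as a composable fragment.

    ``routing`` maps state ("mod"/"dis") to per-channel referral fractions of
    the help-seeking flow; each state's fractions must sum to at most 1 (the
    remainder seeks no care).  ``mod_pool`` / ``dis_pool`` name the series
    holding the distressed headcounts that generate demand.
    """
    by_name = {c.name: c for c in channels}
    missing = set(CHANNEL_NAMES) - set(by_name)
    if missing:
        raise ValueError(f"missing channels: {sorted(missing)}")
    for state in ("mod", "dis"):
        total = sum(routing.get(state, {}).values())
        if total > 1 + 1e-12:
            raise ValueError(f"routing fractions for state {state!r} sum above 1")

    g = ModelGraph()
    g.add_param(prefix + "hs_mod", helpseek_mod, unit="1/yr")
    g.add_param(prefix + "hs_dis", helpseek_dis, unit="1/yr")
    g.add_param(prefix + "tau_start", tau_start, unit="yr")
    g.add_aux(prefix + "seek_mod", f"{prefix}hs_mod * {mod_pool}", unit="persons/yr")
    g.add_aux(prefix + "seek_dis", f"{prefix}hs_dis * {dis_pool}", unit="persons/yr")

    for name in TREATMENT_CHANNELS:
        ch = by_name[name]
        g.add_stock(prefix + "cap_" + name, ch.capacity, unit="episodes/yr")
        g.add_stock(prefix + "wait_" + name, 0.0, unit="persons")
        g.add_stock(prefix + "treat_" + name, 0.0, unit="persons")
        g.add_lookup(
            prefix + "growth_" + name,
            [
                (start_time - 1.0, ch.growth_long),
                (ch.recent_from - 0.25, ch.growth_long),
                (ch.recent_from, ch.growth_recent),
            ],
        )
        g.add_param(prefix + "gmult_" + name, 1.0)
        g.add_flow(
            prefix + "cap_growth_" + name,
            f"{prefix}growth_{name}(t) * {prefix}gmult_{name} * {prefix}cap_{name}",
            sink=prefix + "cap_" + name,
        )
        g.add_param(prefix + "route_mod_" + name, routing.get("mod", {}).get(name, 0.0))
        g.add_param(prefix + "route_dis_" + name, routing.get("dis", {}).get(name, 0.0))
        g.add_param(prefix + "diseng_" + name, ch.disengagement, unit="1/yr")
        g.add_param(prefix + "dur_" + name, ch.duration_years, unit="yr")
        g.add_param(prefix + "prec_mod_" + name, ch.p_recovery_mod)
        g.add_param(prefix + "prec_dis_" + name, ch.p_recovery_dis)
        g.add_param(prefix + "sess_" + name, ch.sessions_per_episode)

    for name in TREATMENT_CHANNELS:
        ch = by_name[name]
        direct_mod = f"{prefix}route_mod_{name} * {prefix}seek_mod"
        direct_dis = f"{prefix}route_dis_{name} * {prefix}seek_dis"
        referred = []
        for src in TREATMENT_CHANNELS:
            frac = by_name[src].referrals_out.get(name, 0.0)
            if frac > 0:
                g.add_param(f"{prefix}refer_{src}_{name}", frac)
                referred.append(f"{prefix}refer_{src}_{name} * {prefix}return_{src}")
        demand = " + ".join([direct_mod, direct_dis] + referred)
        g.add_aux(prefix + "demand_" + name, demand, unit="persons/yr")
        g.add_aux(
            prefix + "dismix_" + name,
            f"({direct_dis}) / max(({direct_mod}) + ({direct_dis}), 1e-9)",
        )
        # rate auxiliaries (referencable by other expressions) feed thin flows
        g.add_aux(
            prefix + "starts_" + name,
            f"min({prefix}wait_{name} / {prefix}tau_start, {prefix}cap_{name})",
            unit="persons/yr",
        )
        # disengagement acts on the backlog beyond the frictional queue
        # (people in the short mobilisation delay do not abandon care)
        g.add_aux(
            prefix + "backlog_" + name,
            f"max(0, {prefix}wait_{name} - {prefix}demand_{name} * {prefix}tau_start)",
            unit="persons",
        )
        g.add_aux(
            prefix + "drop_" + name,
            f"{prefix}diseng_{name} * {prefix}backlog_{name}",
            unit="persons/yr",
        )
        g.add_aux(
            prefix + "comp_" + name,
            f"{prefix}treat_{name} / {prefix}dur_{name}",
            unit="persons/yr",
        )
        g.add_flow(
            prefix + "referrals_" + name,
            f"{prefix}demand_{name}",
            sink=prefix + "wait_" + name,
        )
        g.add_flow(
            prefix + "starts_flow_" + name,
            f"{prefix}starts_{name}",
            source=prefix + "wait_" + name,
            sink=prefix + "treat_" + name,
        )
        g.add_flow(
            prefix + "drop_flow_" + name,
            f"{prefix}drop_{name}",
            source=prefix + "wait_" + name,
        )
        g.add_flow(
            prefix + "comp_flow_" + name,
            f"{prefix}comp_{name}",
            source=prefix + "treat_" + name,
        )
        g.add_aux(
            prefix + "rec_dis_" + name,
            f"{prefix}comp_{name} * {prefix}dismix_{name} * {prefix}prec_dis_{name}",
            unit="persons/yr",
        )
        g.add_aux(
            prefix + "rec_mod_" + name,
            f"{prefix}comp_{name} * (1 - {prefix}dismix_{name}) * {prefix}prec_mod_{name}",
            unit="persons/yr",
        )
        g.add_aux(
            prefix + "return_" + name,
            f"{prefix}comp_{name} - {prefix}rec_dis_{name} - {prefix}rec_mod_{name}",
            unit="persons/yr",
        )
        g.add_aux(
            prefix + "sessions_" + name,
            f"{prefix}comp_{name} * {prefix}sess_{name}",
            unit="sessions/yr",
        )

    for agg, per in (
        ("rec_dis_total", "rec_dis_"),
        ("rec_mod_total", "rec_mod_"),
        ("drop_total", "drop_"),
        ("wait_total", "wait_"),
    ):
        g.add_aux(prefix + agg, " + ".join(prefix + per + c for c in TREATMENT_CHANNELS))
    g.add_aux(
        prefix + "starts_consult",
        " + ".join(f"{prefix}starts_{c}" for c in TREATMENT_CHANNELS if c != "online"),
        unit="persons/yr",
    )
    g.add_aux(prefix + "starts_digital", f"{prefix}starts_online", unit="persons/yr")
    return g


def apply_tech_enabled_care(
    effect: InterventionEffect,
    channels: list[ServiceChannel],
    routing: dict[str, dict[str, float]],
    start_time: float = 2025.0,
    prefix: str = "svc_",
) -> list[Override]:
    """Overrides implementing technology-enabled integrated care coordination.

    Every affected parameter becomes the uptake-weighted mix
    ``(1-u)*baseline + u*modified``: the recovery odds ratio acts on the
    per-episode recovery probabilities of every treatment channel, the
    disengagement hazard ratio on every waiting-stock disengagement hazard,
    and the referral odds ratio on the with-disorder routing fraction to
    specialized care.
    """
    u = effect.uptake
    ov: list[Override] = []
    for ch in channels:
        if ch.name not in TREATMENT_CHANNELS:
            continue
        for state, p in (("mod", ch.p_recovery_mod), ("dis", ch.p_recovery_dis)):
            mixed = (1 - u) * p + u * apply_odds_ratio(p, effect.or_recovery)
            ov.append(Override(f"{prefix}prec_{state}_{ch.name}", "set", mixed, start_time))
        mixed_dis = ch.disengagement * (1 - u + u * effect.hr_disengagement)
        ov.append(Override(f"{prefix}diseng_{ch.name}", "set", mixed_dis, start_time))
    base_ref = routing.get("dis", {}).get("specialized", 0.0)
    mixed_ref = (1 - u) * base_ref + u * apply_odds_ratio(base_ref, effect.or_referral_specialized)
    ov.append(Override(f"{prefix}route_dis_specialized", "set", mixed_ref, start_time))
    return ov


def scale_inbound_referrals(
    fractions: dict[str, float], channel: str = "online", factor: float = 2.0
) -> dict[str, float]:
    """Multiply one channel's inbound fraction, renormalising only on overflow.

    If the scaled vector sums above 1, the excess is removed proportionally
    from the non-target fractions; otherwise the remainder (no care) simply
    shrinks.
    """
    new = dict(fractions)
    new[channel] = fractions.get(channel, 0.0) * factor
    total = sum(new.values())
    if total > 1.0 + 1e-12:
        others = total - new[channel]
        excess = total - 1.0
        if others <= 0 or new[channel] >= 1.0:
            # target alone saturates the vector
            return {k: (min(1.0, v) if k == channel else 0.0) for k, v in new.items()}
        shrink = (others - excess) / others
        for k in new:
            if k != channel:
                new[k] *= shrink
    return new


def double_online_referrals(
    channels: list[ServiceChannel],
    routing: dict[str, dict[str, float]],
    start_time: float = 2025.0,
    factor: float = 2.0,
    prefix: str = "svc_",
) -> list[Override]:
    """Scale every referral fraction into the online channel from ``start_time``.

    Applies to the state-specific help-seeking routing and to cross-channel
    onward referrals; per-source vectors are renormalised only if they would
    exceed 1 (the excess taken proportionally from non-online fractions).
    """
    ov: list[Override] = []
    for state in ("mod", "dis"):
        scaled = scale_inbound_referrals(routing.get(state, {}), "online", factor)
        for ch_name, value in scaled.items():
            if value != routing.get(state, {}).get(ch_name, 0.0):
                ov.append(Override(f"{prefix}route_{state}_{ch_name}", "set", value, start_time))
    for ch in channels:
        if ch.referrals_out.get("online", 0.0) > 0:
            scaled = scale_inbound_referrals(ch.referrals_out, "online", factor)
            for dest, value in scaled.items():
                if value != ch.referrals_out.get(dest, 0.0):
                    ov.append(Override(f"{prefix}refer_{ch.name}_{dest}", "set", value, start_time))
    return ov
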