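"""Assembly of the full youth mental health system model.

Composes the demographic chain, the SDQ and distress state chains, the
substance-misuse and social-determinant drivers, and the capacity-
constrained service pathways into one simulable :class:`ModelGraph`.
Youth age bands are state-resolved — each band total is the sum of its
SDQ or distress state stocks — so demographic flows (births, migration,
mortality, aging) act proportionally on every state stock and band totals
follow exactly the balanced aging chain of :mod:`ymhsim.demography`.

Key reported series (all defined as auxiliaries, one column each in a
trajectory CSV):

``total_population``, ``pop_15_24``, ``share_under_25``
    demographic surface.
``prevalence_disorder_15_24``, ``disorder_15_24``
    12-month disorder prevalence / headcount, ages 15-24.
``coverage_consult_15_24``, ``coverage_digital_15_24``
    annual service coverage: treatment starts in face-to-face channels and
    in the online channel, as a fraction of the 15-24 population.
``ed_presentations_15_24``, ``ed_rate_quarterly_12_24``
    MH-related emergency department presentations (events/yr, and the
    quarterly rate per 100,000 aged 12-24).
``selfharm_hosp_15_24``, ``selfharm_rate_quarterly_15_24``
    self-harm hospitalisations (events/yr; quarterly rate per 100,000
    aged 15-24).
``sessions_psychological``, ``sessions_headspace``, ``sessions_early_psychosis``
    annual service-session volumes mapped to the published statistics.
"""

from __future__ import annotations

from .defaults import default_config
from .demography import (
    DETERMINANT_NAMES,
    DeterminantIndex,
    balanced_population_params,
    build_determinant_index,
)
from .distress import (
    DISTRESS_STATES,
    SDQ_STATES,
    DistressRates,
    SDQParams,
    SubstanceParams,
    build_distress_chain,
    build_sdq_chain,
    build_substance_misuse,
)
from .engine import ModelGraph, SimulationSettings, compose
from .services import (
    InterventionEffect,
    ServiceChannel,
    apply_odds_ratio,
    build_service_pathways,
)

__all__ = [
    "build_model",
    "default_config",
    "settings_from_config",
    "channels_from_config",
    "intervention_from_config",
]

_SDQ_BANDS = ("a0_4", "a5_11")
_DX_BANDS = ("a12_14", "a15_17", "a18_24")

# memo for the migration-rate refinement (keyed on the population block)
_POP_CACHE: dict = {}


def settings_from_config(config: dict) -> SimulationSettings:
    sim = config["simulation"]
    return SimulationSettings(sim["start"], sim["stop"], sim["dt"])


def intervention_from_config(config: dict) -> InterventionEffect:
    iv = config["intervention"]
    return InterventionEffect(
        uptake=iv["uptake"],
        or_recovery=iv["or_recovery"],
        hr_disengagement=iv["hr_disengagement"],
        or_referral_specialized=iv["or_referral_specialized"],
        or_online_recovery_mod=iv["or_online_recovery_mod"],
        or_online_recovery_dis=iv["or_online_recovery_dis"],
        online_duration_weeks=iv["online_duration_weeks"],
    )


def channels_from_config(config: dict, effect: InterventionEffect | None = None) -> list[ServiceChannel]:
    """Service channels, with online recovery derived from specialized care.

    The online channel's per-episode recovery probabilities are the
    specialized-care probabilities transformed by the online recovery odds
    ratios (without / with disorder), and its mean duration is the online
    treatment duration — both owned by the intervention-effect block so
    sensitivity analysis can vary them.
    """
    if effect is None:
        effect = intervention_from_config(config)
    spec = config["services"]["channels"]["specialized"]
    out: list[ServiceChannel] = []
    for name, c in config["services"]["channels"].items():
        if name == "ed":
            out.append(ServiceChannel("ed", 0.0))
            continue
        kwargs = dict(
            name=name,
            capacity=c["capacity"],
            growth_long=c.get("growth_long", 0.0),
            growth_recent=c.get("growth_recent", 0.0),
            duration_weeks=c.get("duration_weeks", 8.0),
            p_recovery_mod=c.get("p_recovery_mod", 0.0),
            p_recovery_dis=c.get("p_recovery_dis", 0.0),
            disengagement=c.get("disengagement", 0.5),
            referrals_out=dict(c.get("referrals_out", {})),
            sessions_per_episode=c.get("sessions_per_episode", 1.0),
        )
        if name == "online":
            kwargs["p_recovery_mod"] = apply_odds_ratio(
                spec["p_recovery_mod"], effect.or_online_recovery_mod
            )
            kwargs["p_recovery_dis"] = apply_odds_ratio(
                spec["p_recovery_dis"], effect.or_online_recovery_dis
            )
            kwargs["duration_weeks"] = effect.online_duration_weeks
        out.append(ServiceChannel(**kwargs))
    return out


def _population_rates(config: dict):
    pop = config["population"]
    key = (
        pop["total"],
        tuple(sorted(pop["shares"].items())),
        pop["youth_growth"],
        pop["overall_growth"],
        tuple(sorted(pop["mortality"].items())),
        config["simulation"]["start"],
    )
    if key not in _POP_CACHE:
        _POP_CACHE[key] = balanced_population_params(
            pop["total"],
            pop["shares"],
            youth_growth=pop["youth_growth"],
            overall_growth=pop["overall_growth"],
            mortality=pop["mortality"],
            start_time=config["simulation"]["start"],
        )
    return _POP_CACHE[key]


def build_model(config: dict | None = None) -> ModelGraph:
    """Assemble the full model graph from a configuration dictionary."""
    if config is None:
        config = default_config()
    pop_params = _population_rates(config)
    counts = pop_params.initial
    start = config["simulation"]["start"]

    g = ModelGraph()
    g.add_stock("pop_a25p", counts["a25p"], unit="persons")
    g.add_param("birth_rate", pop_params.birth_rate, unit="1/yr")
    for band in counts:
        g.add_param(f"mig_{band}", pop_params.net_migration.get(band, 0.0), unit="1/yr")
        g.add_param(f"mort_{band}", pop_params.mortality.get(band, 0.0), unit="1/yr")

    # --- early-life (SDQ) chain with its onset trend index ---------------
    sdq_cfg = config["sdq"]
    sh = sdq_cfg["initial_shares"]
    sdq_init = {
        band: (
            counts[band] * sh["close"],
            counts[band] * sh["raised"],
            counts[band] * sh["high"],
        )
        for band in _SDQ_BANDS
    }
    g.add_stock("sdq_trend", 1.0, unit="index")
    g.add_param("sdq_trend_rate", sdq_cfg["trend_rate"], unit="1/yr")
    g.add_param("sdq_trend_shift", 0.0)
    g.add_flow(
        "sdq_trend_drift",
        "sdq_trend_rate * (1 + sdq_trend_shift) * sdq_trend",
        sink="sdq_trend",
    )
    sdq = build_sdq_chain(
        SDQParams(
            onset=sdq_cfg["onset"],
            escalation=sdq_cfg["escalation"],
            recovery_raised=sdq_cfg["recovery_raised"],
            recovery_high=sdq_cfg["recovery_high"],
            entry_mod_fraction=sdq_cfg["entry_mod_fraction"],
            carry_multiplier=sdq_cfg["carry_multiplier"],
        ),
        sdq_init,
        onset_mult="sdq_trend",
        exit_to=("dx_low_a12_14", "dx_mod_a12_14"),
    )
    g.merge(sdq)
    g.add_flow("births", "birth_rate * pop_a25p", sink="sdq_close_a0_4", unit="persons/yr")
    for band in _SDQ_BANDS:
        for state in SDQ_STATES:
            stock = f"sdq_{state}_{band}"
            g.add_flow(f"mig_{state}_{band}", f"mig_{band} * {stock}", sink=stock)
            g.add_flow(f"deaths_{state}_{band}", f"mort_{band} * {stock}", source=stock)

    # --- social determinants and substance misuse -------------------------
    det_frags = []
    for name in DETERMINANT_NAMES:
        d = config["determinants"][name]
        det_frags.append(
            build_determinant_index(
                DeterminantIndex(
                    name,
                    change_rate=d["rate"],
                    elasticity_onset=d["elasticity_onset"],
                    elasticity_recovery=d["elasticity_recovery"],
                )
            )
        )
    for frag in det_frags:
        g.merge(frag)
    g.add_aux("det_onset_mult", " * ".join(f"det_mult_onset_{n}" for n in DETERMINANT_NAMES))
    g.add_aux("det_rec_mult", " * ".join(f"det_mult_rec_{n}" for n in DETERMINANT_NAMES))

    sub_cfg = config["substance"]
    g.merge(
        build_substance_misuse(
            SubstanceParams(
                initial_prevalence=sub_cfg["initial_prevalence"],
                onset=sub_cfg["onset"],
                remission=sub_cfg["remission"],
                trend_rate=sub_cfg["trend_rate"],
                escalation_elasticity=sub_cfg["escalation_elasticity"],
                treatment_rate=sub_cfg["treatment_rate"],
            ),
            pool="pop_12_24",
        )
    )

    # --- distress chain ----------------------------------------------------
    dx_cfg = config["distress"]
    dx_init = {
        band: tuple(counts[band] * s for s in dx_cfg["initial_shares"][band])
        for band in _DX_BANDS
    }
    dx = build_distress_chain(
        DistressRates(
            onset=dict(dx_cfg["onset"]),
            escalation=dict(dx_cfg["escalation"]),
            recovery_mod=dict(dx_cfg["recovery_mod"]),
            recovery_dis=dict(dx_cfg["recovery_dis"]),
        ),
        dx_init,
        onset_mult="det_onset_mult",
        escalation_mult="sub_esc_mult",
        recovery_mult="det_rec_mult",
        service_recovery_mod="svc_rec_mod_total",
        service_recovery_dis="svc_rec_dis_total",
        age_out_to="pop_a25p",
    )
    g.merge(dx)
    for band in _DX_BANDS:
        for state in DISTRESS_STATES:
            stock = f"dx_{state}_{band}"
            g.add_flow(f"mig_{state}_{band}", f"mig_{band} * {stock}", sink=stock)
            g.add_flow(f"deaths_{state}_{band}", f"mort_{band} * {stock}", source=stock)
    g.add_flow("migration_a25p", "mig_a25p * pop_a25p", sink="pop_a25p")
    g.add_flow("deaths_a25p", "mort_a25p * pop_a25p", source="pop_a25p")

    # --- service pathways --------------------------------------------------
    svc_cfg = config["services"]
    svc = build_service_pathways(
        channels_from_config(config),
        helpseek_mod=svc_cfg["helpseek"]["mod"],
        helpseek_dis=svc_cfg["helpseek"]["dis"],
        routing=svc_cfg["routing"],
        mod_pool="dx_mod_total",
        dis_pool="dx_dis_total",
        start_time=start,
        tau_start=svc_cfg.get("tau_start", 1.0 / 6.0),
    )
    g.merge(svc)

    # --- demographic / outcome reporting -----------------------------------
    g.add_aux("pop_a0_4", " + ".join(f"sdq_{s}_a0_4" for s in SDQ_STATES), unit="persons")
    g.add_aux("pop_12_24", " + ".join(f"dx_pop_{b}" for b in _DX_BANDS), unit="persons")
    g.add_aux("pop_15_24", "dx_pop_a15_17 + dx_pop_a18_24", unit="persons")
    g.add_aux(
        "total_population",
        "pop_a0_4 + sdq_pop_a5_11 + pop_12_24 + pop_a25p",
        unit="persons",
    )
    g.add_aux("share_under_25", "(total_population - pop_a25p) / total_population")
    g.add_aux("disorder_15_24", "dx_dis_a15_17 + dx_dis_a18_24", unit="persons")
    g.add_aux("prevalence_disorder_15_24", "disorder_15_24 / max(pop_15_24, 1e-9)")
    g.add_aux("distressed_15_24", "dx_mod_a15_17 + dx_mod_a18_24 + disorder_15_24", unit="persons")
    g.add_aux("distressed_12_24", "distressed_15_24 + dx_mod_a12_14 + dx_dis_a12_14", unit="persons")

    ev = config["events"]
    for kind in ("ed", "selfharm", "suicide"):
        for state in DISTRESS_STATES:
            g.add_param(f"ev_{kind}_{state}", ev[kind][state], unit="1/yr")
    g.add_param("ev_ed_spill", ev["ed_spill_fraction"])

    def hazard_sum(kind: str, bands) -> str:
        return " + ".join(
            f"ev_{kind}_{state} * dx_{state}_{band}" for band in bands for state in DISTRESS_STATES
        )

    g.add_aux("ed_hazard_15_24", hazard_sum("ed", ("a15_17", "a18_24")), unit="events/yr")
    g.add_aux("ed_hazard_12_24", hazard_sum("ed", _DX_BANDS), unit="events/yr")
    g.add_aux("ed_spill", "ev_ed_spill * svc_drop_total", unit="events/yr")
    g.add_aux(
        "ed_presentations_15_24",
        "ed_hazard_15_24 + ed_spill * distressed_15_24 / max(distressed_12_24, 1e-9)",
        unit="events/yr",
    )
    g.add_aux("ed_presentations_12_24", "ed_hazard_12_24 + ed_spill", unit="events/yr")
    g.add_aux(
        "ed_rate_quarterly_12_24",
        "ed_presentations_12_24 / max(pop_12_24, 1e-9) * 25000",
        unit="per 100k per quarter",
    )
    g.add_aux("selfharm_hosp_15_24", hazard_sum("selfharm", ("a15_17", "a18_24")), unit="events/yr")
    g.add_aux(
        "selfharm_rate_quarterly_15_24",
        "selfharm_hosp_15_24 / max(pop_15_24, 1e-9) * 25000",
        unit="per 100k per quarter",
    )
    g.add_aux("suicide_deaths_15_24", hazard_sum("suicide", ("a15_17", "a18_24")), unit="events/yr")

    g.add_aux("coverage_consult_15_24", "svc_starts_consult / max(pop_15_24, 1e-9)", unit="1/yr")
    g.add_aux("coverage_digital_15_24", "svc_starts_digital / max(pop_15_24, 1e-9)", unit="1/yr")
    g.add_param("phn_psych_youth_share", svc_cfg["phn_psych_youth_share"])
    g.add_aux(
        "sessions_psychological",
        "svc_sessions_specialized / max(phn_psych_youth_share, 1e-9)",
        unit="sessions/yr",
    )
    g.add_aux("sessions_headspace", "svc_sessions_headspace", unit="sessions/yr")
    g.add_aux("sessions_early_psychosis", "svc_sessions_community", unit="sessions/yr")
    return g
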