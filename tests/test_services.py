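"""Service pathways: min-rule throughput, effect-size transforms, referrals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from ymhsim.engine import ModelGraph, SimulationSettings, compose, simulate, validate_graph
from ymhsim.services import (
    CHANNEL_NAMES,
    TREATMENT_CHANNELS,
    InterventionEffect,
    ServiceChannel,
    apply_hazard_ratio,
    apply_odds_ratio,
    apply_tech_enabled_care,
    build_service_pathways,
    capacity_growth,
    double_online_referrals,
    scale_inbound_referrals,
)


def default_channels(**caps):
    out = []
    for name in CHANNEL_NAMES:
        out.append(
            ServiceChannel(
                name,
                capacity=caps.get(name, 1000.0),
                growth_long=0.04,
                growth_recent=0.01,
                duration_weeks=8.0,
                p_recovery_mod=0.4,
                p_recovery_dis=0.3,
                disengagement=0.8,
            )
        )
    return out


ROUTING = {
    "mod": {"gp": 0.3, "online": 0.1, "headspace": 0.05},
    "dis": {"gp": 0.3, "specialized": 0.2, "online": 0.05, "headspace": 0.05, "community": 0.05},
}


def pathway_model(channels, mod_pool=5000.0, dis_pool=3000.0, routing=ROUTING):
    pools = ModelGraph()
    pools.add_param("mod_pool", mod_pool)
    pools.add_param("dis_pool", dis_pool)
    svc = build_service_pathways(
        channels, 0.5, 0.9, routing, mod_pool="mod_pool", dis_pool="dis_pool", start_time=0.0
    )
    return compose(pools, svc)


class TestOddsHazardTransforms:
    @pytest.mark.parametrize(
        "p,oratio,expected",
        [
            (0.5, 1.0, 0.5),
            (0.5, 1.177, 1.177 / 2.177),
            (0.2, 0.18507, 0.0462675 / 1.0462675),
            (1.0, 5.0, 1.0),
            (0.0, 3.0, 0.0),
        ],
    )
    def test_odds_ratio_examples(self, p, oratio, expected):
        assert apply_odds_ratio(p, oratio) == pytest.approx(expected, abs=1e-12)

    @hyp_settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(0.001, 0.999), oratio=st.floats(0.01, 100.0))
    def test_odds_ratio_inverts_and_is_monotone(self, p, oratio):
        forward = apply_odds_ratio(p, oratio)
        assert apply_odds_ratio(forward, 1.0 / oratio) == pytest.approx(p, abs=1e-12)
        if oratio > 1:
            assert forward > p
        elif oratio < 1:
            assert forward < p

    def test_hazard_ratio_is_multiplicative(self):
        assert apply_hazard_ratio(0.5, 0.72) == pytest.approx(0.36)
        assert apply_hazard_ratio(0.5, 1.0) == 0.5
        assert apply_hazard_ratio(0.0, 7.0) == 0.0


class TestCapacityGrowth:
    def test_zero_growth_keeps_capacity_constant(self):
        ch = ServiceChannel("gp", 100.0, growth_long=0.0, growth_recent=0.0)
        assert capacity_growth(ch, 2030.0, 100.0, multiplier=2.0) == 0.0

    def test_doubled_growth_compounds_to_closed_form(self):
        """g=0.05 with multiplier 2 for one year: C ratio = e^0.10."""
        channels = default_channels()
        for ch in channels:
            ch.growth_long = 0.05
            ch.growth_recent = 0.05
            ch.recent_from = 0.0
        g = pathway_model(channels)
        from ymhsim.engine import Override

        traj = simulate(
            g,
            SimulationSettings(0.0, 1.0, 1.0 / 512),
            [Override("svc_gmult_gp", "set", 2.0, 0.0)],
        )
        ratio = traj["svc_cap_gp"][-1] / traj["svc_cap_gp"][0]
        assert ratio == pytest.approx(math.exp(0.10), rel=5e-4)

    def test_multiplier_before_start_leaves_capacity_on_baseline(self):
        from ymhsim.engine import Override

        g = pathway_model(default_channels())
        s = SimulationSettings(0.0, 10.0, 1.0 / 12)
        base = simulate(g, s)
        scen = simulate(g, s, [Override("svc_gmult_gp", "set", 2.0, 5.0)])
        pre = base.time < 5.0
        assert np.array_equal(base["svc_cap_gp"][pre], scen["svc_cap_gp"][pre])


class TestPathways:
    def test_fragment_valid_and_requires_all_channels(self):
        g = pathway_model(default_channels())
        assert validate_graph(g) == []
        with pytest.raises(ValueError, match="missing channels"):
            build_service_pathways(default_channels()[:3], 0.5, 0.9, ROUTING)

    def test_ample_capacity_keeps_waiting_empty(self):
        g = pathway_model(default_channels(gp=1e7, specialized=1e7, online=1e7,
                                           headspace=1e7, community=1e7,
                                           psychiatric_hospital=1e7,
                                           nonspecialized_hospital=1e7))
        traj = simulate(g, SimulationSettings(0.0, 5.0, 1.0 / 12))
        # waiting never accumulates beyond one start delay's worth of inflow
        demand = traj["svc_demand_gp"]
        assert np.all(traj["svc_wait_gp"] <= demand.max() / 6.0 + 1e-9)
        # no backlog beyond the frictional queue: throughput tracks demand
        assert traj["svc_backlog_gp"][-1] == pytest.approx(0.0, abs=1e-6)
        assert traj["svc_starts_gp"][-1] == pytest.approx(demand[-1], rel=0.01)

    def test_overloaded_channel_throughput_equals_capacity_and_queue_grows(self):
        """demand D > capacity C: starts = C, waiting grows at ~D - C."""
        channels = default_channels(specialized=100.0)
        for ch in channels:
            ch.growth_long = ch.growth_recent = 0.0
            ch.disengagement = 0.0
        g = pathway_model(channels)
        traj = simulate(g, SimulationSettings(0.0, 3.0, 1.0 / 12))
        d = traj["svc_demand_specialized"][-1]
        assert d > 100.0
        assert traj["svc_starts_specialized"][-1] == pytest.approx(100.0)
        growth = np.diff(traj["svc_wait_specialized"]) / (1.0 / 12)
        assert growth[-1] == pytest.approx(d - 100.0, rel=0.05)

    def test_throughput_never_exceeds_capacity(self):
        g = pathway_model(default_channels(gp=500.0, specialized=50.0))
        traj = simulate(g, SimulationSettings(0.0, 10.0, 1.0 / 12))
        for c in TREATMENT_CHANNELS:
            assert np.all(traj[f"svc_starts_{c}"] <= traj[f"svc_cap_{c}"] + 1e-9)

    def test_pathway_stocks_balance_entries_and_exits(self):
        """referrals = starts + drops + d(wait)/dt at every step (discrete)."""
        g = pathway_model(default_channels(gp=800.0))
        traj = simulate(g, SimulationSettings(0.0, 5.0, 1.0 / 12))
        w = traj["svc_wait_gp"]
        inflow = traj["svc_referrals_gp"][:-1]
        outflow = traj["svc_starts_flow_gp"][:-1] + traj["svc_drop_flow_gp"][:-1]
        assert np.allclose(np.diff(w), (inflow - outflow) * traj.dt, atol=1e-9)

    def test_excess_routing_rejected(self):
        bad = {"mod": {"gp": 0.9, "online": 0.3}, "dis": {}}
        with pytest.raises(ValueError, match="sum above 1"):
            build_service_pathways(default_channels(), 0.5, 0.9, bad)


class TestTechEnabledCare:
    def test_zero_uptake_is_identity(self):
        ov = apply_tech_enabled_care(
            InterventionEffect(uptake=0.0), default_channels(), ROUTING, start_time=5.0
        )
        g = pathway_model(default_channels())
        s = SimulationSettings(0.0, 10.0, 1.0 / 12)
        assert simulate(g, s).equals(simulate(g, s, ov))

    def test_full_uptake_scales_disengagement_by_hazard_ratio(self):
        ov = apply_tech_enabled_care(
            InterventionEffect(uptake=1.0), default_channels(), ROUTING
        )
        vals = {o.parameter: o.value for o in ov}
        assert vals["svc_diseng_gp"] == pytest.approx(0.8 * 0.72)

    def test_half_uptake_mixes_hazard_ratio(self):
        """u=0.5 with HR 0.72 gives an effective rate of 0.86 r."""
        ov = apply_tech_enabled_care(
            InterventionEffect(uptake=0.5), default_channels(), ROUTING
        )
        vals = {o.parameter: o.value for o in ov}
        assert vals["svc_diseng_specialized"] == pytest.approx(0.8 * 0.86)

    def test_recovery_probability_gets_odds_mix(self):
        ov = apply_tech_enabled_care(
            InterventionEffect(uptake=1.0), default_channels(), ROUTING
        )
        vals = {o.parameter: o.value for o in ov}
        assert vals["svc_prec_mod_gp"] == pytest.approx(apply_odds_ratio(0.4, 1.177))


class TestOnlineReferralDoubling:
    def test_zero_fraction_stays_zero(self):
        assert scale_inbound_referrals({"online": 0.0, "gp": 0.5}, "online")["online"] == 0.0

    def test_headroom_case_needs_no_renormalisation(self):
        new = scale_inbound_referrals({"online": 0.1, "gp": 0.5}, "online")
        assert new == {"online": 0.2, "gp": 0.5}

    def test_overflow_is_taken_proportionally_from_others(self):
        new = scale_inbound_referrals({"online": 0.4, "gp": 0.3, "specialized": 0.3}, "online")
        assert new["online"] == pytest.approx(0.8)
        assert sum(new.values()) == pytest.approx(1.0)
        assert new["gp"] == pytest.approx(new["specialized"])

    def test_overrides_leave_prestart_identical(self):
        channels = default_channels()
        ov = double_online_referrals(channels, ROUTING, start_time=5.0)
        g = pathway_model(channels)
        s = SimulationSettings(0.0, 10.0, 1.0 / 12)
        base, scen = simulate(g, s), simulate(g, s, ov)
        pre = base.time < 5.0
        assert np.array_equal(base["svc_wait_online"][pre], scen["svc_wait_online"][pre])
        assert scen["svc_demand_online"][-1] > base["svc_demand_online"][-1]


def test_channel_invariants():
    with pytest.raises(ValueError, match="unknown channel"):
        ServiceChannel("telehealth", 10.0)
    with pytest.raises(ValueError, match="probabilities"):
        ServiceChannel("gp", 10.0, p_recovery_mod=1.2)
    with pytest.raises(ValueError, match="sum above 1"):
        ServiceChannel("gp", 10.0, referrals_out={"online": 0.7, "specialized": 0.5})
    with pytest.raises(ValueError, match="uptake"):
        InterventionEffect(uptake=1.5)
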