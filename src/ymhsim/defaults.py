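"""Default parameterization of the Western-Sydney-style youth mental health model.

These values describe a fast-growing, culturally diverse urban catchment of
~1.1 million people (2021) with a third of residents under 25: 12-month
disorder prevalence of 31% among older youth, 19.3% annual mental-health
consultation coverage and 7.9% digital-service access (2023), quarterly
MH-related ED presentations near 500/100k (ages 12-24) and quarterly
self-harm hospitalisations near 119/100k (ages 15-24), with youth service
capacity whose recent (3-4 year) growth trend sits well below the trend
observed since the early 2010s.

Demographic anchors (population size, age shares, growth rates) are
regional statistics; behavioural and service parameters are calibration
outputs — values estimated by constrained optimisation so that the
simulated baseline reproduces the service-use and outcome surface above —
not published constants.  They are exposed here, and in the serialized
config, precisely so users can replace them.
"""

from __future__ import annotations

import copy
import math

__all__ = ["default_config"]


_DEFAULT: dict = {
    "simulation": {
        "start": 2011.0,
        "stop": 2035.0,
        "dt": 1.0 / 12.0,
    },
    "population": {
        # 2011 totals back-cast from 1.1e6 (2021): under-25s at the 1.42 %/yr
        # youth trend, 25+ at the balancing adult rate
        "total": 946600.0,
        "shares": {
            "a0_4": 0.06922,
            "a5_11": 0.09711,
            "a12_14": 0.04132,
            "a15_17": 0.04132,
            "a18_24": 0.09711,
            "a25p": 0.65392,
        },
        "youth_growth": 0.0142,  # expected CAGR, ages 15-24
        "overall_growth": 0.0175,
        "mortality": {
            "a0_4": 0.0008,
            "a5_11": 0.0001,
            "a12_14": 0.0002,
            "a15_17": 0.0003,
            "a18_24": 0.0004,
            "a25p": 0.0120,
        },
    },
    "determinants": {
        # reduced-form trend indices: baseline change rate (/yr) and
        # elasticities on distress onset and recovery
        "education": {"rate": 0.002, "elasticity_onset": -0.10, "elasticity_recovery": 0.0},
        "labour_neet": {"rate": 0.004, "elasticity_onset": 0.25, "elasticity_recovery": 0.0},
        "homelessness": {"rate": 0.010, "elasticity_onset": 0.05, "elasticity_recovery": 0.0},
        "justice": {"rate": -0.010, "elasticity_onset": 0.05, "elasticity_recovery": 0.0},
        "social_cohesion": {"rate": -0.008, "elasticity_onset": -0.80, "elasticity_recovery": 0.30},
        "family_violence": {"rate": 0.005, "elasticity_onset": 0.15, "elasticity_recovery": 0.0},
    },
    "sdq": {
        "onset": 0.050,  # close-to-average -> slightly raised, /yr
        "escalation": 0.120,  # slightly raised -> high/very-high, /yr
        "recovery_raised": 0.250,
        "recovery_high": 0.200,
        "entry_mod_fraction": 0.12,  # age-12 entrants starting distressed
        "carry_multiplier": 2.0,  # extra entry risk for high/very-high SDQ
        "trend_rate": 0.010,  # historical drift of early-life-exposure onset
        "initial_shares": {"close": 0.84, "raised": 0.09, "high": 0.07},
    },
    "substance": {
        "initial_prevalence": 0.115,
        "onset": 0.045,
        "remission": 0.30,
        "trend_rate": 0.005,
        "escalation_elasticity": 0.6,
        "treatment_rate": 0.15,
    },
    "distress": {
        # initial state shares (low, mod, dis) per band at 2011
        "initial_shares": {
            "a12_14": [0.72, 0.17, 0.11],
            "a15_17": [0.54, 0.18, 0.28],
            "a18_24": [0.50, 0.18, 0.32],
        },
        "onset": {"a12_14": 0.236125, "a15_17": 0.439319, "a18_24": 0.599997},
        "escalation": {"a12_14": 0.35, "a15_17": 0.858629, "a18_24": 0.252985},
        "recovery_mod": {"a12_14": 0.55, "a15_17": 0.50, "a18_24": 0.50},
        "recovery_dis": {"a12_14": 0.14, "a15_17": 0.0201076, "a18_24": 0.0202244},
    },
    "events": {
        # per-person-year hazards by distress state
        "ed": {"low": 0.004, "mod": 0.0297584, "dis": 0.0297584},
        "selfharm": {"low": 0.0019, "mod": 0.0054932, "dis": 0.00822201},
        "suicide": {"low": 2e-5, "mod": 8e-5, "dis": 2.5e-4},
        "ed_spill_fraction": 0.0108899,  # share of waiting-list disengagements presenting to ED
    },
    "services": {
        "helpseek": {"mod": 0.300574, "dis": 1.93604},  # /yr, of the distressed pools
        "tau_start": 1.0 / 6.0,  # waiting-to-treatment mobilisation delay (yr)
        "routing": {
            "mod": {"gp": 0.0817159, "online": 0.080076, "headspace": 0.0100454, "community": 0.004, "specialized": 0.03},
            "dis": {
                "gp": 0.4499,
                "specialized": 0.268116,
                "online": 0.103617,
                "headspace": 0.0859708,
                "community": 0.012,
                "psychiatric_hospital": 0.012,
                "nonspecialized_hospital": 0.015,
            },
        },
        "channels": {
            "gp": {
                "capacity": 7933.15,
                "growth_long": 0.040,
                "growth_recent": 0.0448958,
                "duration_weeks": 6.0,
                "p_recovery_mod": 0.499841,
                "p_recovery_dis": 0.349064,
                "disengagement": 1.0,
                "sessions_per_episode": 2.5,
                "referrals_out": {"specialized": 0.12, "online": 0.06},
            },
            "specialized": {
                "capacity": 4743.62,
                "growth_long": 0.055,
                "growth_recent": 0.067948,
                "duration_weeks": 14.0,
                "p_recovery_mod": 0.30281,
                "p_recovery_dis": 0.608872,
                "disengagement": 0.9,
                "sessions_per_episode": 6.97803,
                "referrals_out": {"online": 0.03},
            },
            "community": {
                "capacity": 389.918,
                "growth_long": 0.035,
                "growth_recent": 0.0270347,
                "duration_weeks": 20.0,
                "p_recovery_mod": 0.50,
                "p_recovery_dis": 0.42,
                "disengagement": 0.8,
                "sessions_per_episode": 38.440,
                "referrals_out": {},
            },
            "headspace": {
                "capacity": 1332.09,
                "growth_long": 0.060,
                "growth_recent": 0.0595107,
                "duration_weeks": 10.0,
                "p_recovery_mod": 0.50,
                "p_recovery_dis": 0.29676,
                "disengagement": 0.9,
                "sessions_per_episode": 4.213,
                "referrals_out": {"specialized": 0.08},
            },
            "psychiatric_hospital": {
                "capacity": 550.0,
                "growth_long": 0.020,
                "growth_recent": 0.000,
                "duration_weeks": 3.0,
                "p_recovery_mod": 0.45,
                "p_recovery_dis": 0.35,
                "disengagement": 0.5,
                "sessions_per_episode": 1.0,
                "referrals_out": {"specialized": 0.30, "community": 0.10},
            },
            "nonspecialized_hospital": {
                "capacity": 700.0,
                "growth_long": 0.020,
                "growth_recent": 0.000,
                "duration_weeks": 1.0,
                "p_recovery_mod": 0.20,
                "p_recovery_dis": 0.12,
                "disengagement": 0.5,
                "sessions_per_episode": 1.0,
                "referrals_out": {"specialized": 0.20},
            },
            "online": {
                "capacity": 5870.34,
                "growth_long": 0.100,
                "growth_recent": 0.00240922,
                "duration_weeks": 6.0,
                # recovery probabilities are derived from the specialized
                # channel through the online odds ratios in `intervention`
                "disengagement": 1.5,
                "sessions_per_episode": 3.0,
                "referrals_out": {},
            },
            "ed": {"capacity": 0.0},
        },
        # share of specialized youth sessions within the all-ages
        # PHN-funded psychological-session statistic
        "phn_psych_youth_share": 0.702651,
    },
    "intervention": {
        "uptake": 0.5,
        "or_recovery": 1.177,
        "hr_disengagement": 0.72,
        "or_referral_specialized": 1.266,
        "or_online_recovery_mod": 0.4,
        "or_online_recovery_dis": 0.18507,
        "online_duration_weeks": 6.0,
        "start": 2025.0,
    },
}


def default_config() -> dict:
    """A deep copy of the default model configuration."""
    return copy.deepcopy(_DEFAULT)
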