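# Full default configuration of the youth mental health system model.
# Structure mirrors ymhsim.default_config(); load with ymhsim.io.load_config
# or pass to the CLI via --config.
# Demographic anchors are regional statistics; behavioural and service
# parameters are calibration outputs (see docs/methods.md) and are meant
# to be replaced with better regional estimates where available.
# Sections: simulation (time axis), population (aging chain), determinants
# (reduced-form trend indices with elasticities on distress onset/recovery),
# sdq (early-life risk states, ages 0-11), substance (misuse prevalence and
# its escalation link), distress (K10 state chain, ages 12-24), events
# (per-state ED / self-harm / suicide hazards), services (help-seeking,
# routing fractions, and the eight care channels), intervention
# (technology-enabled care and online-service effect sizes).
determinants:
  education:
    elasticity_onset: -0.1
    elasticity_recovery: 0.0
    rate: 0.002
  family_violence:
    elasticity_onset: 0.15
    elasticity_recovery: 0.0
    rate: 0.005
  homelessness:
    elasticity_onset: 0.05
    elasticity_recovery: 0.0
    rate: 0.01
  justice:
    elasticity_onset: 0.05
    elasticity_recovery: 0.0
    rate: -0.01
  labour_neet:
    elasticity_onset: 0.25
    elasticity_recovery: 0.0
    rate: 0.004
  social_cohesion:
    elasticity_onset: -0.8
    elasticity_recovery: 0.3
    rate: -0.008
distress:
  escalation:
    a12_14: 0.35
    a15_17: 0.858629
    a18_24: 0.252985
  initial_shares:
    a12_14:
    - 0.72
    - 0.17
    - 0.11
    a15_17:
    - 0.54
    - 0.18
    - 0.28
    a18_24:
    - 0.5
    - 0.18
    - 0.32
  onset:
    a12_14: 0.236125
    a15_17: 0.439319
    a18_24: 0.599997
  recovery_dis:
    a12_14: 0.14
    a15_17: 0.0201076
    a18_24: 0.0202244
  recovery_mod:
    a12_14: 0.55
    a15_17: 0.5
    a18_24: 0.5
events:
  ed:
    dis: 0.0297584
    low: 0.004
    mod: 0.0297584
  ed_spill_fraction: 0.0108899
  selfharm:
    dis: 0.00822201
    low: 0.0019
    mod: 0.0054932
  suicide:
    dis: 0.00025
    low: 2.0e-05
    mod: 8.0e-05
intervention:
  hr_disengagement: 0.72
  online_duration_weeks: 6.0
  or_online_recovery_dis: 0.18507
  or_online_recovery_mod: 0.4
  or_recovery: 1.177
  or_referral_specialized: 1.266
  start: 2025.0
  uptake: 0.5
population:
  mortality:
    a0_4: 0.0008
    a12_14: 0.0002
    a15_17: 0.0003
    a18_24: 0.0004
    a25p: 0.012
    a5_11: 0.0001
  overall_growth: 0.0175
  shares:
    a0_4: 0.06922
    a12_14: 0.04132
    a15_17: 0.04132
    a18_24: 0.09711
    a25p: 0.65392
    a5_11: 0.09711
  total: 946600.0
  youth_growth: 0.0142
sdq:
  carry_multiplier: 2.0
  entry_mod_fraction: 0.12
  escalation: 0.12
  initial_shares:
    close: 0.84
    high: 0.07
    raised: 0.09
  onset: 0.05
  recovery_high: 0.2
  recovery_raised: 0.25
  trend_rate: 0.01
services:
  channels:
    community:
      capacity: 389.918
      disengagement: 0.8
      duration_weeks: 20.0
      growth_long: 0.035
      growth_recent: 0.0270347
      p_recovery_dis: 0.42
      p_recovery_mod: 0.5
      referrals_out: {}
      sessions_per_episode: 38.44
    ed:
      capacity: 0.0
    gp:
      capacity: 7933.15
      disengagement: 1.0
      duration_weeks: 6.0
      growth_long: 0.04
      growth_recent: 0.0448958
      p_recovery_dis: 0.349064
      p_recovery_mod: 0.499841
      referrals_out:
        online: 0.06
        specialized: 0.12
      sessions_per_episode: 2.5
    headspace:
      capacity: 1332.09
      disengagement: 0.9
      duration_weeks: 10.0
      growth_long: 0.06
      growth_recent: 0.0595107
      p_recovery_dis: 0.29676
      p_recovery_mod: 0.5
      referrals_out:
        specialized: 0.08
      sessions_per_episode: 4.213
    nonspecialized_hospital:
      capacity: 700.0
      disengagement: 0.5
      duration_weeks: 1.0
      growth_long: 0.02
      growth_recent: 0.0
      p_recovery_dis: 0.12
      p_recovery_mod: 0.2
      referrals_out:
        specialized: 0.2
      sessions_per_episode: 1.0
    online:
      capacity: 5870.34
      disengagement: 1.5
      duration_weeks: 6.0
      growth_long: 0.1
      growth_recent: 0.00240922
      referrals_out: {}
      sessions_per_episode: 3.0
    psychiatric_hospital:
      capacity: 550.0
      disengagement: 0.5
      duration_weeks: 3.0
      growth_long: 0.02
      growth_recent: 0.0
      p_recovery_dis: 0.35
      p_recovery_mod: 0.45
      referrals_out:
        community: 0.1
        specialized: 0.3
      sessions_per_episode: 1.0
    specialized:
      capacity: 4743.62
      disengagement: 0.9
      duration_weeks: 14.0
      growth_long: 0.055
      growth_recent: 0.067948
      p_recovery_dis: 0.608872
      p_recovery_mod: 0.30281
      referrals_out:
        online: 0.03
      sessions_per_episode: 6.97803
  helpseek:
    dis: 1.93604
    mod: 0.300574
  phn_psych_youth_share: 0.702651
  routing:
    dis:
      community: 0.012
      gp: 0.4499
      headspace: 0.0859708
      nonspecialized_hospital: 0.015
      online: 0.103617
      psychiatric_hospital: 0.012
      specialized: 0.268116
    mod:
      community: 0.004
      gp: 0.0817159
      headspace: 0.0100454
      online: 0.080076
      specialized: 0.03
  tau_start: 0.16666666666666666
simulation:
  dt: 0.08333333333333333
  start: 2011.0
  stop: 2035.0
substance:
  escalation_elasticity: 0.6
  initial_prevalence: 0.115
  onset: 0.045
  remission: 0.3
  treatment_rate: 0.15
  trend_rate: 0.005
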