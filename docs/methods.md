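# Methods

## The model in brief

`ymhsim` is a deterministic stock-flow (system dynamics) model of youth
mental health in a fast-growing urban catchment, built from five coupled
subsystems:

1. **Demography.** Six age bands (0-4, 5-11, 12-14, 15-17, 18-24, 25+)
   with first-order aging chains (aging outflow = stock / band width),
   births proportional to the 25+ population, proportional net migration
   per band, and per-band mortality. Migration rates are solved so the
   chain sits on a balanced growth path: the 15-24 population grows at
   1.42 %/yr (2025-2035) and the total at about 1.75 %/yr, the growth
   regime of the catchment the model describes. A secant refinement on
   the 15-24 migration rates pins the simulated CAGR because the birth
   pipeline makes the analytic balance only approximate.
2. **Early-life risk (SDQ).** Children aged 0-11 occupy
   close-to-average / slightly-raised / high-or-very-high
   Strengths-and-Difficulties states with onset, escalation and recovery
   flows; an onset trend index captures the historical drift of adverse
   early-life exposures. Children aging into the 12-14 band enter the
   distress chain; entrants start distressed with a base probability that
   is multiplied (capped at 1) for the high/very-high state — the
   carry-over of early-life risk.
3. **Psychological distress.** Ages 12-24 occupy low distress (K10
   10-15), moderate-to-very-high distress without a 12-month disorder,
   or moderate-to-very-high distress meeting 12-month disorder criteria.
   Onset is modulated by the social-determinant indices, escalation by
   substance-misuse prevalence, and recovery both by spontaneous
   remission and by service-attributable flows. Aging preserves distress
   state; the 18-24 band ages out into the 25+ stock.
4. **Social determinants and substance misuse.** Education, labour
   market/NEET, homelessness, justice contact, social cohesion, and
   family violence are reduced-form trend indices
   `dL/dt = r (1 + shift) L` exporting multipliers `L^elasticity` on
   distress onset and recovery. Substance misuse is a prevalence stock
   whose level (relative to baseline) multiplies escalation through a
   power elasticity. This reduced form is a deliberate boundary choice:
   the full internal structure of those subsystems is out of scope, and
   only their trend-level influence on distress dynamics is retained.
5. **Services.** Seven treatment channels (GP, specialized MH care,
   psychiatric and non-specialized hospital care, community services,
   headspace, online services) each carry a capacity stock (episodes/yr,
   growing at `g(t) * m(t) * C` with a long-era and a recent-era trend
   rate and a scenario multiplier), a waiting stock and an in-treatment
   stock. Help-seeking demand (state-specific rates on the distressed
   pools) is routed by state-specific fractions; treatment starts are
   `min(waiting / tau, capacity)`; the backlog beyond the frictional
   queue disengages at a hazard, and a fraction of disengagements
   presents to the ED. Completions (in-treatment / mean duration) split
   into recovery and non-recovered return using per-episode, per-state
   recovery probabilities; a slice of returns is referred onward to
   other channels. The ED is an event channel (no queue): presentations
   arise from state-dependent hazards plus the disengagement spillover.
   Self-harm hospitalisations and suicide deaths are state-dependent
   hazard flows (reporting only; they do not deplete stocks, a
   negligible approximation at these hazard levels).

Waiting and in-treatment stocks are bookkeeping subsets of the distress
stocks (people keep their distress state while queued or treated); the
pathway balance entries = exits + d(stocks)/dt holds exactly at every
step, but queue membership does not suppress further help-seeking, so
help-seeking rates are calibrated *net* rates.

### Effect-size semantics

Odds ratios act on per-episode probabilities through the odds transform
`p -> OR p / (1 - p + OR p)`; hazard ratios multiply rates; an
intervention with uptake `u` sets each affected parameter to the
uptake-weighted mix `(1-u)·baseline + u·modified`. Technology-enabled
integrated care applies a recovery odds ratio (1.177) to every channel's
per-episode recovery probabilities, a disengagement hazard ratio (0.72)
to every waiting-stock disengagement hazard, and a referral odds ratio
(1.266) to the with-disorder routing fraction into specialized care.
The online channel's per-episode recovery probabilities are derived from
the specialized-care ones via odds ratios 0.4 (no disorder) and
0.18507 = 0.4 x 0.462687 (with disorder, the primary-to-specialized
effect-size ratio), with a 6-week mean duration. "Doubling referrals to
online services" doubles every inbound routing fraction (help-seeking
and onward referral), renormalising a source vector only if it would
exceed 1 (excess removed proportionally from non-online fractions);
total help-seeking is unchanged.

"Degrowth" of specialized services is implemented as growth multiplier
-3 on the recent-era trend rate. The phrase "a 3-fold reduction in the
historic growth rate" combined with "negative growth" is ambiguous
(-3g, g/3 or -2g all fit the words); the multiplier is an exposed
scenario parameter (`DEGROWTH_MULTIPLIER`), so all readings are runnable.

## Numerical scheme

Explicit first-order (Euler) fixed-step integration, default dt = 1/12
yr on a decimal-calendar-year axis ("from 2025" = t >= 2025.0; "January
2028" = t >= 2028.0). Euler is the default of mainstream
system-dynamics tools and keeps runs bit-reproducible.
`refine_until_converged` halves dt until every watched series changes by
less than 0.5 % of its scale between refinements (error floor dt =
1/1024 yr); for the shipped model the outcome series certify convergence
at dt = 1/48 yr, so default-dt trajectories carry a discretisation error
of order 1 % of scale — well inside the calibration uncertainty. Convergence and oracle errors
are measured relative to series scale (max |err| / max |ref|): the
pointwise-relative error of a first-order method on a decaying
exponential grows like k^2 t dt / 2 and no fixed pointwise tolerance is
attainable for late, near-zero values.

Nonnegative stocks are protected by proportional outflow rescaling
within the step: if a step would cross zero, all outflows of that stock
are scaled by a common factor so it lands exactly at zero, keeping flow
budgets consistent (up to four sweeps resolve chained limits). Rate
expressions live in a small arithmetic language (+, -, *, /, ^, min,
max, pow, abs, piecewise-linear lookups with clamped ends, and the time
symbol t) so model graphs are fully serializable and auditable; `pow`
exists because determinant multipliers are `level^elasticity`.
Divisions by aggregate pools are guarded with `max(pool, 1e-9)`.
Parameter overrides are piecewise-constant in time, active on
[start, stop), applied in list order; an all-multipliers-equal-1
override set reproduces the unmodified run bit for bit.

## Calibration and the default parameterization

The printed regional surface — total population 1.1 M (2021) with 33.5 %
under 25, 12-month disorder prevalence 31 % (2023), 19.3 % annual
consultation coverage and 7.9 % digital access (2023), quarterly ED
presentations ~500/100k ages 12-24 and self-harm hospitalisations
119/100k ages 15-24 (early 2024), and annual session volumes (~83,000
PHN-funded psychological sessions all ages, ~10,400 headspace sessions
to ~2,234 clients, ~21,300 early-psychosis sessions) — is encoded in
`calibration.default_targets`. The loss is a weighted sum of squared
*relative* errors so counts, fractions and rates are commensurable;
it is invariant to target ordering. `calibrate` runs seeded
differential evolution over box bounds followed by a least-squares
polish.

The shipped default configuration is a calibration output, not a set of
published constants: demographic anchors are regional statistics, while
behavioural and service parameters (transition rates, hazards,
capacities, routing fractions, growth trends) were estimated by
constrained optimisation against that surface *and* against the
published scenario responses of the study system (for example, doubling
specialized-care capacity growth reducing cumulative disorder-years by
about 8 %, and all-services doubling by about 15 %). The second set of
constraints is what identifies quantities the surface alone cannot,
such as how binding each channel's capacity constraint is. Anyone with
better regional estimates — service throughput records, workforce
projections, linked administrative data — should replace these defaults;
every value is exposed in the config.

Mapping approximations worth knowing: the published prevalence is for
ages 16-24 and is matched to the model's 15-24 band; the published
session statistics are mapped as specialized-channel sessions divided
by a youth share (PHN psychological sessions are an all-ages figure),
headspace sessions directly, and early-psychosis sessions to the
community channel; consultation coverage counts treatment starts in
face-to-face channels over the 15-24 population.

## Sensitivity analysis

Latin hypercube sampling (n = 200 by default) with stratified
inverse-CDF draws — one draw per equal-probability stratum per
parameter, independently permuted (scipy's LatinHypercube engine
provides the stratified unit-cube sample). Lognormal parameters are
specified by log-scale (mu, sigma) with median e^mu equal to the
baseline effect size; uniform parameters by bounds (a point mass
lower == upper is allowed for degenerate designs). Implementation
uncertainties (uptake, effect sizes, online recovery/duration) redefine
the scenario's intervention block per sample; social-determinant shifts
perturb the world itself and therefore apply to both the baseline and
the scenario run of a sample, with reductions computed within-sample.
Failed (non-finite) runs are recorded, never silently dropped, and the
ensemble aborts above a 1 % failure fraction rather than imputing.
Uncertainty intervals are pointwise empirical percentile bands (50 % UI
= 25th-75th, 95 % UI = 2.5th-97.5th, linear interpolation between order
statistics); cumulative reductions are summarised as means with
2.5/97.5 percentile intervals.

## Synthetic data

`generate_synthetic_targets` simulates the model at known parameters
and applies mean-one multiplicative lognormal noise with a chosen
coefficient of variation to the target table. It emulates the
*aggregate* observation surface (a handful of statistics at a handful
of time points), not unit-record service data: passing recovery tests
demonstrate that the chosen rates are identifiable from that surface
under the model's own dynamics, and say nothing about structural
misspecification against real data. Noise-free recovery of three free
rates lands within a few percent; identifiability degrades as more
strongly confounded parameter sets are freed, which is why the shipped
recovery experiments use three well-separated rates (distress onset,
help-seeking, self-harm hazard).

## Problem sizes and defaults

Default runs integrate 2011-2035 at dt = 1/12 (288 steps, ~30 ms per
run), so a 200-sample ensemble of a scenario completes in well under a
minute; the recovery experiments restrict the horizon to the
calibration window (2011-2024). These sizes are the package defaults
chosen to keep the full analysis reproducible on a laptop; n = 200 is
the design size of the reported sensitivity analyses.

## Known limitations

- Ensemble means track the deterministic run closely: the model's
  response to the sampled implementation uncertainties is nearly linear,
  and capacity constraints cap the upside (a favourable draw cannot push
  a channel's throughput beyond its capacity).  A system whose response
  to the same uncertainty design is convex would show ensemble means
  sitting noticeably above its deterministic run; here the gap is small,
  so ensemble means should be read as centred on the default-parameter
  projection.
- Determinant uncertainty propagates weakly under the default
  elasticities and trend rates: the reduced-form social-determinant
  channel is the least constrained part of the parameterization, and the
  social-determinant sensitivity analysis consequently yields very tight
  uncertainty intervals.

- Aggregate, deterministic compartments: no individual heterogeneity,
  no stochastic event noise, first-order (exponential) aging rather
  than cohort-exact bookkeeping.
- Queue membership does not gate further help-seeking, and in-treatment
  people remain in their distress stocks; both are standard aggregate
  approximations whose bias is absorbed by calibration.
- The per-state ED/self-harm hazard ratios and the split between
  hazard-driven and disengagement-driven ED presentations are
  calibration outputs constrained only by the ordering invariant
  (disorder >= moderate >= low) and the published rate levels.
- Suicide deaths are reported as a flow but are not a calibrated or
  accepted output surface.
- The degrowth multiplier reading (-3g) is one of three defensible
  interpretations of the published phrase (exposed as a parameter).
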