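"""Latin hypercube sampling, ensembles, and uncertainty-interval bands."""

import math

import numpy as np
import pandas as pd
import pytest

from ymhsim.scenarios import INDICATORS, OutcomeSummary
from ymhsim.sensitivity import (
    EnsembleResult,
    ParameterDistribution,
    latin_hypercube,
    run_ensemble,
    builtin_designs,
    ui_bands,
)


class TestDesigns:
    def test_lognormal_locations_are_log_of_baseline_effects(self):
        """Every lognormal mu equals ln(baseline effect size)."""
        digital = {d.name: d for d in builtin_designs()["digital_implementation"]}
        assert digital["or_recovery"].mu == pytest.approx(math.log(1.177), abs=5e-4)
        assert digital["hr_disengagement"].mu == pytest.approx(math.log(0.72), abs=5e-4)
        assert digital["or_referral_specialized"].mu == pytest.approx(math.log(1.266), abs=5e-4)
        assert digital["or_online_recovery_dis"].mu == pytest.approx(math.log(0.18507), abs=5e-4)
        assert digital["or_online_recovery_mod"].mu == pytest.approx(math.log(0.4), abs=5e-4)

    def test_online_with_disorder_is_scaled_no_disorder_effect(self):
        """0.4 x 0.462687 = 0.18507: the with-disorder odds ratio derivation."""
        assert 0.4 * 0.462687 == pytest.approx(0.18507, abs=5e-6)

    def test_uniform_bounds_and_baselines(self):
        digital = {d.name: d for d in builtin_designs()["digital_implementation"]}
        assert (digital["tech_care_uptake"].lower, digital["tech_care_uptake"].upper) == (0.30, 0.70)
        dur = digital["online_duration_weeks"]
        assert (dur.lower, dur.upper) == (2.0, 10.0)
        assert dur.lower < 6.0 < dur.upper  # baseline duration inside the band
        det = {d.name: d for d in builtin_designs()["social_determinants"]}
        assert (det["social_cohesion_shift"].lower, det["social_cohesion_shift"].upper) == (-0.14, 0.07)
        assert (det["substance_onset_shift"].lower, det["substance_onset_shift"].upper) == (-0.10, 0.0)
        assert (det["sdq_onset_shift"].lower, det["sdq_onset_shift"].upper) == (-0.20, 0.16)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown distribution"):
            ParameterDistribution("x", "triangular", lower=0, upper=1)


class TestLatinHypercube:
    def stratum_counts(self, draws, dist, n):
        """How many draws fall in each of the n equal-probability strata."""
        if dist.kind == "uniform":
            u = (draws - dist.lower) / (dist.upper - dist.lower)
        else:
            from scipy import stats

            u = stats.lognorm.cdf(draws, s=dist.sigma, scale=math.exp(dist.mu))
        return np.bincount(np.clip((u * n).astype(int), 0, n - 1), minlength=n)

    @pytest.mark.parametrize("n", [4, 200])
    def test_marginal_stratification(self, n):
        dists = builtin_designs()["digital_implementation"]
        design = latin_hypercube(n, dists, seed=3)
        for dist in dists:
            counts = self.stratum_counts(design.samples[dist.name].to_numpy(), dist, n)
            assert np.all(counts == 1), f"{dist.name} not stratified at n={n}"

    def test_lognormal_sample_median_is_exp_mu(self):
        dist = ParameterDistribution("or", "lognormal", mu=0.16324, sigma=0.24061)
        design = latin_hypercube(10_000, [dist], seed=7)
        med = float(design.samples["or"].median())
        assert med == pytest.approx(1.177, rel=0.01)

    def test_same_seed_identical_matrix(self):
        dists = builtin_designs()["social_determinants"]
        a = latin_hypercube(50, dists, seed=11)
        b = latin_hypercube(50, dists, seed=11)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        c = latin_hypercube(50, dists, seed=12)
        assert not a.samples.equals(c.samples)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            latin_hypercube(1, builtin_designs()["social_determinants"], seed=0)


def point_mass_design(config, n=4):
    """A degenerate design fixing every implementation parameter at baseline."""
    iv = config["intervention"]
    dists = [
        ParameterDistribution("tech_care_uptake", "uniform", lower=iv["uptake"],
                              upper=iv["uptake"], target="intervention.uptake"),
        ParameterDistribution("online_duration_weeks", "uniform",
                              lower=iv["online_duration_weeks"],
                              upper=iv["online_duration_weeks"],
                              target="intervention.online_duration_weeks"),
    ]
    return latin_hypercube(n, dists, seed=0)


class TestEnsembles:
    def test_degenerate_design_reproduces_the_default_run(self, base_config, base_model, base_settings, baseline_trajectory):
        from ymhsim.engine import simulate
        from ymhsim.scenarios import builtin_scenarios, compare

        ens = run_ensemble("digital", point_mass_design(base_config), base_config)
        expected = compare(
            baseline_trajectory,
            simulate(base_model, base_settings,
                     builtin_scenarios(base_config)["digital"].overrides),
            "digital",
        )
        for s in ens.summaries:
            for k in INDICATORS:
                assert s.reduction_pct[k] == pytest.approx(expected.reduction_pct[k], abs=1e-9)

    def test_ensemble_size_and_failure_bookkeeping(self, base_config):
        dists = builtin_designs()["social_determinants"]
        design = latin_hypercube(25, dists, seed=5)
        ens = run_ensemble("double_specialized", design, base_config)
        assert len(ens.summaries) == 25
        assert ens.failed == []
        assert ens.series["prevalence_disorder_15_24"].shape[0] == 25

    def test_seeded_determinism_of_bands(self, base_config):
        dists = builtin_designs()["social_determinants"]
        bands = []
        for _ in range(2):
            design = latin_hypercube(20, dists, seed=9)
            ens = run_ensemble("double_specialized", design, base_config)
            bands.append(ui_bands(ens))
        for k in INDICATORS:
            assert bands[0].reduction_mean[k] == bands[1].reduction_mean[k]
        for name in bands[0].bands:
            pd.testing.assert_frame_equal(bands[0].bands[name], bands[1].bands[name])


def synthetic_ensemble(values: np.ndarray) -> EnsembleResult:
    """An EnsembleResult whose outcomes are externally supplied pseudo-draws."""
    n = len(values)
    time = np.linspace(2025, 2035, 5)
    series = {"prevalence_disorder_15_24": np.tile(values[:, None], (1, 5))}
    summaries = [
        OutcomeSummary(
            "synthetic", (2025.0, 2035.0),
            {k: 100.0 for k in INDICATORS},
            {k: 100.0 - v for k in INDICATORS},
            {k: float(v) for k in INDICATORS},
        )
        for v in values
    ]
    return EnsembleResult("synthetic", n, time, series, summaries)


class TestBands:
    def test_identical_runs_give_zero_width_bands(self):
        ens = synthetic_ensemble(np.full(40, 7.5))
        bands = ui_bands(ens)
        frame = bands.bands["prevalence_disorder_15_24"]
        assert np.all(frame["p2_5"].to_numpy() == frame["p97_5"].to_numpy())
        assert bands.reduction_mean["cum_years_disorder"] == pytest.approx(7.5)
        assert bands.reduction_ui95["cum_years_disorder"] == (7.5, 7.5)

    def test_standard_normal_pseudo_outcomes_recover_the_normal_quantiles(self):
        rng = np.random.default_rng(1234)
        ens = synthetic_ensemble(rng.standard_normal(10_000))
        bands = ui_bands(ens)
        lo, hi = bands.reduction_ui95["cum_years_disorder"]
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_band_nesting_and_median_containment(self):
        rng = np.random.default_rng(7)
        ens = synthetic_ensemble(rng.exponential(2.0, size=500))
        frame = ui_bands(ens).bands["prevalence_disorder_15_24"]
        assert np.all(frame["p2_5"] <= frame["p25"])
        assert np.all(frame["p25"] <= frame["median"])
        assert np.all(frame["median"] <= frame["p75"])
        assert np.all(frame["p75"] <= frame["p97_5"])

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            ui_bands(synthetic_ensemble(np.arange(10.0)))
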