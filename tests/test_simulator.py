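"""Scheduler, Monte-Carlo replication, and the verification experiments."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nitocra.simulator import (SimulationConfig, replicate_seed,
                               run_development_test, run_monte_carlo,
                               run_reproduction_test, run_simulation)

warnings.simplefilter("ignore")  # clamp/extrapolation warnings in bulk runs


@pytest.fixture(scope="module")
def small_config():
    return SimulationConfig(temperature_C=19.34, n_initial_nauplii=72, days=35,
                            mode="direct_temperature", master_seed=42)


class TestDeterminism:
    def test_identical_seeds_reproduce_bitwise(self, small_config):
        a = run_simulation(small_config)
        b = run_simulation(small_config)
        assert a.abundance.equals(b.abundance)
        assert a.events.equals(b.events)
        assert a.naupliar_durations == b.naupliar_durations

    def test_monte_carlo_reproducible(self, small_config):
        cfg = SimulationConfig(temperature_C=19.34, n_initial_nauplii=20, days=10,
                               mode="direct_temperature", replicates=5, master_seed=7)
        s1, s2 = run_monte_carlo(cfg), run_monte_carlo(cfg)
        for stage in s1.mean:
            assert np.array_equal(s1.mean[stage], s2.mean[stage])
            assert np.array_equal(s1.upper[stage], s2.upper[stage])

    def test_replicates_reproducible_in_isolation(self):
        cfg = SimulationConfig(temperature_C=19.34, n_initial_nauplii=20, days=10,
                               mode="direct_temperature", replicates=3, master_seed=9)
        summary = run_monte_carlo(cfg, keep_replicates=True)
        r = 2
        seed = int(replicate_seed(cfg.master_seed, r).generate_state(1)[0] % (2**31))
        rerun = run_simulation(cfg, seed=seed)
        assert rerun.abundance.equals(summary.replicate_results[r].abundance)


class TestConservationAndStages:
    def test_closed_run_conserves_individuals(self, small_config):
        result = run_simulation(small_config)
        totals = result.abundance[["nauplius", "copepodite", "adult", "dead"]].sum(axis=1)
        assert (totals == 72).all()

    def test_stage_sequence_is_irreversible(self, small_config):
        result = run_simulation(small_config)
        events = result.events
        for ind_id, group in events.groupby("id"):
            order = [e for e in group.sort_values("day")["event"]
                     if e in ("molt_to_copepodite", "maturation")]
            assert order in ([], ["molt_to_copepodite"],
                             ["molt_to_copepodite", "maturation"])

    def test_mean_durations_match_rates(self):
        """Direct-mode realized durations recover the reciprocal rates:
        6.44 d naupliar and 10.12 d copepodite at the 20 C setup's measured
        temperature."""
        cfg = SimulationConfig(temperature_C=19.34, n_initial_nauplii=4000,
                               days=35, mode="direct_temperature", master_seed=3)
        result = run_simulation(cfg)
        assert np.mean(result.naupliar_durations) == pytest.approx(6.44, abs=0.1)
        assert np.mean(result.copepodite_durations) == pytest.approx(10.12, abs=0.15)


class TestMonteCarloSummary:
    def test_band_ordering_and_median_inside(self):
        cfg = SimulationConfig(temperature_C=14.86, n_initial_nauplii=72, days=20,
                               mode="direct_temperature", replicates=50, master_seed=1)
        s = run_monte_carlo(cfg)
        for stage in s.mean:
            assert (s.lower[stage] <= s.upper[stage] + 1e-12).all()
            assert (s.lower[stage] <= s.median[stage] + 1e-12).all()
            assert (s.median[stage] <= s.upper[stage] + 1e-12).all()

    def test_relative_band_width_shrinks_with_population_size(self):
        """Binomial scaling: the widest relative stage-count band narrows
        as the cohort grows."""
        widths = {}
        for n in (18, 288):
            cfg = SimulationConfig(temperature_C=19.34, n_initial_nauplii=n,
                                   days=20, mode="direct_temperature",
                                   replicates=200, master_seed=5)
            s = run_monte_carlo(cfg)
            widths[n] = max(np.max(s.upper[stage] - s.lower[stage]) / n
                            for stage in ("nauplius", "copepodite"))
        assert widths[288] < widths[18]

    def test_requires_at_least_two_replicates(self):
        cfg = SimulationConfig(temperature_C=20.0, replicates=1)
        with pytest.raises(ValueError, match="replicates >= 2"):
            run_monte_carlo(cfg)


class TestDevelopmentTest:
    def test_unknown_setup_rejected(self):
        with pytest.raises(ValueError, match="unknown setup"):
            run_development_test("30C")

    def test_20C_setup_mostly_survives_to_adulthood(self):
        s = run_development_test("20C", replicates=100, master_seed=11)
        assert s.mean["adult"][-1] >= 0.90 * 72

    def test_zero_food_blocks_copepodite_emergence(self):
        """Starved cohorts never reach the copepodite stage: the naupliar
        development rate collapses to its intercept while starvation
        mortality removes the cohort."""
        s = run_development_test("food-0", replicates=100, master_seed=11,
                                 keep_replicates=True)
        runs_with_copepodites = sum(
            r.abundance["copepodite"].max() > 0 for r in s.replicate_results)
        assert runs_with_copepodites == 0

    def test_monotone_food_stress_response(self):
        """Lower rations mean more deaths, fewer adults and slower naupliar
        development across the six food setups."""
        deaths, adults, durations = [], [], []
        for name in ("1.25e4", "2.5e4", "5e4", "1.25e5", "2.5e5", "5e5"):
            s = run_development_test(f"food-{name}", replicates=60, master_seed=13,
                                     keep_replicates=True)
            deaths.append(s.mean["dead"][-1])
            adults.append(s.mean["adult"][-1])
            pooled = [d for r in s.replicate_results for d in r.naupliar_durations]
            durations.append(np.mean(pooled))
        assert all(b < a for a, b in zip(deaths, deaths[1:]))
        assert all(b > a for a, b in zip(adults, adults[1:]))
        assert all(b < a for a, b in zip(durations, durations[1:]))


class TestReproductionTest:
    def test_simulated_means_near_theoretical(self):
        rt = run_reproduction_test("20C", master_seed=21)
        se = np.std(rt.periods, ddof=1) / np.sqrt(len(rt.periods))
        assert abs(np.mean(rt.periods) - rt.theoretical_period) < 4 * se
        se_b = np.std(rt.clutch_sizes, ddof=1) / np.sqrt(len(rt.clutch_sizes))
        assert abs(np.mean(rt.clutch_sizes) - rt.theoretical_brood_size) < 4 * se_b

    def test_summary_reports_both_aggregations(self):
        rt = run_reproduction_test("25C", n_females=10, master_seed=2)
        table = rt.summary()
        assert set(table["quantity"]) == {
            "brood size (per female)", "brood-to-brood period (per female)",
            "brood size (per clutch)", "brood-to-brood period (per clutch)"}

    def test_food_setup_uses_isolated_female_vessel(self):
        rt = run_reproduction_test("food-2.5e4", n_females=5, master_seed=2)
        assert rt.theoretical_brood_size < 24.0  # food-limited clutches

    def test_unknown_setup_rejected(self):
        with pytest.raises(ValueError, match="unknown setup"):
            run_reproduction_test("12C")


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"days": 0}, {"replicates": 0}, {"mode": "indirect"},
        {"n_initial_nauplii": -1}, {"food_cells_per_mL": -5.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(temperature_C=20.0, **kwargs)
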