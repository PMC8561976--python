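import math

import numpy as np
import pytest

from islandcoal import (
    GeneratorConfig,
    STUDY_PRESETS,
    exact_iicr,
    make_log_grid,
    random_scenario,
    read_psmc,
    scale_psmc,
    validate_scenario,
)
from islandcoal.fit import FitConfig, fit_scenario
from islandcoal.scenario import TimeGrid, evaluate_curve
from islandcoal.synth import benchmark_scenario, make_psmc_fixture, noisy_target


class TestRandomScenario:
    def test_deterministic_per_seed(self):
        cfg = GeneratorConfig(seed=1)
        assert random_scenario(cfg) == random_scenario(cfg)
        assert random_scenario(cfg) != random_scenario(cfg, seed=2)

    def test_thousand_draws_all_valid(self):
        cfg = GeneratorConfig()
        for seed in range(1000):
            assert validate_scenario(random_scenario(cfg, seed=seed)) == []

    def test_fixed_component_count(self):
        cfg = GeneratorConfig(c_range=(1, 1))
        for seed in range(10):
            assert len(random_scenario(cfg, seed=seed).migration_rates) == 1

    def test_ranges_respected(self):
        cfg = GeneratorConfig(n_range=(5, 10), M_range=(1.0, 2.0), c_range=(2, 3))
        for seed in range(20):
            s = random_scenario(cfg, seed=seed)
            assert 5 <= s.n_islands <= 10
            assert all(1.0 <= m <= 2.0 for m in s.migration_rates)


class TestBenchmarkScenario:
    @pytest.mark.parametrize("c", [2, 3])
    def test_contrast_constraints(self, c):
        for seed in range(10):
            s = benchmark_scenario(seed, c)
            ms = np.asarray(s.migration_rates)
            assert np.all(np.maximum(ms[:-1], ms[1:]) / np.minimum(ms[:-1], ms[1:]) >= 2.0)
            ts = np.asarray(s.change_times)
            if ts.size > 1:
                assert np.all(ts[1:] / ts[:-1] >= 4.0)


class TestStudyPresets:
    def test_published_counts_and_times(self):
        mur = STUDY_PRESETS["murinus"]
        rav = STUDY_PRESETS["ravelobensis"]
        assert mur.n_islands == 84 and rav.n_islands == 61
        assert len(mur.change_times_kyr) == 5 and len(rav.change_times_kyr) == 5
        scen = mur.scenario()
        assert len(scen.migration_rates) == 6
        assert validate_scenario(scen) == []


class TestNoisyTarget:
    def test_none_mode_is_exact(self, two_component):
        cfg = GeneratorConfig(noise_mode="none", seed=0)
        grid = make_log_grid(0.01, 10.0, 32)
        t = noisy_target(two_component, cfg, grid=grid, time_unit="coalescent")
        e = exact_iicr(two_component, grid)
        assert np.allclose(t.values, e.values)

    def test_lognormal_residual_scale(self, two_component):
        cfg = GeneratorConfig(noise_mode="lognormal", noise_sigma=0.05, seed=3)
        grid = make_log_grid(0.01, 10.0, 256)
        t = noisy_target(two_component, cfg, grid=grid, time_unit="coalescent")
        e = exact_iicr(two_component, grid)
        resid = np.log10(t.values) - np.log10(e.values)
        assert resid.std() == pytest.approx(0.05 / math.log(10), rel=0.2)

    def test_finite_t2_tracks_exact(self, two_component):
        """Resampling noise stays within a few percent on the interior grid."""
        cfg = GeneratorConfig(noise_mode="finite_t2", noise_size=100_000, seed=5)
        t = noisy_target(two_component, cfg, time_unit="coalescent")
        interior = (t.grid.times > 0.05) & (t.grid.times < 10.0)
        mids = t.grid.times[interior]
        e = exact_iicr(two_component, TimeGrid(mids), value_unit="effective_size")
        ratio = t.values[interior] / e.values
        assert np.median(np.abs(np.log10(ratio))) < 0.02

    def test_reproducible(self, two_component):
        cfg = GeneratorConfig(noise_mode="finite_t2", noise_size=5000, seed=9)
        a = noisy_target(two_component, cfg)
        b = noisy_target(two_component, cfg)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.grid.times, b.grid.times)


class TestPsmcFixture:
    def test_constant_history_flat_lambdas(self, scaling):
        from islandcoal import PanmicticHistory

        hist = PanmicticHistory(np.array([0.0]), np.array([1000.0]))
        text = make_psmc_fixture(hist, theta0=4 * scaling.mu * 100 * 1000.0, pattern="64*1")
        it = read_psmc(text).final
        assert it.times.size == 64
        assert np.allclose(it.lambdas, it.lambdas[0])

    def test_structured_fixture_encodes_exact_iicr(self, two_component, scaling):
        """Scaled fixture steps equal the exact IICR at the interval midpoints."""
        theta0 = 4 * scaling.mu * 100 * two_component.deme_size
        text = make_psmc_fixture(two_component, theta0=theta0, pattern="4+25*2+4+6")
        curve = scale_psmc(read_psmc(text), scaling).curve
        assert curve.grid.times.size == 64
        # recompute the midpoints in coalescent units and compare
        N = two_component.deme_size
        bounds_c = curve.grid.times / (2.0 * N * scaling.generation_time_years)
        mids = np.sqrt(bounds_c[1:-1] * bounds_c[2:])
        e = exact_iicr(two_component, TimeGrid(mids), scaling=scaling)
        assert np.allclose(curve.values[1:-1], e.values, rtol=1e-9)

    def test_round_trip_relative_error(self, scaling):
        from islandcoal import PanmicticHistory

        hist = PanmicticHistory(np.array([0.0, 2000.0, 30_000.0]),
                                np.array([5000.0, 900.0, 12_000.0]))
        text = make_psmc_fixture(hist, theta0=0.0048, pattern="4+25*2+4+6")
        back = scale_psmc(read_psmc(text), scaling)
        # every reconstructed step value must be one of the history's sizes
        assert set(np.round(back.curve.values, 6)) <= set(hist.sizes)

    def test_bad_pattern_propagates(self, two_component):
        with pytest.raises(ValueError, match="malformed"):
            make_psmc_fixture(two_component, pattern="4+*2")


class TestEndToEndClosure:
    def test_fixture_fit_recovers_generator(self, scaling):
        """scenario -> pseudo-PSMC -> rescale -> fit round trip.

        Identifiable one- and two-component scenarios pushed through the
        64-interval fixture discretisation are recovered within the
        validation tolerances in at least 80% of seeded cases.
        """
        n_cases, hits, failures = 20, 0, []
        for i in range(n_cases):
            c = 1 + (i % 2)
            truth = benchmark_scenario(300 + i, c)
            theta0 = 4 * scaling.mu * 100 * truth.deme_size
            text = make_psmc_fixture(truth, theta0=theta0, pattern="4+25*2+4+6")
            target = scale_psmc(read_psmc(text), scaling).curve
            cfg = FitConfig(n_components=c, n_bounds=(2, 80), N_bounds=(1e2, 5e5),
                            M_bounds=(0.05, 50.0), seed=i)
            fit = fit_scenario(target, cfg, scaling)
            s, tol = fit.scenario, cfg.tolerances
            ok = (
                abs(s.n_islands - truth.n_islands) <= tol["n"]
                and abs(s.deme_size / truth.deme_size - 1.0) <= tol["N"]
                and all(
                    abs(math.log(a / b)) <= math.log(1 + tol["t"])
                    for a, b in zip(s.change_times, truth.change_times)
                )
                and all(
                    abs(a / b - 1.0) <= tol["M"]
                    for a, b in zip(s.migration_rates, truth.migration_rates)
                )
            )
            hits += ok
            if not ok:
                failures.append((i, truth, s))
        assert hits >= 16, f"only {hits}/20 recovered; failures: {failures}"
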