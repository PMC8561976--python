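"""Seeded end-to-end benchmarks: oracle agreement, recovery, spurious signals.

These are the package's own quality gates, exercised by the test suite
and the reproduction script.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exact import exact_iicr, mean_t2
from .fit import FitConfig, fit_scenario, validate_by_reinference
from .interpret import iicr_as_ne_history
from .montecarlo import exact_empirical_discrepancy
from .scenario import (
    IslandScenario,
    SamplingConfig,
    ScalingConfig,
    coalescent_to_years,
    make_log_grid,
)
from .synth import GeneratorConfig, benchmark_scenario, random_scenario

__all__ = [
    "oracle_max_discrepancy",
    "mean_t2_worst_error",
    "panmictic_exactness",
    "RecoveryCase",
    "recovery_benchmark",
    "spurious_change_fraction",
]


def oracle_max_discrepancy(
    n_scenarios: int = 5,
    n_samples: int = 100_000,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> float:
    """Worst |log10(exact/empirical IICR)| over seeded random scenarios."""
    cfg = config if config is not None else GeneratorConfig()
    worst = 0.0
    for i in range(n_scenarios):
        scen = random_scenario(cfg, seed=seed + 100 + i)
        worst = max(worst, exact_empirical_discrepancy(scen, n_samples=n_samples, seed=seed + i))
    return worst


def mean_t2_worst_error(seed: int = 0, n_scenarios: int = 5) -> float:
    """Worst relative error of integrated E[T2] against the exact value n.

    Single-component island models with same-deme sampling have mean T2
    equal to the island count, whatever the migration rate.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_scenarios):
        n = int(rng.integers(2, 101))
        M = float(np.exp(rng.uniform(np.log(0.05), np.log(50.0))))
        scen = IslandScenario(n, 1000.0, (), (M,))
        worst = max(worst, abs(mean_t2(scen) / n - 1.0))
    return worst


def panmictic_exactness(n_ref: float = 5000.0, n_islands: int = 10, big_m: float = 1e4) -> dict:
    """Constancy checks of the two panmictic limits of the exact IICR.

    ``n1_max_rel_dev``: deviation of the n = 1 curve from the constant N.
    ``bigM_max_rel_dev``: deviation of an M -> large island curve from the
    constant n*N.
    """
    grid = make_log_grid(0.01, 50.0, 64)
    pan = exact_iicr(IslandScenario(1, n_ref, (), (0.0,)), grid)
    dev1 = float(np.max(np.abs(pan.values / n_ref - 1.0)))
    isl = exact_iicr(IslandScenario(n_islands, n_ref, (), (big_m,)), grid)
    dev2 = float(np.max(np.abs(isl.values / (n_islands * n_ref) - 1.0)))
    return {"n1_max_rel_dev": dev1, "bigM_max_rel_dev": dev2}


@dataclass(frozen=True)
class RecoveryCase:
    """One parameter-recovery trial: truth, fit, errors, verdicts."""

    truth: IslandScenario
    fitted: IslandScenario
    distance: float
    errors: dict
    recovered: bool
    reinference_pass: bool | None


def _recovery_errors(truth: IslandScenario, fitted: IslandScenario) -> dict:
    return {
        "n": abs(fitted.n_islands - truth.n_islands),
        "N": abs(fitted.deme_size / truth.deme_size - 1.0),
        "t": [abs(math.log(a / b)) for a, b in zip(fitted.change_times, truth.change_times)],
        "M": [abs(a / b - 1.0) for a, b in zip(fitted.migration_rates, truth.migration_rates)],
    }


def _recovered(errors: dict, tol: dict) -> bool:
    return (
        errors["n"] <= tol["n"]
        and errors["N"] <= tol["N"]
        and all(e <= math.log(1.0 + tol["t"]) for e in errors["t"])
        and all(e <= tol["M"] for e in errors["M"])
    )


def recovery_benchmark(
    n_cases: int = 10,
    seed: int = 0,
    components: tuple[int, ...] = (2, 3),
    validate: bool = True,
    popsize: int = 16,
    maxiter: int = 200,
    scaling: ScalingConfig = ScalingConfig(),
) -> list[RecoveryCase]:
    """Noise-free parameter recovery on identifiable benchmark scenarios.

    Case ``i`` uses component count ``components[i % len(components)]``
    and seed ``seed + i``.  The target is the exact IICR in (years, Ne) on
    a 64-point log grid covering the scenario's dynamics; the fit gets
    matching component count and generous box bounds.  Successful fits
    are optionally validated by re-inference.
    """
    cases: list[RecoveryCase] = []
    for i in range(n_cases):
        c = components[i % len(components)]
        truth = benchmark_scenario(seed + i, c)
        N = truth.deme_size
        t_hi = max(10.0, 4.0 * truth.change_times[-1]) if truth.change_times else 10.0
        grid = make_log_grid(
            coalescent_to_years(0.01, N, scaling),
            coalescent_to_years(t_hi, N, scaling),
            64,
            unit="years",
        )
        target = exact_iicr(truth, grid, scaling=scaling)
        cfg = FitConfig(
            n_components=c,
            n_bounds=(2, 80),
            N_bounds=(1e2, 5e5),
            M_bounds=(0.05, 50.0),
            popsize=popsize,
            maxiter=maxiter,
            seed=seed + i,
        )
        fit = fit_scenario(target, cfg, scaling)
        errors = _recovery_errors(truth, fit.scenario)
        ok = _recovered(errors, cfg.tolerances)
        re_pass: bool | None = None
        if validate and ok:
            re_pass = validate_by_reinference(fit, cfg, scaling).verdict
        cases.append(RecoveryCase(truth, fit.scenario, fit.distance, errors, ok, re_pass))
    return cases


def spurious_change_fraction(
    n_cases: int = 100,
    seed: int = 0,
    min_variation: float = 0.01,
    sampling: SamplingConfig = SamplingConfig(),
) -> float:
    """Fraction of structured constant-size scenarios with a non-constant reading.

    Every scenario has constant deme size and at least one genuine
    connectivity change; its exact IICR read as a panmictic Ne history
    should vary by more than ``min_variation`` (relative range), i.e. a
    spurious size change appears even though no size ever changed.
    """
    cfg = GeneratorConfig(c_range=(2, 8))
    hits = 0
    for i in range(n_cases):
        scen = random_scenario(cfg, seed=seed + i)
        t_hi = max(10.0, 1.5 * scen.change_times[-1])
        grid = make_log_grid(
            coalescent_to_years(0.01, scen.deme_size),
            coalescent_to_years(t_hi, scen.deme_size),
            64,
            unit="years",
        )
        curve = exact_iicr(scen, grid, sampling)
        hist = iicr_as_ne_history(curve)
        variation = float(np.max(hist.sizes) / np.min(hist.sizes) - 1.0)
        if variation > min_variation:
            hits += 1
    return hits / n_cases
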