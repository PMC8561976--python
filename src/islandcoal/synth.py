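"""Synthetic scenarios, noisy targets and pseudo-PSMC fixtures.

Everything the pipeline consumes can be generated here with a seed:
random piecewise-stationary island scenarios, exact or noisy target
curves (finite-T2 resampling noise or i.i.d. lognormal perturbation), and
`.psmc` text fixtures whose step function encodes a known history or the
exact IICR of a known structured scenario.  Study presets carry the
published change times and island counts of the two mouse lemur fits;
their migration rates and deme size are free choices (the source analyses
never printed them) and are documented as illustrative defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .exact import exact_iicr
from .montecarlo import empirical_iicr, sample_t2
from .psmc import pattern_to_intervals, write_psmc
from .scenario import (
    IICRCurve,
    IslandScenario,
    PanmicticHistory,
    SamplingConfig,
    ScalingConfig,
    TimeGrid,
    coalescent_to_years,
    make_log_grid,
    require_valid,
    years_to_coalescent,
)

__all__ = [
    "GeneratorConfig",
    "StudyPreset",
    "STUDY_PRESETS",
    "random_scenario",
    "benchmark_scenario",
    "BENCHMARK_CONFIG",
    "noisy_target",
    "make_psmc_fixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ranges and noise model for the scenario generator.

    All continuous parameters are drawn log-uniformly within their range.
    ``noise_mode`` controls :func:`noisy_target`: ``none`` (exact curve),
    ``finite_t2`` (empirical IICR from ``noise_size`` T2 draws — realistic
    correlated estimation noise, the default), or ``lognormal``
    (independent lognormal factors of log-sd ``noise_sigma`` per point).
    """

    n_range: tuple[int, int] = (2, 100)
    N_range: tuple[float, float] = (1e2, 1e6)
    c_range: tuple[int, int] = (1, 8)
    M_range: tuple[float, float] = (0.05, 50.0)
    t_range: tuple[float, float] = (0.01, 20.0)
    noise_mode: Literal["none", "finite_t2", "lognormal"] = "finite_t2"
    noise_size: int = 100_000
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in (("n", self.n_range), ("N", self.N_range), ("c", self.c_range),
                        ("M", self.M_range), ("t", self.t_range)):
            if r[0] > r[1]:
                raise ValueError(f"{name}_range must be ordered low <= high")
        if self.noise_mode not in ("none", "finite_t2", "lognormal"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")


@dataclass(frozen=True)
class StudyPreset:
    """Named scenario template with published change times and island count.

    ``change_times_kyr`` are ages, youngest first.  ``deme_size`` and
    ``migration_rates`` are illustrative defaults, not published values:
    the rates simply alternate between a high and a low level so that
    connectivity falls between the oldest change and the glacial maximum
    and rises again toward the present, matching the qualitative direction
    of the published bars.
    """

    name: str
    n_islands: int
    change_times_kyr: tuple[float, ...]
    deme_size: float = 1000.0
    migration_rates: tuple[float, ...] | None = None
    scaling: ScalingConfig = field(default_factory=ScalingConfig)

    def scenario(self) -> IslandScenario:
        c = len(self.change_times_kyr) + 1
        if self.migration_rates is not None:
            M = self.migration_rates
        else:
            # youngest component first; oldest component gets the high rate
            M = tuple(5.0 if (c - 1 - i) % 2 == 0 else 0.5 for i in range(c))
        t_coal = tuple(
            float(years_to_coalescent(t * 1000.0, self.deme_size, self.scaling))
            for t in self.change_times_kyr
        )
        scen = IslandScenario(self.n_islands, self.deme_size, t_coal, M)
        require_valid(scen)
        return scen


STUDY_PRESETS: dict[str, StudyPreset] = {
    # gray mouse lemur-like fit: 84 islands, five connectivity changes
    "murinus": StudyPreset(
        name="murinus",
        n_islands=84,
        change_times_kyr=(5.1, 13.7, 30.7, 42.7, 129.1),
    ),
    # golden-brown mouse lemur-like fit: 61 islands, five changes
    "ravelobensis": StudyPreset(
        name="ravelobensis",
        n_islands=61,
        change_times_kyr=(7.9, 20.1, 27.1, 135.6, 338.9),
    ),
}


def random_scenario(config: GeneratorConfig, seed: int | None = None) -> IslandScenario:
    """Draw a random scenario inside the config's ranges (deterministic per seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
    N = float(_log_uniform(rng, *config.N_range))
    c = int(rng.integers(config.c_range[0], config.c_range[1] + 1))
    while True:
        ts = np.sort(_log_uniform(rng, *config.t_range, size=c - 1))
        if ts.size < 2 or np.all(np.diff(ts) > 0):
            break
    if n == 1:
        scen = IslandScenario(1, N, tuple(ts), (0.0,) * c)
    else:
        Ms = _log_uniform(rng, *config.M_range, size=c)
        scen = IslandScenario(n, N, tuple(ts), tuple(Ms))
    require_valid(scen)
    return scen


#: generator ranges for recovery benchmarks: moderate island counts and
#: migration rates, so scenarios stay identifiable from a single curve
BENCHMARK_CONFIG = GeneratorConfig(
    n_range=(3, 40),
    N_range=(5e2, 5e4),
    M_range=(0.2, 10.0),
    t_range=(0.05, 5.0),
    noise_mode="none",
)


def benchmark_scenario(seed: int, n_components: int, config: GeneratorConfig | None = None) -> IslandScenario:
    """Identifiable random scenario for parameter-recovery benchmarks.

    Draws from :data:`BENCHMARK_CONFIG` (or ``config``) but rejects
    scenarios whose connectivity changes would be invisible in the curve:
    adjacent migration rates must differ by at least a factor 2 and
    adjacent change times by at least a factor 4.  Near-panmictic or
    barely-changing scenarios are legitimate demographies but weakly
    identified by construction, so they are benchmarked separately.
    """
    base = BENCHMARK_CONFIG if config is None else config
    cfg = replace(base, c_range=(n_components, n_components))
    for attempt in range(1000):
        scen = random_scenario(cfg, seed=seed * 1009 + attempt)
        ms = np.asarray(scen.migration_rates)
        ts = np.asarray(scen.change_times)
        ratio_ok = True
        if scen.n_islands > 1 and ms.size > 1:
            ratio_ok = bool(np.all(np.maximum(ms[:-1], ms[1:]) / np.minimum(ms[:-1], ms[1:]) >= 2.0))
        sep_ok = bool(ts.size < 2 or np.all(ts[1:] / ts[:-1] >= 4.0))
        if ratio_ok and sep_ok:
            return scen
    raise RuntimeError("no identifiable scenario found (ranges too tight)")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    if lo == hi:
        return lo if size is None else np.full(size, float(lo))
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def noisy_target(
    scenario: IslandScenario,
    config: GeneratorConfig,
    grid: TimeGrid | None = None,
    sampling: SamplingConfig = SamplingConfig(),
    scaling: ScalingConfig = ScalingConfig(),
    time_unit: str = "years",
    seed: int | None = None,
) -> IICRCurve:
    """Target curve for the scenario under the config's noise model.

    Returned in effective-size values over a grid in ``time_unit``
    (years by default, the PSMC presentation); the default grid is 64 log
    points over coalescent [0.01, 1.2 x oldest change or 10].
    """
    require_valid(scenario)
    rng_seed = config.seed if seed is None else seed
    if grid is None:
        t_hi = 1.2 * scenario.change_times[-1] if scenario.change_times else 10.0
        t_hi = max(t_hi, 10.0)
        grid_coal = make_log_grid(0.01, t_hi, 64)
    elif grid.unit != "coalescent":
        raise ValueError("noisy_target expects its grid in coalescent units")
    else:
        grid_coal = grid

    if config.noise_mode == "finite_t2":
        sample = sample_t2(scenario, sampling, config.noise_size, seed=rng_seed)
        emp = empirical_iicr(sample, grid_coal)
        times_c = emp.grid.times
        values = emp.values * scenario.deme_size
        kind = "step"
    else:
        ex = exact_iicr(scenario, grid_coal, sampling, scaling, value_unit="effective_size")
        times_c = grid_coal.times
        values = ex.values
        kind = "smooth"
        if config.noise_mode == "lognormal":
            rng = np.random.default_rng(rng_seed)
            values = values * np.exp(rng.normal(0.0, config.noise_sigma, size=values.shape))

    if time_unit == "coalescent":
        out_grid = TimeGrid(times_c, unit="coalescent")
    elif time_unit == "years":
        out_grid = TimeGrid(coalescent_to_years(times_c, scenario.deme_size, scaling), unit="years")
    elif time_unit == "generations":
        out_grid = TimeGrid(2.0 * scenario.deme_size * times_c, unit="generations")
    else:
        raise ValueError(f"unknown time unit {time_unit!r}")
    return IICRCurve(out_grid, values, value_unit="effective_size", kind=kind)


def make_psmc_fixture(
    source: PanmicticHistory | IslandScenario,
    theta0: float = 0.0048,
    scaling: ScalingConfig = ScalingConfig(),
    pattern: str = "4+25*2+4+6",
    rho0: float = 0.005,
    t_min_coal: float = 0.005,
    t_max_coal: float | None = None,
    sampling: SamplingConfig = SamplingConfig(),
) -> str:
    """`.psmc` text whose step function encodes ``source``.

    The pattern (e.g. ``"4+25*2+4+6"`` = 64 atomic intervals) fixes the
    number of steps; boundaries are t_0 = 0 followed by log-spaced times
    in units of 2*N0 generations.  For a structured scenario the lambda of
    each interval is its exact IICR (effective-size units) at the interval
    midpoint divided by N0, giving the "PSMC of a structured population"
    test input.
    """
    k, _ = pattern_to_intervals(pattern)
    if theta0 <= 0:
        raise ValueError("theta0 must be > 0")
    n0 = theta0 / (4.0 * scaling.mu * scaling.psmc_bin_size)

    if isinstance(source, IslandScenario):
        require_valid(source)
        N = source.deme_size
        if t_max_coal is None:
            # cover both the youngest-to-oldest change span and the old-time
            # plateau: ~10 relaxation times of the oldest component's slowest
            # mode, else the island count is invisible in the fixture
            t_max_coal = 4.0 * source.change_times[-1] if source.change_times else 20.0
            if source.n_islands > 1:
                A = np.array(
                    [
                        [-(source.migration_rates[-1] + 1.0), source.migration_rates[-1]],
                        [
                            source.migration_rates[-1] / (source.n_islands - 1.0),
                            -source.migration_rates[-1] / (source.n_islands - 1.0),
                        ],
                    ]
                )
                slow = float(np.min(np.abs(np.linalg.eigvals(A))))
                t_max_coal = max(t_max_coal, 10.0 / max(slow, 1e-6))
            t_max_coal = max(t_max_coal, 20.0, 10.0 * t_min_coal)
        # boundaries in source coalescent units, then converted to 2N0-gen units
        bounds_c = np.concatenate([[0.0], np.geomspace(t_min_coal, t_max_coal, k - 1)])
        mids = np.empty(k)
        mids[0] = bounds_c[1] / 2.0
        mids[1:-1] = np.sqrt(bounds_c[1:-1] * bounds_c[2:])
        mids[-1] = bounds_c[-1] * np.sqrt(bounds_c[-1] / bounds_c[-2])
        curve = exact_iicr(source, TimeGrid(mids, unit="coalescent"), sampling, scaling,
                           value_unit="effective_size")
        starts_gen = 2.0 * N * bounds_c
        history = PanmicticHistory(starts_gen, curve.values)
    else:
        hist = source
        if t_max_coal is None:
            oldest = hist.epoch_starts[-1] / (2.0 * n0)
            t_max_coal = max(2.0 * oldest, 2.0 * t_min_coal) if oldest > 0 else 20.0
        bounds_units = np.concatenate([[0.0], np.geomspace(t_min_coal, t_max_coal, k - 1)])
        starts_gen = bounds_units * 2.0 * n0
        mids = np.empty(k)
        mids[0] = starts_gen[1] / 2.0
        mids[1:-1] = np.sqrt(starts_gen[1:-1] * starts_gen[2:])
        mids[-1] = starts_gen[-1] * 1.5
        history = PanmicticHistory(starts_gen, hist.size_at(mids))
    return write_psmc(history, theta0=theta0, rho0=rho0, scaling=scaling)
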