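"""Monte-Carlo simulation of pairwise coalescence times and empirical IICR.

Draws T2 — the coalescence time of two gene copies — by simulating the
two-lineage {S, D} jump chain directly with exponential waiting times.
Component changes are handled by truncating every pending exponential
clock at the boundary and redrawing it under the next component's rates,
which is exact by memorylessness.  The empirical IICR is then a discrete
hazard estimate on a grid: per interval, survival divided by the
interval's event density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenario import (
    IICRCurve,
    IslandScenario,
    SamplingConfig,
    TimeGrid,
    make_log_grid,
    require_valid,
)

__all__ = [
    "T2Sample",
    "sample_t2",
    "empirical_iicr",
    "default_grid_for",
    "exact_empirical_discrepancy",
]

#: the study's sample size for empirical IICR curves
DEFAULT_N_SAMPLES = 100_000


@dataclass(frozen=True)
class T2Sample:
    """Draws of the pairwise coalescence time T2, in coalescent units."""

    draws: np.ndarray
    scenario: IslandScenario
    sampling: SamplingConfig
    seed: int

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", d)
        if d.size < 1 or not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("T2 draws must be positive, finite and non-empty")

    @property
    def size(self) -> int:
        return int(self.draws.size)


def sample_t2(
    scenario: IslandScenario,
    sampling: SamplingConfig = SamplingConfig(),
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> T2Sample:
    """Simulate ``n_samples`` independent T2 draws under the scenario.

    Fully vectorised over draws with a single seeded generator and a fixed
    event order, so the result is a deterministic function of
    ``(scenario, sampling, n_samples, seed)``.
    """
    require_valid(scenario)
    sampling.check_against(scenario)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)

    if scenario.n_islands == 1:
        draws = rng.exponential(1.0, size=n_samples)
        return T2Sample(draws, scenario, sampling, seed)

    n = scenario.n_islands
    t = np.zeros(n_samples)
    # state: 0 = same deme, 1 = different demes
    state = np.zeros(n_samples, dtype=np.int8)
    if sampling.mode == "different_demes":
        state[:] = 1
    coal_time = np.full(n_samples, np.nan)
    alive = np.arange(n_samples)

    bounds = list(scenario.change_times) + [np.inf]
    for M, t_end in zip(scenario.migration_rates, bounds):
        rate_S = M + 1.0
        rate_D = M / (n - 1.0)
        p_coal = 1.0 / rate_S  # P(next event from S is coalescence)
        # iterate events until every live pair has reached t_end or coalesced
        active = alive[t[alive] < t_end] if np.isfinite(t_end) else alive
        while active.size:
            rates = np.where(state[active] == 0, rate_S, rate_D)
            t_new = t[active] + rng.exponential(1.0, size=active.size) / rates
            u = rng.random(active.size)

            crossed = t_new >= t_end
            inS = state[active] == 0
            coal = (~crossed) & inS & (u < p_coal)
            move = (~crossed) & ~coal

            idx_coal = active[coal]
            coal_time[idx_coal] = t_new[coal]
            idx_move = active[move]
            t[idx_move] = t_new[move]
            state[idx_move] ^= 1
            # crossed pairs park at the boundary; memorylessness lets the
            # next component redraw their clocks from t_end
            t[active[crossed]] = t_end if np.isfinite(t_end) else t[active[crossed]]
            active = idx_move
        alive = alive[np.isnan(coal_time[alive])]
        if not alive.size:
            break
    return T2Sample(coal_time, scenario, sampling, seed)


def default_grid_for(sample: T2Sample, k: int = 64, t_min: float = 0.01) -> TimeGrid:
    """Default evaluation grid: ``k`` log points to the 99.9th percentile.

    For small samples the upper end backs off so that at least 20 draws
    survive past it (the estimator needs a populated tail).
    """
    q = min(0.999, 1.0 - 20.0 / sample.size)
    if q <= 0:
        raise ValueError("sample too small for a default grid (need > 20 draws)")
    t_max = float(np.quantile(sample.draws, q))
    return make_log_grid(min(t_min, t_max / 10.0), t_max, k)


def empirical_iicr(
    sample: T2Sample,
    grid: TimeGrid | None = None,
    min_events: int = 1,
) -> IICRCurve:
    """Empirical IICR from T2 draws: inverse discrete hazard on the grid.

    Per interval ``[t_k, t_{k+1})`` the value is

        S(t_k) * (t_{k+1} - t_k) / (S(t_k) - S(t_{k+1}))

    with S the empirical survival.  Intervals holding fewer than
    ``min_events`` coalescences are merged rightward (trailing deficits
    leftward) so every reported value rests on at least that many events;
    the default 1 merges only empty intervals.  Event counts are conserved
    by merging.  The curve is a step function over the merged interval
    starts, in coalescent units.
    """
    if grid is None:
        grid = default_grid_for(sample)
    if grid.unit != "coalescent":
        raise ValueError("empirical IICR needs a coalescent-unit grid (draws are in coalescent units)")
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    draws = np.sort(sample.draws)
    m = draws.size
    # survivors strictly beyond each grid time
    counts = m - np.searchsorted(draws, grid.times, side="right")
    if counts[-1] < 10:
        raise ValueError(
            f"grid beyond support: only {counts[-1]} of {m} draws survive past t = {grid.times[-1]:g}"
        )
    # merged intervals as (start index, end index) with >= min_events events
    spans: list[tuple[int, int]] = []
    k = 0
    npts = len(grid)
    while k < npts - 1:
        j = k + 1
        while j < npts - 1 and counts[k] - counts[j] < min_events:
            j += 1
        if counts[k] - counts[j] >= min_events:
            spans.append((k, j))
        elif counts[k] - counts[j] > 0 and spans:
            spans[-1] = (spans[-1][0], j)  # fold trailing deficit leftward
        elif counts[k] - counts[j] > 0:
            spans.append((k, j))
        k = j
    starts = np.array([grid.times[k] for k, _ in spans])
    values = np.array(
        [
            counts[k] * (grid.times[j] - grid.times[k]) / (counts[k] - counts[j])
            for k, j in spans
        ]
    )
    out_grid = TimeGrid(starts, unit="coalescent")
    return IICRCurve(out_grid, values, value_unit="coalescent", kind="step")


def exact_empirical_discrepancy(
    scenario: IslandScenario,
    sampling: SamplingConfig = SamplingConfig(),
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    n_points: int = 64,
    quantiles: tuple[float, float] = (0.10, 0.90),
    min_events: int | None = None,
) -> float:
    """Max |log10(exact / empirical IICR)| on an interior log grid.

    The Monte-Carlo cross-check behind the analytic curves: draws T2,
    builds an ``n_points`` log grid between the given sample quantiles
    (the interior, away from the noisy edges), estimates the empirical
    IICR with at least ``min_events`` coalescences per reported interval
    (default ``n_samples // 100``), and compares it against the exact
    survival pushed through the same discrete-hazard functional on the
    same merged intervals.
    """
    from .exact import exact_discrete_iicr  # local import avoids a cycle

    sample = sample_t2(scenario, sampling, n_samples, seed)
    lo, hi = np.quantile(sample.draws, quantiles)
    grid = make_log_grid(lo, hi, n_points)
    if min_events is None:
        min_events = max(1, n_samples // 100)
    emp = empirical_iicr(sample, grid, min_events=min_events)
    bounds = TimeGrid(np.append(emp.grid.times, grid.times[-1]), unit="coalescent")
    exact = exact_discrete_iicr(scenario, bounds, sampling)
    return float(np.max(np.abs(np.log10(exact.values / emp.values))))
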