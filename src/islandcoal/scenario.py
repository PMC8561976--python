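"""Domain types for structured demographies, time grids and IICR curves.

Conventions used throughout the package:

* The internal time unit is the coalescent unit of ``2N`` generations,
  where ``N`` is the diploid deme size.  In this unit a panmictic
  population of size ``N`` has a constant IICR equal to ``N`` (or 1 in
  coalescent value units), which makes unit bookkeeping trivial.
* Times are ages: present = 0, increasing into the past, matching the
  orientation of PSMC plots.
* The scaled migration rate is ``M = 4*N*m`` (the ``ms`` convention), the
  expected scaled number of immigrant gene copies per deme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "IslandScenario",
    "SamplingConfig",
    "TimeGrid",
    "IICRCurve",
    "ScalingConfig",
    "PanmicticHistory",
    "make_log_grid",
    "coalescent_to_years",
    "years_to_coalescent",
    "coalescent_to_generations",
    "validate_scenario",
    "require_valid",
    "evaluate_curve",
]

TimeUnit = Literal["coalescent", "generations", "years"]
ValueUnit = Literal["coalescent", "effective_size"]


@dataclass(frozen=True)
class ScalingConfig:
    """Scaling constants linking coalescent quantities to real units.

    Parameters
    ----------
    mu : float
        Per-site per-generation mutation rate.  Default ``1.2e-8``.
    generation_time_years : float
        Generation time ``g`` in years.  Default ``2.5``.
    psmc_bin_size : int
        Number of bases per PSMC bin ``s`` (the ``fq2psmcfa`` default of
        100); used when converting theta0 to N0.
    """

    mu: float = 1.2e-8
    generation_time_years: float = 2.5
    psmc_bin_size: int = 100

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.generation_time_years > 0 and self.psmc_bin_size > 0):
            raise ValueError("all scaling constants must be strictly positive")


@dataclass(frozen=True)
class IslandScenario:
    """Piecewise-stationary symmetric n-island demography.

    The demography has ``c = len(migration_rates)`` components (periods of
    constant migration), separated by ``c - 1`` strictly increasing change
    times in coalescent units of ``2N`` generations.  ``n_islands = 1``
    denotes a panmictic population; its migration rates are stored as a
    single 0.

    Attributes
    ----------
    n_islands : int
        Number of demes ``n`` (>= 1).
    deme_size : float
        Effective diploid individuals per deme ``N`` (> 0).
    change_times : tuple of float
        Ages (before present) at which the migration rate changes,
        coalescent units, strictly increasing, length ``c - 1``.
    migration_rates : tuple of float
        Scaled migration rate ``M_i = 4*N*m`` per component, youngest
        first, length ``c``; all > 0 when ``n_islands > 1``.
    """

    n_islands: int
    deme_size: float
    change_times: tuple[float, ...] = ()
    migration_rates: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        # construction never raises: validate_scenario stays usable as a
        # diagnostic on deliberately broken scenarios
        object.__setattr__(self, "change_times", tuple(float(t) for t in self.change_times))
        object.__setattr__(self, "migration_rates", tuple(float(m) for m in self.migration_rates))

    @property
    def n_components(self) -> int:
        return len(self.migration_rates)

    def component_index(self, t: float) -> int:
        """Index of the component containing age ``t`` (right-continuous)."""
        return int(np.searchsorted(np.asarray(self.change_times), t, side="right"))


def validate_scenario(scenario: IslandScenario) -> list[str]:
    """Return a list of invariant violations (empty iff the scenario is valid).

    Diagnostic only: never raises.  Each entry names the offending field
    and the rule it breaks.
    """
    out: list[str] = []
    if int(scenario.n_islands) != scenario.n_islands or scenario.n_islands < 1:
        out.append("n_islands: must be an integer >= 1")
    if not (scenario.deme_size > 0 and math.isfinite(scenario.deme_size)):
        out.append("deme_size: must be finite and > 0")
    ts = np.asarray(scenario.change_times, dtype=float)
    if ts.size and (not np.all(np.isfinite(ts)) or np.any(ts <= 0)):
        out.append("change_times: must be finite and > 0")
    if ts.size > 1 and np.any(np.diff(ts) <= 0):
        out.append("change_times: non-increasing (must be strictly increasing)")
    ms = np.asarray(scenario.migration_rates, dtype=float)
    if len(ms) != len(ts) + 1:
        out.append("migration_rates: length must equal len(change_times) + 1")
    if not np.all(np.isfinite(ms)):
        out.append("migration_rates: must be finite")
    if scenario.n_islands == 1:
        if np.any(ms != 0):
            out.append("migration_rates: must be stored as 0 when n_islands = 1")
    else:
        if np.any(ms <= 0):
            # M = 0 leaves the different-deme state absorbing: no valid IICR
            out.append("migration_rates: absorbing structure (all M_i must be > 0 when n_islands > 1)")
    return out


def require_valid(scenario: IslandScenario) -> None:
    """Raise ``ValueError`` listing every invariant the scenario breaks."""
    problems = validate_scenario(scenario)
    if problems:
        raise ValueError("invalid scenario: " + "; ".join(problems))


@dataclass(frozen=True)
class SamplingConfig:
    """Where the two sampled gene copies start: same deme or different demes.

    The default, ``same_deme``, is the configuration of a single diploid
    individual and the one used for PSMC-style targets.
    """

    mode: Literal["same_deme", "different_demes"] = "same_deme"

    def __post_init__(self) -> None:
        if self.mode not in ("same_deme", "different_demes"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")

    def check_against(self, scenario: IslandScenario) -> None:
        if self.mode == "different_demes" and scenario.n_islands < 2:
            raise ValueError("different_demes sampling requires n_islands >= 2")


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing, strictly positive evaluation times with a unit tag.

    Evaluation grids (from :func:`make_log_grid`) carry at least two
    points; a single point is allowed so one-step curves (a constant
    history) remain representable.
    """

    times: np.ndarray
    unit: TimeUnit = "coalescent"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("a time grid needs at least 1 point")
        if not np.all(np.isfinite(t)):
            raise ValueError("grid times must be finite")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("grid times must be strictly positive and strictly increasing")
        if self.unit not in ("coalescent", "generations", "years"):
            raise ValueError(f"unknown time unit {self.unit!r}")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class IICRCurve:
    """A positive-valued curve over a time grid.

    ``kind`` distinguishes step functions (PSMC output, empirical discrete
    hazard) from smooth curves (exact IICR sampled on a grid): step curves
    are evaluated right-continuously from their step starts, smooth curves
    by log-log linear interpolation.
    """

    grid: TimeGrid
    values: np.ndarray
    value_unit: ValueUnit = "effective_size"
    kind: Literal["step", "smooth"] = "smooth"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != self.grid.times.shape:
            raise ValueError("values and grid must have the same length")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("curve values must be finite and > 0")
        if self.value_unit not in ("coalescent", "effective_size"):
            raise ValueError(f"unknown value unit {self.value_unit!r}")
        if self.kind not in ("step", "smooth"):
            raise ValueError(f"unknown curve kind {self.kind!r}")


@dataclass(frozen=True)
class PanmicticHistory:
    """Piecewise-constant effective-size history of a panmictic population.

    ``epoch_starts`` are ages in generations, first entry 0, strictly
    increasing; ``sizes`` are effective diploid individuals per epoch.
    """

    epoch_starts: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.epoch_starts, dtype=float)
        n = np.asarray(self.sizes, dtype=float)
        object.__setattr__(self, "epoch_starts", s)
        object.__setattr__(self, "sizes", n)
        if s.shape != n.shape or s.ndim != 1 or s.size < 1:
            raise ValueError("epoch_starts and sizes must be 1-d arrays of equal positive length")
        if s[0] != 0:
            raise ValueError("first epoch must start at 0 (the present)")
        if s.size > 1 and np.any(np.diff(s) <= 0):
            raise ValueError("epoch starts must be strictly increasing")
        if not np.all(np.isfinite(n)) or np.any(n <= 0):
            raise ValueError("sizes must be finite and > 0")

    def size_at(self, t_generations):
        """Ne at age ``t`` generations (right-continuous step lookup)."""
        t = np.asarray(t_generations, dtype=float)
        idx = np.clip(np.searchsorted(self.epoch_starts, t, side="right") - 1, 0, None)
        return self.sizes[idx]


def make_log_grid(t_min: float, t_max: float, k: int, unit: TimeUnit = "coalescent") -> TimeGrid:
    """``k`` log-uniformly spaced times from ``t_min`` to ``t_max`` inclusive."""
    if not (t_min > 0 and t_max > t_min):
        raise ValueError("need 0 < t_min < t_max")
    if k < 2:
        raise ValueError("need k >= 2 grid points")
    return TimeGrid(np.geomspace(t_min, t_max, int(k)), unit=unit)


def coalescent_to_generations(t_coal, n_ref: float):
    """Coalescent units (2N generations) -> generations."""
    if n_ref <= 0:
        raise ValueError("N_ref must be > 0")
    t = np.asarray(t_coal, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    return 2.0 * n_ref * t


def coalescent_to_years(t_coal, n_ref: float, scaling: ScalingConfig = ScalingConfig()):
    """Coalescent units -> years: ``2 * N_ref * t * g``."""
    return coalescent_to_generations(t_coal, n_ref) * scaling.generation_time_years


def years_to_coalescent(t_years, n_ref: float, scaling: ScalingConfig = ScalingConfig()):
    """Exact inverse of :func:`coalescent_to_years`."""
    if n_ref <= 0:
        raise ValueError("N_ref must be > 0")
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    return t / (2.0 * n_ref * scaling.generation_time_years)


def evaluate_curve(curve: IICRCurve, times) -> np.ndarray:
    """Evaluate a curve at arbitrary times in its own grid unit.

    Step curves are right-continuous in their step starts (times before the
    first start take the first value).  Smooth curves are interpolated
    linearly in log-log space and clamped at their endpoints.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("negative evaluation time")
    g = curve.grid.times
    if curve.kind == "step":
        idx = np.clip(np.searchsorted(g, t, side="right") - 1, 0, None)
        return curve.values[idx]
    logv = np.interp(np.log(np.maximum(t, g[0])), np.log(g), np.log(curve.values))
    return np.exp(logv)
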