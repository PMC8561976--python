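"""File formats: scenario YAML files and two-column curve tables."""

from __future__ import annotations

import re
from pathlib import Path
from typing import TextIO

import numpy as np
import yaml

from .scenario import (
    IICRCurve,
    IslandScenario,
    ScalingConfig,
    TimeGrid,
    require_valid,
    years_to_coalescent,
)

__all__ = ["read_scenario", "write_scenario", "read_curve", "write_curve"]


def read_scenario(
    source: str | Path | TextIO,
    scaling: ScalingConfig = ScalingConfig(),
) -> IslandScenario:
    """Load an island scenario from YAML.

    Keys: ``n_islands``, ``deme_size``, ``migration_rates`` and
    ``change_times`` — either a plain list (coalescent units) or a mapping
    ``{unit: coalescent|years, values: [...]}``; years are converted using
    the scenario's own deme size.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    n = int(data["n_islands"])
    N = float(data["deme_size"])
    ct = data.get("change_times", [])
    if isinstance(ct, dict):
        unit = ct.get("unit", "coalescent")
        vals = [float(v) for v in ct.get("values", [])]
        if unit == "years":
            vals = [float(years_to_coalescent(v, N, scaling)) for v in vals]
        elif unit != "coalescent":
            raise ValueError(f"unknown change_times unit {unit!r}")
    else:
        vals = [float(v) for v in ct]
    ms = tuple(float(m) for m in data.get("migration_rates", [0.0]))
    scen = IslandScenario(n, N, tuple(sorted(vals)), ms)
    require_valid(scen)
    return scen


def write_scenario(scenario: IslandScenario, path: str | Path) -> None:
    require_valid(scenario)
    data = {
        "n_islands": scenario.n_islands,
        "deme_size": float(scenario.deme_size),
        "change_times": {"unit": "coalescent", "values": [float(t) for t in scenario.change_times]},
        "migration_rates": [float(m) for m in scenario.migration_rates],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


_HEADER_RE = re.compile(r"time_unit=(\w+)\s+value_unit=(\w+)\s+kind=(\w+)")


def write_curve(curve: IICRCurve, path: str | Path) -> None:
    """Two-column table (time, value) with a unit-naming header line."""
    header = f"time_unit={curve.grid.unit} value_unit={curve.value_unit} kind={curve.kind}"
    np.savetxt(path, np.column_stack([curve.grid.times, curve.values]),
               header=header, fmt="%.10g")


def read_curve(path: str | Path) -> IICRCurve:
    with open(path) as fh:
        first = fh.readline()
    m = _HEADER_RE.search(first)
    if not m:
        raise ValueError(f"curve table {path} lacks a 'time_unit=... value_unit=... kind=...' header")
    data = np.loadtxt(path)
    grid = TimeGrid(data[:, 0], unit=m.group(1))
    return IICRCurve(grid, data[:, 1], value_unit=m.group(2), kind=m.group(3))
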