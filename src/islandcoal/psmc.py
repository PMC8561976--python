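"""Read, scale and write PSMC text output.

A ``.psmc`` file is a sequence of iteration blocks.  Each block starts
with an ``RD <round>`` line and ends with ``//``; inside, the ``TR`` line
carries theta0 and rho0 and the ``RS`` lines carry the inferred step
function as ``(k, t_k, lambda_k, ...)`` with t_k in units of 2*N0
generations and lambda_k the relative size.  Scaling to real units uses

    N0   = theta0 / (4 * mu * s)        (s = bases per PSMC bin)
    t_yr = 2 * N0 * t_k * g
    Ne_k = N0 * lambda_k

Only the records needed for curve reconstruction are interpreted; other
record types (LL, QD, TC, MM, DC, PA, ...) are skipped.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np

from .scenario import IICRCurve, PanmicticHistory, ScalingConfig, TimeGrid

__all__ = [
    "PsmcIteration",
    "PsmcDocument",
    "PsmcCurve",
    "read_psmc",
    "scale_psmc",
    "write_psmc",
    "pattern_to_intervals",
]

logger = logging.getLogger(__name__)

_KNOWN_RECORDS = {"RD", "TR", "RS", "PA", "LL", "QD", "RI", "TC", "MM", "MT", "DC", "CC", "//"}


@dataclass(frozen=True)
class PsmcIteration:
    """One EM iteration: theta0, rho0 and the (t_k, lambda_k) step function."""

    round_index: int
    theta0: float
    rho0: float
    times: np.ndarray  # t_k, units of 2*N0 generations, t_0 = 0
    lambdas: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lambdas", lam)
        if self.theta0 <= 0:
            raise ValueError("theta0 must be > 0")
        if t.size != lam.size or t.size < 1:
            raise ValueError("times and lambdas must have equal positive length")
        if t[0] != 0:
            raise ValueError("first RS time must be 0")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("RS times must be strictly increasing")
        if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
            raise ValueError("lambda values must be finite and > 0")


@dataclass(frozen=True)
class PsmcDocument:
    """All iteration blocks of a ``.psmc`` file; the last block is the result."""

    iterations: tuple[PsmcIteration, ...]

    @property
    def final(self) -> PsmcIteration:
        return self.iterations[-1]


@dataclass(frozen=True)
class PsmcCurve:
    """PSMC step function scaled to (years, diploid Ne)."""

    curve: IICRCurve
    n0: float

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("N0 must be > 0")

    def as_history(self, scaling: ScalingConfig = ScalingConfig()) -> PanmicticHistory:
        """The panmictic reading: step starts (generations) and Ne values."""
        if self.curve.grid.unit != "years":
            raise ValueError("PsmcCurve grid must be in years")
        starts_gen = self.curve.grid.times / scaling.generation_time_years
        return PanmicticHistory(
            epoch_starts=np.concatenate([[0.0], starts_gen[1:]]),
            sizes=self.curve.values.copy(),
        )


def read_psmc(source: TextIO | str | Iterable[str]) -> PsmcDocument:
    """Parse PSMC text output into a :class:`PsmcDocument`.

    ``source`` may be an open text stream, a string of file content, or an
    iterable of lines.  Unknown record types are skipped with a debug log;
    a final block lacking TR or RS records is a parse error.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    blocks: list[PsmcIteration] = []
    cur_round: int | None = None
    cur_tr: tuple[float, float] | None = None
    cur_rs: list[tuple[float, float]] = []
    last_line = 0

    def close_block(line_no: int) -> None:
        nonlocal cur_round, cur_tr, cur_rs
        if cur_round is None:
            return
        if cur_tr is None:
            raise ValueError(f"psmc parse error: block RD {cur_round} has no TR record (near line {line_no})")
        if not cur_rs:
            raise ValueError(f"psmc parse error: block RD {cur_round} has no RS records (near line {line_no})")
        times = np.array([t for t, _ in cur_rs])
        lams = np.array([l for _, l in cur_rs])
        blocks.append(PsmcIteration(cur_round, cur_tr[0], cur_tr[1], times, lams))
        cur_round, cur_tr, cur_rs = None, None, []

    for line_no, raw in enumerate(source, start=1):
        last_line = line_no
        line = raw.strip()
        if not line:
            continue
        tag, *rest = line.split(None, 1)
        fields = rest[0].split() if rest else []
        if tag == "RD":
            close_block(line_no)
            cur_round = int(fields[0]) if fields else len(blocks)
        elif tag == "TR":
            if len(fields) < 2:
                raise ValueError(f"psmc parse error: malformed TR record at line {line_no}")
            cur_tr = (float(fields[0]), float(fields[1]))
        elif tag == "RS":
            if len(fields) < 3:
                raise ValueError(f"psmc parse error: malformed RS record at line {line_no}")
            cur_rs.append((float(fields[1]), float(fields[2])))
        elif tag == "//":
            close_block(line_no)
        else:
            if tag not in _KNOWN_RECORDS:
                logger.warning("ignoring unknown psmc record type %r at line %d", tag, line_no)
    close_block(last_line + 1)
    if not blocks:
        raise ValueError("psmc parse error: no RD blocks found")
    return PsmcDocument(tuple(blocks))


def scale_psmc(
    doc: PsmcDocument | PsmcIteration,
    scaling: ScalingConfig = ScalingConfig(),
    iteration: int | None = None,
) -> PsmcCurve:
    """Scale a parsed document to a (years, Ne) step curve.

    Uses the final iteration unless ``iteration`` selects an earlier one.
    """
    if isinstance(doc, PsmcDocument):
        it = doc.final if iteration is None else doc.iterations[iteration]
    else:
        it = doc
    if it.times.size < 2:
        raise ValueError("document has a single RS step; a curve needs at least two")
    n0 = it.theta0 / (4.0 * scaling.mu * scaling.psmc_bin_size)
    years = 2.0 * n0 * it.times * scaling.generation_time_years
    ne = n0 * it.lambdas
    # step starts at 0 cannot live on a strictly-positive grid; shift the
    # first start to a tiny positive epsilon relative to the next step
    if years[0] == 0.0:
        eps = years[1] * 1e-9 if years.size > 1 else 1e-9
        years = years.copy()
        years[0] = eps
    grid = TimeGrid(years, unit="years")
    return PsmcCurve(IICRCurve(grid, ne, value_unit="effective_size", kind="step"), n0)


def write_psmc(
    history: PanmicticHistory,
    theta0: float,
    rho0: float = 0.005,
    scaling: ScalingConfig = ScalingConfig(),
    n_rounds: int = 1,
) -> str:
    """Render a panmictic history as PSMC text (synthetic fixture writer).

    The history's epochs become RS steps with N0 = theta0/(4*mu*s);
    ``read_psmc`` then ``scale_psmc`` recovers the history to better than
    1e-9 relative.  ``n_rounds`` repeats the block to mimic multi-iteration
    files (all rounds identical; the final one is what counts).
    """
    if theta0 <= 0:
        raise ValueError("theta0 must be > 0")
    n0 = theta0 / (4.0 * scaling.mu * scaling.psmc_bin_size)
    t_units = history.epoch_starts / (2.0 * n0)
    lambdas = history.sizes / n0
    lines: list[str] = []
    for rd in range(n_rounds):
        lines.append(f"RD\t{rd}")
        lines.append(f"TR\t{theta0:.17g}\t{rho0:.17g}")
        for k, (t, lam) in enumerate(zip(t_units, lambdas)):
            lines.append(f"RS\t{k}\t{t:.17g}\t{lam:.17g}")
        lines.append("PA\t" + f"{theta0:.17g} {rho0:.17g}")
        lines.append("//")
    return "\n".join(lines) + "\n"


def pattern_to_intervals(pattern: str) -> tuple[int, list[tuple[int, int]]]:
    """Parse a PSMC ``-p`` pattern like ``"4+25*2+4+6"``.

    Returns ``(total_atomic_intervals, groups)`` where each group is
    ``(parameter_blocks, intervals_per_block)`` — i.e. ``a*b`` contributes
    ``a`` free parameters spanning ``b`` atomic intervals each.
    """
    groups: list[tuple[int, int]] = []
    total = 0
    for term in pattern.replace(" ", "").split("+"):
        if not term:
            raise ValueError(f"malformed pattern term in {pattern!r}: empty term")
        parts = term.split("*")
        if len(parts) > 2 or not all(p.isdigit() for p in parts):
            raise ValueError(f"malformed pattern term {term!r} (expected 'a' or 'a*b')")
        a = int(parts[0])
        b = int(parts[1]) if len(parts) == 2 else 1
        if a < 1 or b < 1:
            raise ValueError(f"malformed pattern term {term!r}: counts must be >= 1")
        groups.append((a, b))
        total += a * b
    return total, groups
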