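"""Outcome classification and pattern-oriented validation statistics.

A run counts as *cooperative* only under the strict reading: a group
agreement existed every tick and every agent took the agreed share every
tick (equal sharing throughout).  Exploitation is classed by where the mean
post-harvest stock sits relative to the maximum-regeneration plateau of the
growth table: below it (over-exploitation), above it (under-exploitation) or
on it (optimal).  Deviation series compare each tick's harvest with what the
long-run-optimal policy would have taken at the realized stock, and the
learning trend is the least-squares slope of the absolute deviation over
ticks (negative = the group moves toward optimal harvesting).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import math

import numpy as np
import pandas as pd

from .resource import RegenerationTable, msy, optimal_action_map, optimal_policy
from .simulation import RunResult

__all__ = [
    "Classification",
    "classify_cooperation",
    "classify_exploitation",
    "classify_run",
    "config_cooperative",
    "deviation_series",
    "distance_from_optimal",
    "learning_trend",
    "pattern_check",
    "DEFAULT_EXPLOITATION_TOLERANCE",
    "DEFAULT_COOPERATIVE_FRACTION",
]

DEFAULT_EXPLOITATION_TOLERANCE = 2.0
DEFAULT_COOPERATIVE_FRACTION = 0.76


@dataclass(frozen=True)
class Classification:
    """Run-level outcome labels."""

    run_cooperative: bool
    exploitation_class: str  # 'over' | 'under' | 'optimal'
    learning_trend: float


def classify_cooperation(run: RunResult) -> bool:
    """True iff an agreement existed and every agent chose it, every tick."""
    return run.agreement_every_tick() and run.all_chose_group()


def classify_exploitation(
    run: RunResult,
    table: RegenerationTable,
    tolerance: float = DEFAULT_EXPLOITATION_TOLERANCE,
) -> str:
    """Class of the mean post-harvest stock relative to the MSY plateau.

    The first tick is excluded: drawing the virgin stock down to the plateau
    is part of every sensible path, so only the maintained level counts.
    """
    _, (lo, hi) = msy(table)
    p = run.post_harvest_stock
    m = float(p[1:].mean()) if len(p) > 1 else float(p.mean())
    if m < lo - tolerance:
        return "over"
    if m > hi + tolerance:
        return "under"
    return "optimal"


def deviation_series(run: RunResult, table: RegenerationTable) -> np.ndarray:
    """Per-tick total harvest minus the optimal harvest at the realized stock.

    Positive values over-harvest relative to the long-run-optimal policy,
    negative values under-harvest.  Non-integer stocks are floored for the
    optimal-action lookup.
    """
    act = optimal_action_map(table)
    dev = np.empty(run.n_ticks)
    for i, t in enumerate(run.ticks):
        s = min(int(math.floor(t.stock_before)), table.capacity)
        dev[i] = float(t.realized_extraction.sum()) - act[s]
    return dev


@lru_cache(maxsize=64)
def _optimal_reported_path(
    table: RegenerationTable, initial_stock: int, n_ticks: int
) -> tuple[float, ...]:
    from .resource import step

    seq = optimal_policy(table, initial_stock, n_ticks)
    s = float(initial_stock)
    opt = []
    for e in seq:
        s = step(table, s, e)
        opt.append(s)
    return tuple(opt)


def distance_from_optimal(run: RunResult, table: RegenerationTable) -> float:
    """Mean absolute gap between the reported stock and the optimal path.

    The optimal path is the reported-stock trajectory of the
    long-run-optimal policy started from the same initial stock.
    """
    opt = _optimal_reported_path(table, int(run.config.initial_stock), run.n_ticks)
    return float(np.abs(run.reported_stock - np.asarray(opt)).mean())


def learning_trend(deviations: np.ndarray) -> float:
    """Least-squares slope of |deviation| against tick index."""
    d = np.abs(np.asarray(deviations, dtype=float))
    if d.size < 2:
        raise ValueError("learning trend needs at least two ticks")
    t = np.arange(d.size)
    return float(np.polyfit(t, d, 1)[0])


def classify_run(run: RunResult, table: RegenerationTable) -> Classification:
    dev = deviation_series(run, table)
    return Classification(
        run_cooperative=classify_cooperation(run),
        exploitation_class=classify_exploitation(run, table),
        learning_trend=learning_trend(dev),
    )


def config_cooperative(
    cooperative_flags: np.ndarray | list[bool],
    threshold: float = DEFAULT_COOPERATIVE_FRACTION,
) -> bool:
    """Config-level cooperation: the fraction of fully cooperative runs
    reaches ``threshold``."""
    flags = np.asarray(cooperative_flags, dtype=bool)
    if flags.size == 0:
        return False
    return bool(flags.mean() >= threshold)


def pattern_check(sweep_results: pd.DataFrame) -> dict[str, bool]:
    """Pattern-oriented validation of a sweep.

    a) both cooperative and non-cooperative runs occur;
    b) over-, under- and optimal exploitation all occur;
    c) all three exploitation classes occur among cooperative runs.
    """
    if sweep_results is None or len(sweep_results) == 0:
        return {"a": False, "b": False, "c": False}
    coop = sweep_results["cooperative"].astype(bool)
    classes = set(sweep_results["exploitation_class"])
    coop_classes = set(sweep_results.loc[coop, "exploitation_class"])
    return {
        "a": bool(coop.any() and (~coop).any()),
        "b": classes >= {"over", "under", "optimal"},
        "c": coop_classes >= {"over", "under", "optimal"},
    }
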