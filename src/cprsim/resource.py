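"""Renewable-resource dynamics: a stepwise discrete logistic growth model.

The resource is a stock of at most ``capacity`` units.  Each tick the group
harvests, and the post-harvest stock regenerates by an amount read from a
stepwise table: regeneration is piecewise constant on consecutive bins of
``bin_width`` stock units, zero below a minimum viable stock and zero at (or
above) carrying capacity.  The default table is a binned discrete logistic
curve with capacity 50, viability threshold 5, 5-unit bins and a maximum
sustainable yield (MSY) of 9 units on stocks 25-29.

The module also provides an optimal-policy oracle: a dynamic program over
integer stock states that maximises long-run per-tick harvest (the game end
is treated as unknown, so there is no terminal liquidation), with ties broken
in favour of harvesting earlier.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

__all__ = [
    "RegenerationTable",
    "build_default_table",
    "build_logistic_table",
    "regen",
    "step",
    "optimal_policy",
    "optimal_action_map",
    "msy",
    "recovery_stock",
    "load_table_csv",
]

DEFAULT_CAPACITY = 50
DEFAULT_MIN_REGEN_STOCK = 5
DEFAULT_BIN_WIDTH = 5
DEFAULT_GROWTH_RATE = 0.72


@dataclass(frozen=True)
class RegenerationTable:
    """Stepwise map from stock size to per-tick regeneration.

    ``regen_by_bin[i]`` is the regeneration for stocks in
    ``[min_regen_stock + i*bin_width, min_regen_stock + (i+1)*bin_width)``;
    stocks below ``min_regen_stock`` or at/above ``capacity`` do not
    regenerate.  The table must be unimodal with a unique maximum bin and
    contain only non-negative integers.
    """

    capacity: int = DEFAULT_CAPACITY
    min_regen_stock: int = DEFAULT_MIN_REGEN_STOCK
    bin_width: int = DEFAULT_BIN_WIDTH
    regen_by_bin: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.capacity <= self.min_regen_stock:
            raise ValueError("capacity must exceed min_regen_stock")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n_bins = (self.capacity - self.min_regen_stock) // self.bin_width + 1
        if len(self.regen_by_bin) != n_bins:
            raise ValueError(
                f"expected {n_bins} bin values for stocks "
                f"{self.min_regen_stock}..{self.capacity}, got {len(self.regen_by_bin)}"
            )
        vals = self.regen_by_bin
        if any(v < 0 or v != int(v) for v in vals):
            raise ValueError("regeneration values must be non-negative integers")
        peak = max(vals)
        if peak <= 0:
            raise ValueError("table must have positive regeneration somewhere")
        if vals.count(peak) != 1:
            raise ValueError("table must be unimodal with a unique maximum bin")
        imax = vals.index(peak)
        if any(vals[i] > vals[i + 1] for i in range(imax)) or any(
            vals[i] < vals[i + 1] for i in range(imax, len(vals) - 1)
        ):
            raise ValueError("table must be unimodal (rise then fall)")

    @property
    def bin_edges(self) -> tuple[int, ...]:
        """Lower edge of each bin, from ``min_regen_stock`` to ``capacity``."""
        return tuple(
            self.min_regen_stock + i * self.bin_width for i in range(len(self.regen_by_bin))
        )

    def max_bin(self) -> tuple[int, int]:
        """Inclusive stock interval ``[lo, hi]`` of the maximum-regeneration bin."""
        i = self.regen_by_bin.index(max(self.regen_by_bin))
        lo = self.min_regen_stock + i * self.bin_width
        return lo, lo + self.bin_width - 1


def build_logistic_table(
    capacity: int = DEFAULT_CAPACITY,
    min_regen_stock: int = DEFAULT_MIN_REGEN_STOCK,
    bin_width: int = DEFAULT_BIN_WIDTH,
    growth_rate: float = DEFAULT_GROWTH_RATE,
) -> RegenerationTable:
    """Bin a discrete logistic growth curve into a stepwise table.

    Regeneration for the bin whose lower edge is ``s`` is
    ``floor(growth_rate * s * (1 - s / capacity))``, so growth vanishes at the
    carrying capacity and below the minimum viable stock.
    """
    edges = range(min_regen_stock, capacity + 1, bin_width)
    vals = tuple(
        int(math.floor(growth_rate * s * (1.0 - s / capacity))) for s in edges
    )
    return RegenerationTable(capacity, min_regen_stock, bin_width, vals)


def build_default_table() -> RegenerationTable:
    """The default table: capacity 50, threshold 5, 5-unit bins, MSY 9 on 25-29."""
    return build_logistic_table()


def regen(table: RegenerationTable, stock: float) -> int:
    """Per-tick regeneration at the given stock (binned by ``floor(stock)``)."""
    if stock < 0:
        raise ValueError(f"negative stock {stock!r}: corrupted state")
    s = math.floor(stock)
    if s < table.min_regen_stock or s >= table.capacity:
        return 0
    i = (s - table.min_regen_stock) // table.bin_width
    return table.regen_by_bin[i]


def step(table: RegenerationTable, stock: float, total_extraction: float) -> float:
    """One ecological tick: harvest (capped at the stock), then regenerate.

    The result is clamped to ``[0, capacity]``.  Over-demand is rationed by
    the simulation before this point; the cap here is defensive.
    """
    e = min(total_extraction, stock)
    p = stock - e
    return min(float(table.capacity), p + regen(table, p))


def msy(table: RegenerationTable) -> tuple[int, tuple[int, int]]:
    """Maximum sustainable yield and the stock bin attaining it."""
    return max(table.regen_by_bin), table.max_bin()


def recovery_stock(table: RegenerationTable) -> int:
    """Smallest integer stock from which harvesting the MSY leaves the
    post-harvest stock inside the maximum-regeneration bin (the stock at
    which the optimal policy resumes extraction after letting the resource
    recover)."""
    y, (lo, hi) = msy(table)
    for s in range(table.capacity + 1):
        if lo <= s - y <= hi:
            return s
    raise ValueError("table admits no sustainable-cycle stock")


def _deep_action_table(table: RegenerationTable, lookahead: int) -> list[int]:
    """Stationary long-run-optimal action per integer stock state.

    Backward induction maximising total harvest over ``lookahead`` ticks with
    zero terminal value; for a lookahead much longer than the transient to
    the sustainable cycle, the deepest table is the policy that maximises
    long-run per-tick yield.  Ties are broken toward larger extraction, which
    yields the lexicographically earliest-harvesting optimal sequence.
    """
    cap = table.capacity
    nxt = [[int(step(table, s, e)) for e in range(s + 1)] for s in range(cap + 1)]
    v = [0] * (cap + 1)
    act = [0] * (cap + 1)
    for _ in range(lookahead):
        v_new = [0] * (cap + 1)
        for s in range(cap + 1):
            best_val, best_e = -1, 0
            for e in range(s + 1):
                val = e + v[nxt[s][e]]
                if val > best_val or (val == best_val and e > best_e):
                    best_val, best_e = val, e
            v_new[s], act[s] = best_val, best_e
        v = v_new
    return act


def optimal_policy(
    table: RegenerationTable, initial_stock: int, horizon: int, tail: int = 60
) -> tuple[int, ...]:
    """Per-tick group extraction sequence of the long-run-optimal policy.

    Dynamic programming over integer stock states (at most ``capacity + 1``
    states, ``capacity + 1`` actions per state).  The game end is treated as
    unknown: the lookahead extends ``tail`` ticks past the horizon so the
    reported sequence never liquidates the stock.
    """
    if not 0 <= initial_stock <= table.capacity:
        raise ValueError("initial_stock outside [0, capacity]")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    act = _deep_action_table(table, horizon + tail)
    seq = []
    s = int(initial_stock)
    for _ in range(horizon):
        e = act[s]
        seq.append(e)
        s = int(step(table, s, e))
    return tuple(seq)


@lru_cache(maxsize=16)
def optimal_action_map(table: RegenerationTable, tail: int = 60) -> tuple[int, ...]:
    """Long-run-optimal extraction for every integer stock 0..capacity."""
    return tuple(_deep_action_table(table, tail))


def load_table_csv(path: str | Path) -> RegenerationTable:
    """Load a regeneration table from a two-column CSV.

    Expected header ``bin_lower_edge,regeneration``; one row per bin, edges
    consecutive with a constant width, last edge at the carrying capacity.
    """
    rows: list[tuple[int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != [
            "bin_lower_edge",
            "regeneration",
        ]:
            raise ValueError(
                "regeneration CSV must have header 'bin_lower_edge,regeneration'"
            )
        for row in reader:
            rows.append((int(row["bin_lower_edge"]), int(row["regeneration"])))
    if len(rows) < 2:
        raise ValueError("regeneration CSV needs at least two bins")
    edges = [e for e, _ in rows]
    widths = {b - a for a, b in zip(edges, edges[1:])}
    if len(widths) != 1:
        raise ValueError("bin edges must be evenly spaced and ascending")
    width = widths.pop()
    if width <= 0:
        raise ValueError("bin edges must be ascending")
    return RegenerationTable(
        capacity=edges[-1],
        min_regen_stock=edges[0],
        bin_width=width,
        regen_by_bin=tuple(v for _, v in rows),
    )
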