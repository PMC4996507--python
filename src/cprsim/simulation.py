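"""Tick orchestration, 14-tick runs, replication batches, scenarios and sweeps.

A run starts from a full stock (50 units) and iterates a fixed per-tick
order: speak-up draws, group-agreement formation, social knowledge updating,
extraction computation, the cooperate/defect choice, rationed harvesting,
regeneration, and finally ecological feedback on confidence and trust.  All
stochasticity in a run flows through a single numpy generator in this fixed
order (agents iterated by ascending id), so a run is bit-reproducible from
its seed.

The seven published group compositions (scenario set I: the effect of
informed, confident agents among uninformed ones; set II: opposing speakers)
are provided by :func:`scenario`, and :func:`sweep` crosses factor levels of
trust, social preferences, social skills, knowledge and confidence into a
factorial verification grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agents import (
    AgentState,
    BehaviorParams,
    GroupState,
    choose_extraction,
    decide_speak,
    expected_stock,
    form_group_knowledge,
    group_extraction,
    individual_extraction,
    update_confidence_trust,
    update_knowledge,
)
from .resource import RegenerationTable, build_default_table, step

__all__ = [
    "AgentSpec",
    "ScenarioConfig",
    "TickRecord",
    "RunResult",
    "BatchSummary",
    "tick",
    "run",
    "batch",
    "scenario",
    "default_grid",
    "sweep",
    "INFORMED_RANGE",
    "UNINFORMED_RANGE",
    "TRUST_RANGE_HIGH",
    "TRUST_RANGE_ROBUSTNESS",
    "CONFIDENCE_HIGH",
    "CONFIDENCE_LOW",
]

INFORMED_RANGE = (25, 29)
UNINFORMED_RANGE = (10, 24)
TRUST_RANGE_HIGH = (0.66, 0.94)
TRUST_RANGE_ROBUSTNESS = (0.66, 0.80)
CONFIDENCE_HIGH = 0.8
CONFIDENCE_LOW = 0.2


@dataclass(frozen=True)
class AgentSpec:
    """Initialization spec for one agent.

    Knowledge is drawn uniformly over the integers of ``knowledge_range``
    (inclusive); trust uniformly on the real interval ``trust_range``."""

    knowledge_range: tuple[int, int] = UNINFORMED_RANGE
    confidence: float = CONFIDENCE_LOW
    social_skills: float = 1.0
    social_preferences: bool = True
    trust_range: tuple[float, float] = TRUST_RANGE_HIGH


@dataclass(frozen=True)
class ScenarioConfig:
    """A 4-agent group composition plus run settings."""

    scenario_id: str
    agent_specs: tuple[AgentSpec, ...]
    n_ticks: int = 14
    initial_stock: float = 50.0
    replications: int = 5000
    base_seed: int = 0

    @property
    def n_agents(self) -> int:
        return len(self.agent_specs)

    def validate(self) -> list[str]:
        """Return all invariant violations (empty when valid)."""
        problems = []
        if self.n_agents < 1:
            problems.append("at least one agent is required")
        if self.n_ticks < 1:
            problems.append("n_ticks must be >= 1")
        if self.replications < 1:
            problems.append("replications must be >= 1")
        if not 0 <= self.initial_stock <= 50:
            problems.append("initial_stock must lie in [0, 50]")
        for i, spec in enumerate(self.agent_specs):
            lo, hi = spec.knowledge_range
            if lo > hi or lo < 5 or hi > 50:
                problems.append(f"agent {i}: knowledge_range {spec.knowledge_range} invalid")
            tlo, thi = spec.trust_range
            if tlo > thi or tlo < 0 or thi > 1:
                problems.append(f"agent {i}: trust_range {spec.trust_range} invalid")
            if not 0 <= spec.confidence <= 1:
                problems.append(f"agent {i}: confidence {spec.confidence} outside [0, 1]")
            if not 0 <= spec.social_skills <= 1:
                problems.append(f"agent {i}: social_skills {spec.social_skills} outside [0, 1]")
        return problems


@dataclass
class TickRecord:
    """Everything observable about one tick (arrays indexed by agent id)."""

    stock_before: float
    group_knowledge: float | None
    group_total: float
    group_share: float
    knowledge: np.ndarray
    confidence: np.ndarray
    trust: np.ndarray
    spoke: np.ndarray
    chose_group: np.ndarray
    chosen_extraction: np.ndarray
    realized_extraction: np.ndarray
    expected_stock: np.ndarray
    post_harvest_stock: float
    reported_stock: float


@dataclass
class RunResult:
    """Full trajectories of one run."""

    config: ScenarioConfig
    seed: int
    ticks: list[TickRecord]

    @property
    def n_ticks(self) -> int:
        return len(self.ticks)

    @property
    def reported_stock(self) -> np.ndarray:
        return np.array([t.reported_stock for t in self.ticks])

    @property
    def post_harvest_stock(self) -> np.ndarray:
        return np.array([t.post_harvest_stock for t in self.ticks])

    @property
    def total_extraction(self) -> np.ndarray:
        return np.array([float(t.realized_extraction.sum()) for t in self.ticks])

    @property
    def stock_before(self) -> np.ndarray:
        return np.array([t.stock_before for t in self.ticks])

    def agreement_every_tick(self) -> bool:
        return all(t.group_knowledge is not None for t in self.ticks)

    def all_chose_group(self) -> bool:
        return all(bool(t.chose_group.all()) for t in self.ticks)


def _init_agents(config: ScenarioConfig, rng: np.random.Generator) -> list[AgentState]:
    agents = []
    for i, spec in enumerate(config.agent_specs):
        lo, hi = spec.knowledge_range
        k = float(rng.integers(lo, hi + 1))
        tlo, thi = spec.trust_range
        tr = float(tlo + (thi - tlo) * rng.random())
        agents.append(
            AgentState(
                agent_id=i,
                individual_knowledge=k,
                confidence=spec.confidence,
                trust=tr,
                social_skills=spec.social_skills,
                social_preferences=spec.social_preferences,
            )
        )
    return agents


def tick(
    agents: list[AgentState],
    stock: float,
    table: RegenerationTable,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> tuple[float, TickRecord]:
    """Execute one round and return (new stock, record of the round).

    Fixed order: speak-up draws -> group knowledge -> knowledge updates ->
    group extraction level -> individual extraction levels (post-update
    knowledge) -> cooperate/defect choices -> proportional rationing of
    over-demand -> harvest and regeneration -> expectation-based
    confidence/trust feedback.  Agents are always iterated by ascending id.
    """
    n = len(agents)
    stock_before = stock

    for a in agents:
        decide_speak(a, rng)
    gk = form_group_knowledge(
        [(a.individual_knowledge, a.confidence) for a in agents if a.spoke]
    )
    for a in agents:
        update_knowledge(a, gk, params, rng)

    if gk is not None:
        group_total, group_share = group_extraction(gk, stock, n)
    else:
        group_total, group_share = 0.0, None

    individual_levels = [individual_extraction(a, stock, n, params) for a in agents]
    chosen = np.empty(n)
    for a, lvl in zip(agents, individual_levels):
        chosen[a.agent_id], _ = choose_extraction(a, group_share, lvl, params, rng)

    demand = float(chosen.sum())
    if demand > stock and demand > 0:
        realized = chosen * (stock / demand)
    else:
        realized = chosen.copy()

    post_harvest = max(0.0, stock - float(realized.sum()))
    new_stock = step(table, stock, float(realized.sum()))

    expected = np.full(n, np.nan)
    if gk is not None:
        for a in agents:
            expected[a.agent_id] = expected_stock(
                a, stock, a.chosen_extraction, group_share, n, table, params
            )
            update_confidence_trust(a, expected[a.agent_id], new_stock, params, table.capacity)

    for a in agents:
        a.check_invariants(table.capacity)

    rec = TickRecord(
        stock_before=stock_before,
        group_knowledge=gk,
        group_total=group_total if gk is not None else 0.0,
        group_share=group_share if gk is not None else 0.0,
        knowledge=np.array([a.individual_knowledge for a in agents]),
        confidence=np.array([a.confidence for a in agents]),
        trust=np.array([a.trust for a in agents]),
        spoke=np.array([a.spoke for a in agents]),
        chose_group=np.array([a.chose_group for a in agents]),
        chosen_extraction=chosen,
        realized_extraction=realized,
        expected_stock=expected,
        post_harvest_stock=post_harvest,
        reported_stock=new_stock,
    )
    return new_stock, rec


def run(
    config: ScenarioConfig,
    table: RegenerationTable | None = None,
    params: BehaviorParams | None = None,
    seed: int | None = None,
) -> RunResult:
    """Execute one full game; identical seeds give identical results."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    table = table or build_default_table()
    params = params or BehaviorParams()
    seed = config.base_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    agents = _init_agents(config, rng)
    stock = float(config.initial_stock)
    records = []
    for _ in range(config.n_ticks):
        stock, rec = tick(agents, stock, table, params, rng)
        records.append(rec)
    return RunResult(config=config, seed=seed, ticks=records)


@dataclass
class BatchSummary:
    """Cross-replication summary of one configuration."""

    scenario_id: str
    replications: int
    mean_reported_stock: np.ndarray  # per tick
    mean_post_harvest_stock: np.ndarray  # per tick
    cooperative_fraction: float
    exploitation_fractions: dict[str, float]


def batch(
    config: ScenarioConfig,
    table: RegenerationTable | None = None,
    params: BehaviorParams | None = None,
) -> tuple[list[RunResult], BatchSummary]:
    """Run ``config.replications`` runs seeded ``base_seed + index``."""
    from .analysis import classify_cooperation, classify_exploitation

    table = table or build_default_table()
    params = params or BehaviorParams()
    results = [
        run(config, table, params, seed=config.base_seed + i)
        for i in range(config.replications)
    ]
    reported = np.vstack([r.reported_stock for r in results])
    post = np.vstack([r.post_harvest_stock for r in results])
    coop = np.array([classify_cooperation(r) for r in results])
    classes = [classify_exploitation(r, table) for r in results]
    frac = {c: classes.count(c) / len(classes) for c in ("over", "under", "optimal")}
    summary = BatchSummary(
        scenario_id=config.scenario_id,
        replications=config.replications,
        mean_reported_stock=reported.mean(axis=0),
        mean_post_harvest_stock=post.mean(axis=0),
        cooperative_fraction=float(coop.mean()),
        exploitation_fractions=frac,
    )
    return results, summary


def scenario(
    scenario_id: int,
    robustness: bool = False,
    replications: int = 5000,
    base_seed: int = 0,
    uninformed_range: tuple[int, int] = UNINFORMED_RANGE,
) -> ScenarioConfig:
    """The seven published 4-agent group compositions.

    Set I (1-3, everyone speaks): scenario 1 is four uninformed low-confidence
    agents; 2 swaps one for an informed high-confidence agent; 3 has two of
    each.  Set II (4-7, one informed agent and three uninformed): 4 has a
    single informed high-confidence speaker; 5 adds an uninformed
    low-confidence speaker; 6 makes that opposing speaker confident; 7
    additionally makes the informed speaker unconfident.  Non-speakers are
    always uninformed with low confidence; every agent has social preferences
    and draws its initial trust from [0.66, 0.94] (upper bound 0.80 under the
    increased-social-uncertainty robustness variant).
    """
    trust = TRUST_RANGE_ROBUSTNESS if robustness else TRUST_RANGE_HIGH

    def agent(informed: bool, confident: bool, speaks: bool) -> AgentSpec:
        return AgentSpec(
            knowledge_range=INFORMED_RANGE if informed else uninformed_range,
            confidence=CONFIDENCE_HIGH if confident else CONFIDENCE_LOW,
            social_skills=1.0 if speaks else 0.0,
            social_preferences=True,
            trust_range=trust,
        )

    uninformed_speaker = agent(False, False, True)
    silent = agent(False, False, False)
    compositions: dict[int, tuple[AgentSpec, ...]] = {
        1: (uninformed_speaker,) * 4,
        2: (agent(True, True, True),) + (uninformed_speaker,) * 3,
        3: (agent(True, True, True),) * 2 + (uninformed_speaker,) * 2,
        4: (agent(True, True, True),) + (silent,) * 3,
        5: (agent(True, True, True), uninformed_speaker) + (silent,) * 2,
        6: (agent(True, True, True), agent(False, True, True)) + (silent,) * 2,
        7: (agent(True, False, True), agent(False, True, True)) + (silent,) * 2,
    }
    if scenario_id not in compositions:
        raise ValueError(f"unknown scenario id {scenario_id!r}; expected 1..7")
    sid = f"S{scenario_id}" + ("r" if robustness else "")
    return ScenarioConfig(
        scenario_id=sid,
        agent_specs=compositions[scenario_id],
        replications=replications,
        base_seed=base_seed,
    )


# Factor levels of the default verification grid.  Knowledge levels place the
# group's perceived optimum below, around, or above the MSY plateau; all are
# 15-integer-wide so every group contains genuine disagreement (and hence
# temptation to defect).  Crossing them with trust, preference, speaking and
# confidence levels and two group templates (aligned: four agents from the
# cell's range; mixed: two cell-level agents plus two uninformed
# low-confidence agents) spans cooperative and non-cooperative outcomes and
# all three exploitation classes.
DEFAULT_GRID: dict[str, Sequence] = {
    "knowledge": ["uninformed", "midrange", "cautious"],
    "confidence": [CONFIDENCE_LOW, CONFIDENCE_HIGH],
    "social_skills": [0.0, 0.5, 1.0],
    "trust": ["low", "medium", "high"],
    "social_preferences": [True, False],
    "template": ["aligned", "mixed"],
}

KNOWLEDGE_RANGES = {
    "uninformed": UNINFORMED_RANGE,
    "midrange": (20, 34),
    "cautious": (30, 44),
}
TRUST_RANGES = {
    "low": (0.0, 0.33),
    "medium": (0.33, 0.66),
    "high": TRUST_RANGE_HIGH,
}


def default_grid() -> list[dict]:
    """The default factorial grid as a list of factor-level cells."""
    keys = list(DEFAULT_GRID)
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(DEFAULT_GRID[k] for k in keys))
    ]


def config_from_cell(
    cell: Mapping, replications: int, base_seed: int, config_id: str
) -> ScenarioConfig:
    """Build a ScenarioConfig from one grid cell."""
    kr = KNOWLEDGE_RANGES[cell["knowledge"]]
    tr = TRUST_RANGES[cell["trust"]]
    base = AgentSpec(
        knowledge_range=kr,
        confidence=cell["confidence"],
        social_skills=cell["social_skills"],
        social_preferences=cell["social_preferences"],
        trust_range=tr,
    )
    if cell["template"] == "mixed":
        partner = replace(
            base,
            knowledge_range=UNINFORMED_RANGE,
            confidence=CONFIDENCE_LOW,
        )
        specs = (base,) * 2 + (partner,) * 2
    else:
        specs = (base,) * 4
    return ScenarioConfig(
        scenario_id=config_id,
        agent_specs=specs,
        replications=replications,
        base_seed=base_seed,
    )


def sweep(
    grid: Sequence[Mapping] | None = None,
    replications: int = 100,
    base_seed: int = 0,
    table: RegenerationTable | None = None,
    params: BehaviorParams | None = None,
) -> pd.DataFrame:
    """Run a batch per grid cell; long-format one row per (config, run).

    Columns: the factor levels, config_id, run index, run-level cooperation,
    exploitation class, learning slope and mean post-harvest stock.  Each
    cell's runs are seeded from ``base_seed`` plus a per-cell offset so cells
    are independent and the whole sweep is reproducible.
    """
    from .analysis import classify_cooperation, classify_exploitation, deviation_series, learning_trend

    if grid is None:
        grid = default_grid()
    if len(grid) == 0:
        raise ValueError("empty grid")
    table = table or build_default_table()
    params = params or BehaviorParams()
    rows = []
    for ci, cell in enumerate(grid):
        config = config_from_cell(
            cell, replications, base_seed + ci * replications, f"cfg{ci:04d}"
        )
        results, _ = batch(config, table, params)
        for ri, r in enumerate(results):
            dev = deviation_series(r, table)
            rows.append(
                {
                    **cell,
                    "config_id": config.scenario_id,
                    "run": ri,
                    "cooperative": classify_cooperation(r),
                    "exploitation_class": classify_exploitation(r, table),
                    "learning_slope": learning_trend(dev),
                    "mean_post_harvest_stock": float(r.post_harvest_stock[1:].mean()),
                }
            )
    return pd.DataFrame(rows)
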