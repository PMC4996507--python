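"""Agent state and per-tick decision operators.

Each of the four harvesters carries three cognitive attributes — *individual
knowledge* (its perceived harvest-optimal stock size), *confidence* in that
knowledge, and *trust* that the others will act as agreed — plus two fixed
traits: *social skills* (the probability of speaking up during agreement
formation) and *social preferences* (a preference for equal sharing, making
the agent a conditional cooperator).

The tick-level operators implemented here:

* ``decide_speak`` — Bernoulli speak-up draw with probability social_skills.
* ``form_group_knowledge`` — confidence-weighted mean of the speakers'
  knowledge; the group agreement proposes harvesting the surplus above it.
* ``update_knowledge`` — probabilistic partial adoption of the group view,
  gated and scaled by (1 - confidence): unconfident agents learn socially.
* ``individual_extraction`` / ``group_extraction`` — surplus above the
  perceived (individual / group) optimum, shared equally; agents without
  social preferences claim a greed-inflated share.
* ``choose_extraction`` — cooperate (take the group share) or defect (take
  the individual level); defection requires temptation (individual > group)
  and becomes likelier the lower the trust and the larger the temptation gap.
* ``expected_stock`` / ``update_confidence_trust`` — ecological feedback:
  agents project next tick's stock assuming compliance, then raise
  confidence and trust on a match, and lower them in proportion to the
  deviation (a shortfall also erodes trust; an overshoot only dents
  confidence, since no one can have over-harvested).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .resource import RegenerationTable, regen, step

__all__ = [
    "KNOWLEDGE_MIN",
    "KNOWLEDGE_MAX",
    "AgentState",
    "GroupState",
    "BehaviorParams",
    "decide_speak",
    "form_group_knowledge",
    "update_knowledge",
    "individual_extraction",
    "group_extraction",
    "choose_extraction",
    "expected_stock",
    "update_confidence_trust",
]

KNOWLEDGE_MIN = 5.0
KNOWLEDGE_MAX = 50.0


def _clamp(x: float, lo: float, hi: float) -> float:
    return lo if x < lo else hi if x > hi else x


@dataclass
class AgentState:
    """One agent's cognitive state, fixed traits and per-tick decisions."""

    agent_id: int
    individual_knowledge: float  # perceived optimal stock size, in [5, capacity]
    confidence: float  # in [0, 1]
    trust: float  # in [0, 1]
    social_skills: float  # speaking probability, in [0, 1]
    social_preferences: bool
    # per-tick scratch
    spoke: bool = False
    chose_group: bool = False
    chosen_extraction: float = 0.0
    expected_stock: float = field(default=float("nan"))

    def check_invariants(self, capacity: float) -> None:
        if not KNOWLEDGE_MIN <= self.individual_knowledge <= capacity:
            raise ValueError(
                f"agent {self.agent_id}: knowledge {self.individual_knowledge} "
                f"outside [{KNOWLEDGE_MIN}, {capacity}]"
            )
        for name in ("confidence", "trust", "social_skills"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"agent {self.agent_id}: {name} {v} outside [0, 1]")
        if self.chosen_extraction < 0:
            raise ValueError(f"agent {self.agent_id}: negative extraction")


@dataclass(frozen=True)
class GroupState:
    """The group agreement of one tick (absent when nobody spoke)."""

    group_knowledge: float | None
    group_extraction_total: float
    group_share: float


@dataclass(frozen=True)
class BehaviorParams:
    """Free behavioral constants of the model.

    update_probability : float in [0, 1]
        Base probability that an agent revisits its knowledge after an
        agreement; the effective per-tick probability is
        ``update_probability * (1 - confidence)``.
    greed_factor : float >= 1
        Multiplier on the equal share claimed by agents without social
        preferences (capped at the whole surplus).
    reward_increment : float (alpha)
        Additive gain to confidence and trust when the realized stock matches
        the expectation.
    penalty_rate : float (beta)
        Loss per unit of normalized deviation: a deviation of ``d`` stock
        units costs ``beta * |d| / capacity`` confidence (and trust, when the
        stock falls short of the expectation).
    match_tolerance : float
        Deviation (stock units) below which feedback counts as a match.
    temptation_scale : float
        Extraction gap (resource units) at which a tempted conditional
        cooperator's temptation weight saturates at 1; smaller gaps weigh in
        proportionally less, so negligible temptations barely endanger
        cooperation.
    uncertainty_gain, uncertainty_power : float
        Shape of the trust response.  Writing ``u = 1 - trust`` for the
        agent's social uncertainty, a tempted conditional cooperator defects
        with probability ``w(gap) * min(1, uncertainty_gain * u**power)``:
        zero at full trust, saturated under deep distrust, and super-linearly
        sensitive in between, so cooperation collapses quickly once trust
        slips below the high range.
    belief_shifted_expectation : bool
        If True, agents evaluate regeneration as if the growth curve peaked
        at their own perceived optimum (the table is re-centered by the gap
        between their knowledge and the true peak); by default agents know
        the true, publicly displayed growth curve.
    """

    update_probability: float = 0.5
    greed_factor: float = 2.0
    reward_increment: float = 0.2
    penalty_rate: float = 0.5
    match_tolerance: float = 0.5
    temptation_scale: float = 3.5
    uncertainty_gain: float = 12.0
    uncertainty_power: float = 3.0
    belief_shifted_expectation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.update_probability <= 1.0:
            raise ValueError("update_probability must lie in [0, 1]")
        if self.greed_factor < 1.0:
            raise ValueError("greed_factor must be >= 1")
        for name in (
            "reward_increment",
            "penalty_rate",
            "match_tolerance",
            "temptation_scale",
            "uncertainty_gain",
            "uncertainty_power",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def decide_speak(agent: AgentState, rng: np.random.Generator) -> bool:
    """Bernoulli speak-up draw with probability ``social_skills``."""
    agent.spoke = bool(rng.random() < agent.social_skills)
    return agent.spoke


def form_group_knowledge(
    speakers: Sequence[tuple[float, float]],
) -> float | None:
    """Confidence-weighted mean of the speakers' (knowledge, confidence).

    Returns None when nobody spoke.  If every speaking confidence is zero the
    weighted mean is undefined; the unweighted mean (the equal-weight limit)
    is returned instead.
    """
    if not speakers:
        return None
    wsum = sum(c for _, c in speakers)
    if wsum <= 0.0:
        return sum(k for k, _ in speakers) / len(speakers)
    return sum(k * c for k, c in speakers) / wsum


def update_knowledge(
    agent: AgentState,
    group_knowledge: float | None,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> float:
    """Possibly move the agent's knowledge part-way toward the group view.

    Fires with probability ``update_probability * (1 - confidence)``; when it
    fires the knowledge moves a fraction ``(1 - confidence)`` of the gap
    toward the group knowledge (never past it), then is clamped to the valid
    knowledge range.  Confident agents thus neither revisit nor move much.
    """
    if group_knowledge is None:
        return agent.individual_knowledge
    gate = params.update_probability * (1.0 - agent.confidence)
    if gate > 0.0 and rng.random() < gate:
        k = agent.individual_knowledge
        k += (1.0 - agent.confidence) * (group_knowledge - k)
        agent.individual_knowledge = _clamp(k, KNOWLEDGE_MIN, KNOWLEDGE_MAX)
    return agent.individual_knowledge


def individual_extraction(
    agent: AgentState, stock: float, n_agents: int, params: BehaviorParams
) -> float:
    """The agent's own extraction target given its perceived optimum.

    The surplus above the perceived optimal stock is the total the agent
    thinks should be harvested; with social preferences it claims the equal
    share, without them a greed-inflated share (never more than the whole
    surplus)."""
    surplus = max(0.0, stock - agent.individual_knowledge)
    share = surplus / n_agents
    if agent.social_preferences:
        return share
    return min(surplus, params.greed_factor * share)


def group_extraction(
    group_knowledge: float, stock: float, n_agents: int
) -> tuple[float, float]:
    """Total agreed harvest (surplus above the group optimum) and equal share."""
    total = max(0.0, stock - group_knowledge)
    return total, total / n_agents


def choose_extraction(
    agent: AgentState,
    group_share: float | None,
    individual_level: float,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Choose between the agreed share and the agent's own extraction level.

    With no agreement the individual level is the only option.  When the
    agreed share is at least the individual level every agent takes it (it
    pays at least as well).  Otherwise the agent is tempted: a conditional
    cooperator (social preferences) defects with probability
    ``min(1, gap / temptation_scale) * min(1, uncertainty_gain *
    (1 - trust)**uncertainty_power)`` where ``gap`` is the payoff difference
    — both distrust and a material temptation are needed, and the trust
    response is steep so cooperation is safe only in the high-trust range.
    An agent without social preferences always takes its own level.
    """
    if group_share is None:
        agent.chose_group = False
        agent.chosen_extraction = individual_level
        return individual_level, False
    if group_share >= individual_level:
        agent.chose_group = True
        agent.chosen_extraction = group_share
        return group_share, True
    if agent.social_preferences:
        gap = individual_level - group_share
        if params.temptation_scale > 0.0:
            weight = min(1.0, gap / params.temptation_scale)
        else:
            weight = 1.0
        u = 1.0 - agent.trust
        p_defect = weight * min(1.0, params.uncertainty_gain * u**params.uncertainty_power)
        if rng.random() >= p_defect:
            agent.chose_group = True
            agent.chosen_extraction = group_share
            return group_share, True
    agent.chose_group = False
    agent.chosen_extraction = individual_level
    return individual_level, False


def expected_stock(
    agent: AgentState,
    stock: float,
    own_extraction: float,
    group_share: float,
    n_agents: int,
    table: RegenerationTable,
    params: BehaviorParams | None = None,
) -> float:
    """Stock the agent expects next tick: own plan plus compliant others.

    The agent assumes the other ``n_agents - 1`` members take exactly the
    agreed share, and projects the harvested stock through the growth curve.
    By default that is the true table (the growth chart is public); in
    belief-shifted mode the curve is re-centered on the agent's own perceived
    optimum, so disagreement with the true peak also produces ecological
    surprises.
    """
    planned = own_extraction + (n_agents - 1) * group_share
    if params is not None and params.belief_shifted_expectation:
        y, (lo, hi) = max(table.regen_by_bin), table.max_bin()
        center = (lo + hi) / 2.0
        offset = agent.individual_knowledge - center
        e = min(planned, stock)
        p = stock - e
        believed = regen(table, _clamp(p - offset, 0.0, float(table.capacity)))
        agent.expected_stock = min(float(table.capacity), p + believed)
    else:
        agent.expected_stock = step(table, stock, planned)
    return agent.expected_stock


def update_confidence_trust(
    agent: AgentState,
    expected: float,
    actual: float,
    params: BehaviorParams,
    capacity: float = 50.0,
) -> tuple[float, float]:
    """Ecological-feedback update of confidence and trust.

    Match (|deviation| within tolerance): both rise by ``reward_increment``.
    Stock above expectation: only confidence falls (nobody can have taken
    more than agreed from the agent's viewpoint, so trust is untouched).
    Stock below expectation: confidence and trust both fall.  Penalties are
    ``penalty_rate * |deviation| / capacity``, strictly increasing in the
    deviation; all values clamp to [0, 1].
    """
    if expected < 0 or actual < 0:
        raise ValueError("stock sizes must be non-negative")
    d = actual - expected
    if abs(d) <= params.match_tolerance:
        agent.confidence = _clamp(agent.confidence + params.reward_increment, 0.0, 1.0)
        agent.trust = _clamp(agent.trust + params.reward_increment, 0.0, 1.0)
    else:
        loss = params.penalty_rate * abs(d) / capacity
        agent.confidence = _clamp(agent.confidence - loss, 0.0, 1.0)
        if d < 0:
            agent.trust = _clamp(agent.trust - loss, 0.0, 1.0)
    return agent.confidence, agent.trust
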