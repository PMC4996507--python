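# Methods

This note documents the model implemented in `cprsim`, the free parameters
and how their defaults were fixed, what the scenario generator and the
factorial grid emulate, and the numerical and classification choices that
shape the reported outcomes.

## Resource dynamics

The resource is a discrete logistic stock binned into 5-unit steps:
regeneration for the bin with lower edge `s` is
`floor(0.72 · s · (1 − s/50))`, zero below the minimum viable stock (5) and
at carrying capacity (50). This reconstruction reproduces every printed
property of the growth chart used in the laboratory experiments the model
emulates: capacity 50, viability threshold 5, 5-unit steps, an MSY of 9 on
stocks 25–29, and the optimal cycle 50 → (harvest 25) → 25 → (regrow) → 34.
Individual per-bin values off the peak are read from the binned logistic
rather than from a published table; the table is therefore fully
configurable via CSV (`bin_lower_edge,regeneration`), validated against the
same invariants (non-negative integers, unimodal, unique maximum bin).

Stock and extraction are real-valued internally, because confidence-weighted
agreements produce non-integer shares; regeneration is looked up by
`floor(stock)`. If the group demands more than the stock, every agent
receives a proportional share of what is available — proportionality
preserves relative claims, and the model gives no reason to privilege any
agent in a simultaneous harvest.

### Optimal-policy oracle

The benchmark policy maximises long-run per-tick harvest by backward
induction over the 51 integer stock states, with the lookahead extended 60+
ticks beyond the requested horizon so no end-game liquidation leaks into the
reported sequence (the game end is treated as unknown, as it was for the
experiment participants). Ties are broken toward larger extraction, which
selects the lexicographically earliest-harvesting optimal sequence — from a
full stock: 25, then 9 per tick. The action table is cached per table
(states ≤ 51, actions ≤ 51, so the program is trivially cheap but is the
single hot spot when classifying tens of thousands of runs).

## Agents

Per-tick order (fixed, agents always iterated by ascending id; one numpy
generator per run drives every draw, so runs replay bit-identically from
their seed):

1. speak-up draws (Bernoulli, probability = social skills);
2. group knowledge = confidence-weighted mean of speaking agents' knowledge
   (plain mean in the degenerate all-zero-confidence case, the equal-weight
   limit); no speakers → no agreement this tick;
3. knowledge updates: with probability `update_probability · (1 − c)` the
   agent moves `(1 − c)` of the way toward the group knowledge, clamped to
   [5, 50] — a contraction, never overshooting;
4. extraction targets: individual = equal share of the surplus above own
   perceived optimum (times `greed_factor`, capped at the surplus, for
   agents without social preferences); group share = surplus above group
   knowledge divided by group size;
5. choice: the agreed share is always taken when it pays at least as much;
   a tempted conditional cooperator defects with probability
   `min(1, gap/temptation_scale) · min(1, uncertainty_gain · (1 − t)^uncertainty_power)`;
   an agent without social preferences always takes its own level;
6. harvest (proportional rationing of over-demand), regeneration;
7. feedback: each agent projects the stock it expected assuming everyone
   else complied with the agreement (the growth chart is public, so
   expectations use the true dynamics); a match within `match_tolerance`
   raises confidence and trust by `reward_increment`; a shortfall lowers
   both by `penalty_rate · |deviation| / capacity`; an overshoot lowers only
   confidence (nobody can have taken more than agreed if there is *more*
   stock than expected). When no agreement formed, no expectation exists and
   the update is skipped for that tick.

An alternative `belief_shifted_expectation` mode re-centers the growth curve
on the agent's own perceived optimum, so disagreement with the true peak
also produces ecological surprises; it is off by default (the growth chart
was public in the emulated experiments) but lets the positive-deviation
feedback branch arise endogenously, which under true-dynamics expectations
only rationing or forced inputs can reach.

## Behavioral parameters

| parameter | default | units | role |
|---|---|---|---|
| `update_probability` | 0.5 | – | base rate of revisiting knowledge after an agreement |
| `greed_factor` | 2.0 | – | share multiplier for agents without social preferences |
| `reward_increment` | 0.2 | – | confidence/trust gain on matching feedback |
| `penalty_rate` | 0.5 | per stock unit /50 | loss per unit normalized deviation |
| `match_tolerance` | 0.5 | stock units | deviation counted as a match |
| `temptation_scale` | 3.5 | resource units | payoff gap at which temptation saturates |
| `uncertainty_gain` | 12 | – | gain of the trust response |
| `uncertainty_power` | 3 | – | steepness of the trust response |

The qualitative behavioral assumptions fix only directions (who is more
likely to speak, learn, cooperate, lose trust), not functional forms. Every
form above is the simplest monotone choice, and the constants were
calibrated once, jointly, against the qualitative outcome patterns the model
exists to reproduce — all seven scenario compositions cooperative under
high initial trust; scenarios 4 and 5 (one informed speaker facing silent or
weakly confident uninformed majorities) losing cooperation when the initial
trust range is capped at 0.8; exploitation patterns essentially unchanged by
that cap; and, on the factorial grid, cooperative configurations arising
only with social preferences and high initial trust — then frozen.

Two shape choices deserve comment:

* **Temptation weighting.** Defection probability scales with the payoff
  gap between the agent's own level and the agreed share. Negligible
  temptations then barely endanger cooperation, which is what lets
  full-communication groups (where knowledge converges and the gap shrinks
  within a couple of rounds) remain cooperative while structurally divided
  groups stay exposed. A pure trust coin-flip, indifferent to the gap,
  makes *every* group with any below-average agent gamble every round and
  cannot reproduce the observed scenario contrasts at any threshold.
* **Super-linear uncertainty response.** The trust factor
  `min(1, 12·(1−t)³)` is ≈1 below t ≈ 0.56, ≈0.23 at t = 0.73 and ≈0.10 at
  t = 0.8, and exactly 0 at t = 1. Cooperation therefore collapses quickly
  once trust slips below the high range, while within the high range the
  remaining contrast still separates the capped (≤0.8) from the uncapped
  (≤0.94) trust regime. A linear response compresses this contrast to a
  factor ≈2, which is not enough to produce both the scenario-level
  robustness flip and the strict high-trust-only cooperation pattern.

## Scenario generator

Seven published 4-agent compositions, all with social preferences and
initial trust uniform on [0.66, 0.94] ([0.66, 0.80] in the robustness
variant). Informed agents draw their knowledge uniformly from the integers
25–29 (the MSY plateau), uninformed agents from 10–24 (a range that induces
over-exploitation; configurable), confidence is 0.8 (high) or 0.2 (low), and
social skills are 1 (speaker) or 0 (silent). Set I (scenarios 1–3, all
speak) varies how many informed, confident agents the group contains; set II
(scenarios 4–7, one informed agent) varies the number, knowledge and
confidence of speakers. Non-speakers are always uninformed with low
confidence. Knowledge draws are uniform over integers and trust uniform on
the real interval — the minimal assumptions, as the emulated experiments
specify only ranges. Runs are seeded `base_seed + run_index` with one
independent generator per run.

## Factorial verification grid

The default grid crosses knowledge level (uninformed 10–24, midrange 20–34,
cautious 30–44), confidence (0.2/0.8), social skills (0/0.5/1), trust range
(low [0, 0.33], medium [0.33, 0.66], high [0.66, 0.94]), social preferences
(yes/no) and a group template (aligned: four agents from the cell's range;
mixed: two cell-level agents plus two uninformed low-confidence agents) —
216 configurations. All knowledge levels are 15 integers wide so that every
group contains genuine disagreement and hence material temptation; narrow
levels (e.g. four agents all drawn from the 5-value MSY plateau) would make
defection structurally impossible and let low-trust groups "cooperate"
vacuously. The three knowledge levels place the group optimum below, inside
and above the MSY plateau, producing over-, optimal and under-exploitation
among cooperative high-trust cells.

## Outcome classification

* **Run-level cooperation** is strict: an agreement existed and every agent
  took the agreed share in *every* round. Runs in which no agent ever faces
  temptation (e.g. all knowledge draws coincide) count as cooperative by
  this definition even at zero trust; at the configuration level such flukes
  are washed out.
* **Config-level cooperation**: fraction of fully cooperative runs ≥ 0.76.
  The published classification table for this model family is not available;
  0.76 is the midpoint of the feasibility window measured at 3000
  replications per scenario (baseline minimum 0.80 above, robustness-flip
  maximum 0.73 below) and is configurable. Note that with three tempted
  agents gambling every round, the strict all-agents-all-rounds criterion
  bounds attainable fractions well below 1, so thresholds like 0.9 are not
  meaningful for this choice rule.
* **Exploitation class**: mean post-harvest stock over rounds 2–14 (the
  first round's draw-down from the virgin stock is part of every sensible
  path) against the MSY plateau [25, 29] ± 2 units: below → over, above →
  under, else optimal. The optimal-policy trajectory itself classifies
  optimal for any valid table, which the tests assert.
* **Deviation series / learning trend**: per-round total harvest minus what
  the optimal policy would take at the realized (floored) stock;
  the learning trend is the least-squares slope of |deviation| over rounds.
  In scenario 2 about 13% of runs show a negative slope (groups that move
  toward optimal harvesting), while the batch mean is slightly positive:
  the average stock drifts *down* as uninformed agents gain confidence and
  weight in the agreement. Scenario 1 shows no drift — with all-equal
  confidences the weighted mean stays the plain mean, so there is no
  influence shift to drive one.

## Problem sizes

The test suite runs the scenario experiments at 2500 replications per
scenario per trust regime and the grid at 216 × 100 runs; at ≈0.7 ms per
run the full suite finishes in about a minute. Classification fractions at
these sizes carry Monte-Carlo standard errors below 0.01, comfortably inside
the calibrated margins (±0.03–0.07). The acceptance script itself reports
only the deterministic resource-model quantities and runs in under a second.

## What the generator does and does not emulate

The simulator reproduces the *structure* of the laboratory task: 14 rounds,
four harvesters, a public stepwise growth chart, communication before each
harvest. It does not model human deliberation (agreement formation is a
one-shot weighted mean), payoff asymmetries, framing, or learning across
games; initial attribute values are drawn from stylized ranges rather than
measured distributions. Passing tests therefore show that the hypothesized
micro-mechanisms *can* generate the observed outcome patterns under these
stylized conditions — not that they are the mechanisms operating in human
groups, nor that the calibrated constants estimate any behavioral quantity.

## Known limitations

* The behavioral constants are jointly calibrated to qualitative patterns;
  other constellations likely reproduce them too, and none is identified by
  data.
* Trust is influenced only by ecological feedback, not by communication
  itself; social preferences are context-free constants.
* The ecological model is deterministic and smooth — no environmental
  stochasticity or regime shifts.
* The robustness-flip margins are finite (≈±0.03 around the 0.76 threshold);
  very small replication counts (≲500) can misclassify borderline scenarios
  by Monte-Carlo noise.
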