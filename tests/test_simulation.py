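"""Tick orchestration, runs, batches, scenario compositions and the sweep."""

import dataclasses

import numpy as np
import pytest

from cprsim.agents import AgentState, BehaviorParams
from cprsim.simulation import (
    AgentSpec,
    ScenarioConfig,
    batch,
    config_from_cell,
    default_grid,
    run,
    scenario,
    sweep,
    tick,
    INFORMED_RANGE,
    TRUST_RANGE_HIGH,
    TRUST_RANGE_ROBUSTNESS,
)


def fixed_config(specs, reps=1, seed=0, ticks=14, scenario_id="test"):
    return ScenarioConfig(
        scenario_id=scenario_id,
        agent_specs=tuple(specs),
        replications=reps,
        base_seed=seed,
        n_ticks=ticks,
    )


class TestTick:
    def test_identical_informed_agents_sustain_the_msy_cycle(self, table, params, rng):
        """Four agents who all know the optimum harvest 25 and land on 34."""
        agents = [
            AgentState(i, 25.0, 0.8, 1.0, 1.0, True) for i in range(4)
        ]
        stock, rec = tick(agents, 50.0, table, params, rng)
        assert rec.group_knowledge == 25.0
        assert rec.group_total == pytest.approx(25.0)
        assert float(rec.realized_extraction.sum()) == pytest.approx(25.0)
        assert stock == 34.0

    def test_no_speakers_means_no_agreement(self, table, params, rng):
        agents = [AgentState(i, 17.0, 0.2, 0.9, 0.0, True) for i in range(4)]
        stock, rec = tick(agents, 50.0, table, params, rng)
        assert rec.group_knowledge is None
        assert not rec.chose_group.any()
        # everyone takes their individual level instead
        assert float(rec.realized_extraction.sum()) == pytest.approx(4 * (50 - 17) / 4)

    def test_overdemand_is_rationed_proportionally(self, table, rng):
        # greedy agents with low perceived optima demand more than the stock
        params = BehaviorParams(greed_factor=4.0)
        agents = [AgentState(i, 5.0, 1.0, 0.0, 0.0, False) for i in range(4)]
        stock, rec = tick(agents, 10.0, table, params, rng)
        assert float(rec.chosen_extraction.sum()) > 10.0
        assert float(rec.realized_extraction.sum()) == pytest.approx(10.0)
        ratios = rec.realized_extraction / rec.chosen_extraction
        assert np.allclose(ratios, ratios[0])
        assert rec.post_harvest_stock == pytest.approx(0.0)

    def test_rationed_overdemand_erodes_trust_and_confidence(self, table, rng):
        """Greedy over-demand depletes the stock below every agent's
        expectation; the shortfall drags both trust and confidence down."""
        params = BehaviorParams(greed_factor=4.0)
        agents = [AgentState(i, 5.0, 0.5, 0.6, 1.0, False) for i in range(4)]
        stock, rec = tick(agents, 10.0, table, params, rng)
        assert float(rec.realized_extraction.sum()) == pytest.approx(10.0)
        assert stock < rec.expected_stock.min()
        assert all(a.confidence < 0.5 for a in agents)
        assert all(a.trust < 0.6 for a in agents)


class TestRun:
    def test_same_seed_bit_identical(self, table, params):
        cfg = scenario(5, replications=1, base_seed=42)
        a = run(cfg, table, params, seed=42)
        b = run(cfg, table, params, seed=42)
        for ta, tb in zip(a.ticks, tb_list := b.ticks):
            assert ta.reported_stock == tb.reported_stock
            assert np.array_equal(ta.knowledge, tb.knowledge)
            assert np.array_equal(ta.trust, tb.trust)
            assert np.array_equal(ta.chosen_extraction, tb.chosen_extraction)

    def test_stock_stays_in_bounds_every_tick(self, table, params):
        for sid in range(1, 8):
            r = run(scenario(sid, replications=1, base_seed=3), table, params, seed=3)
            assert ((r.reported_stock >= 0) & (r.reported_stock <= 50)).all()
            assert r.n_ticks == 14

    def test_trust_and_confidence_never_fall_under_full_compliance(self, table, params):
        """With certain trust everyone complies, feedback always matches, and
        confidence and trust ratchet monotonically upward."""
        specs = [
            AgentSpec(knowledge_range=(10, 24), confidence=0.2, trust_range=(1.0, 1.0)),
            AgentSpec(knowledge_range=INFORMED_RANGE, confidence=0.8, trust_range=(1.0, 1.0)),
            AgentSpec(knowledge_range=(10, 24), confidence=0.2, trust_range=(1.0, 1.0)),
            AgentSpec(knowledge_range=(30, 44), confidence=0.5, trust_range=(1.0, 1.0)),
        ]
        r = run(fixed_config(specs, seed=9), table, params, seed=9)
        conf = np.vstack([t.confidence for t in r.ticks])
        trust = np.vstack([t.trust for t in r.ticks])
        assert (np.diff(conf, axis=0) >= -1e-12).all()
        assert (np.diff(trust, axis=0) >= -1e-12).all()
        assert r.all_chose_group()

    def test_invalid_config_lists_all_violations(self, table, params):
        cfg = fixed_config(
            [AgentSpec(knowledge_range=(60, 70), confidence=2.0)], ticks=0
        )
        with pytest.raises(ValueError) as err:
            run(cfg, table, params, seed=0)
        msg = str(err.value)
        assert "knowledge_range" in msg and "confidence" in msg and "n_ticks" in msg


class TestBatch:
    def test_single_replication_equals_single_run(self, table, params):
        cfg = scenario(3, replications=1, base_seed=11)
        results, summary = batch(cfg, table, params)
        single = run(cfg, table, params, seed=11)
        assert len(results) == 1
        assert np.array_equal(results[0].reported_stock, single.reported_stock)
        assert np.array_equal(summary.mean_reported_stock, single.reported_stock)

    def test_mean_trajectories_stable_across_replication_counts(self, table, params):
        """500 vs 2000 replications agree within Monte-Carlo error."""
        small = batch(scenario(2, replications=500, base_seed=100), table, params)[1]
        large = batch(scenario(2, replications=2000, base_seed=5000), table, params)[1]
        # conservative bound: 5 x pooled standard error with per-tick sd <= 12
        assert np.abs(small.mean_reported_stock - large.mean_reported_stock).max() < 5 * 12 / np.sqrt(500)

    def test_scenario_one_overexploits_and_scenario_two_drifts_down(self, table, params):
        """Uninformed low-confidence groups hold the stock far below the MSY
        plateau; with one informed agent the stock starts near the plateau
        but drifts downward as the uninformed gain confidence and weight."""
        _, s1 = batch(scenario(1, replications=300, base_seed=17), table, params)
        assert s1.mean_reported_stock.mean() < 25
        _, s2 = batch(scenario(2, replications=600, base_seed=19), table, params)
        curve = s2.mean_reported_stock
        assert curve[-1] < curve[:2].max() - 0.5


class TestScenarios:
    @pytest.mark.parametrize(
        "sid,n_speakers", [(1, 4), (2, 4), (3, 4), (4, 1), (5, 2), (6, 2), (7, 2)]
    )
    def test_published_speaker_counts(self, sid, n_speakers):
        cfg = scenario(sid)
        assert sum(s.social_skills == 1.0 for s in cfg.agent_specs) == n_speakers
        assert all(
            s.social_skills in (0.0, 1.0) for s in cfg.agent_specs
        )

    @pytest.mark.parametrize(
        "sid,n_informed", [(1, 0), (2, 1), (3, 2), (4, 1), (5, 1), (6, 1), (7, 1)]
    )
    def test_published_informed_counts(self, sid, n_informed):
        cfg = scenario(sid)
        assert (
            sum(s.knowledge_range == INFORMED_RANGE for s in cfg.agent_specs)
            == n_informed
        )

    def test_scenario_seven_informed_agent_lacks_confidence(self):
        cfg = scenario(7)
        informed = [s for s in cfg.agent_specs if s.knowledge_range == INFORMED_RANGE]
        assert len(informed) == 1 and informed[0].confidence == 0.2

    def test_non_speakers_are_uninformed_with_low_confidence(self):
        for sid in range(1, 8):
            for s in scenario(sid).agent_specs:
                if s.social_skills == 0.0:
                    assert s.confidence == 0.2
                    assert s.knowledge_range != INFORMED_RANGE

    def test_all_scenarios_share_preferences_and_high_trust(self):
        for sid in range(1, 8):
            for robustness, expected in (
                (False, TRUST_RANGE_HIGH),
                (True, TRUST_RANGE_ROBUSTNESS),
            ):
                cfg = scenario(sid, robustness=robustness)
                assert all(s.social_preferences for s in cfg.agent_specs)
                assert all(s.trust_range == expected for s in cfg.agent_specs)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario(8)


class TestSweep:
    def test_default_grid_size_and_coverage(self):
        grid = default_grid()
        assert len(grid) == 216
        assert {c["template"] for c in grid} == {"aligned", "mixed"}
        assert {c["knowledge"] for c in grid} == {"uninformed", "midrange", "cautious"}

    def test_single_cell_sweep_matches_batch(self, table, params):
        cell = {
            "knowledge": "uninformed",
            "confidence": 0.2,
            "social_skills": 1.0,
            "trust": "high",
            "social_preferences": True,
            "template": "aligned",
        }
        df = sweep([cell], replications=20, base_seed=50, table=table, params=params)
        cfg = config_from_cell(cell, 20, 50, "cfg0000")
        _, summary = batch(cfg, table, params)
        assert len(df) == 20
        assert df["cooperative"].mean() == pytest.approx(summary.cooperative_fraction)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty grid"):
            sweep([], replications=1)

    def test_zero_trust_grid_produces_no_cooperative_configs(self, table, params):
        """Without trust, tempted agents defect: no configuration reaches
        config-level cooperation."""
        from cprsim.analysis import config_cooperative

        cells = [
            {
                "knowledge": k,
                "confidence": c,
                "social_skills": 1.0,
                "trust": "low",
                "social_preferences": True,
                "template": "aligned",
            }
            for k in ("uninformed", "midrange", "cautious")
            for c in (0.2, 0.8)
        ]
        for cell in cells:
            cfg = config_from_cell(cell, 60, 900, "z")
            cfg = dataclasses.replace(
                cfg,
                agent_specs=tuple(
                    dataclasses.replace(s, trust_range=(0.0, 0.0))
                    for s in cfg.agent_specs
                ),
            )
            results, _ = batch(cfg, table, params)
            flags = [r.agreement_every_tick() and r.all_chose_group() for r in results]
            assert not config_cooperative(flags)
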