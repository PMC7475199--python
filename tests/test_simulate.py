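"""Tests for the daily-step simulator."""

import numpy as np
import pytest

from ffvpsim.cohort import AgentRecord
from ffvpsim.core import EnvironmentParams, PreferenceState, draw_gamma
from ffvpsim.simulate import (
    SimulationConfig,
    agent_rng,
    simulate_agent,
    simulate_cohort,
    step_agent,
    trajectories_from_frame,
    trajectories_to_frame,
)

from conftest import make_pattern_cohort


class TestStepAgent:
    def test_forced_healthy_situation_updates(self, rng):
        cfg = SimulationConfig()
        state = PreferenceState(v_hat_H=0.2, alpha=0.1)
        new, rec = step_agent(state, 1.0, cfg, rng)
        assert rec.healthy_only and rec.consumed_healthy
        assert new.v_hat_H == pytest.approx(0.2 + 0.1 * 0.8)

    def test_unformed_state_absorbing_without_healthy_situation(self, rng):
        cfg = SimulationConfig()
        state = PreferenceState(v_hat_H=0.0, alpha=0.1)
        for _ in range(200):
            state, rec = step_agent(state, 0.0, cfg, rng)
            assert not rec.consumed_healthy
            assert rec.servings == 0
        assert state.v_hat_H == 0.0

    def test_total_probability_of_healthy_consumption(self):
        """At gamma=0.5 and v=1, healthy food is consumed with probability
        0.5 + 0.5*0.5 = 0.75 (healthy-only situation or Luce choice)."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(99)
        state = PreferenceState(v_hat_H=1.0, alpha=1e-9)
        n = 100_000
        consumed = sum(step_agent(state, 0.5, cfg, rng)[1].consumed_healthy for _ in range(n))
        se = np.sqrt(0.75 * 0.25 / n)
        assert consumed / n == pytest.approx(0.75, abs=4 * se)


class TestSimulateAgent:
    def test_closed_form_under_daily_updates(self):
        """With the healthy situation forced every day, the valuation follows
        the geometric closed form exactly."""
        agent = AgentRecord(0, "1111111", "0000000", 0.05)
        cfg = SimulationConfig(gamma_override=1.0, seed=1)
        traj = simulate_agent(agent, cfg)
        assert traj.final_v == pytest.approx(1.0 - 0.95**1260, abs=1e-12)
        assert traj.step[-1] == 1260

    def test_absorbing_unformed_state(self):
        agent = AgentRecord(0, "0000000", "1111111", 0.05)
        cfg = SimulationConfig(gamma_override=0.0, seed=1)
        traj = simulate_agent(agent, cfg)
        assert traj.final_v == 0.0
        assert traj.mean_servings == 0.0

    def test_history_length_must_match_years(self):
        agent = AgentRecord(0, "1111111", "0000000", 0.05)
        with pytest.raises(ValueError, match="n_years"):
            simulate_agent(agent, SimulationConfig(n_years=3))

    def test_matches_scalar_step_agent_stream(self, fast_cfg):
        """The batched per-year simulation and a day-by-day driver built from
        step_agent produce identical paths from the same substream."""
        agent = AgentRecord(3, "1010011", "0110001", 0.02)
        cfg = SimulationConfig(
            days_per_year=fast_cfg.days_per_year,
            n_years=7,
            record_every=1,
            seed=42,
        )
        traj = simulate_agent(agent, cfg)

        rng = agent_rng(cfg.seed, agent.agent_id)
        state = PreferenceState(v_hat_H=0.0, alpha=agent.alpha)
        vs, servings = [], []
        for year in range(cfg.n_years):
            gamma = draw_gamma(
                agent.desert[year] == "1", agent.exposure[year] == "1", cfg.env, rng
            )
            for _ in range(cfg.days_per_year):
                state, rec = step_agent(state, gamma, cfg, rng)
                vs.append(rec.v_hat_H)
                servings.append(rec.servings)
        np.testing.assert_allclose(traj.v_hat_H, vs, rtol=0, atol=0)
        assert list(traj.servings) == servings

    def test_trajectory_invariants(self, fast_cfg):
        agent = AgentRecord(1, "0011000", "1111111", 0.03)
        traj = simulate_agent(agent, fast_cfg)
        assert np.all(np.diff(traj.step) > 0)
        assert np.all(np.diff(traj.v_hat_H) >= 0)
        assert 0 <= traj.final_v < 1
        assert np.all(traj.servings >= 0)

    def test_per_day_gamma_redraw_mode(self):
        agent = AgentRecord(2, "1111111", "0000000", 0.01)
        cfg = SimulationConfig(
            days_per_year=30, n_years=7, gamma_per_day=True, seed=8
        )
        traj = simulate_agent(agent, cfg)
        assert 0 < traj.final_v < 1


class TestSimulateCohort:
    def test_deterministic_and_order_independent(self, fast_cfg):
        cohort = make_pattern_cohort("1100000", "1111111", 6)
        _, final_a = simulate_cohort(cohort, fast_cfg)
        _, final_b = simulate_cohort(list(reversed(cohort)), fast_cfg)
        final_b = final_b.sort_values("agent_id").reset_index(drop=True)
        assert final_a.equals(final_b)

    def test_same_agent_same_substream_identical(self, fast_cfg):
        agent = AgentRecord(5, "0001100", "1010101", 0.02)
        t1 = simulate_agent(agent, fast_cfg)
        t2 = simulate_agent(agent, fast_cfg)
        np.testing.assert_array_equal(t1.v_hat_H, t2.v_hat_H)
        assert t1.mean_servings == t2.mean_servings

    def test_empty_cohort_gives_empty_outputs(self, fast_cfg):
        trajs, final = simulate_cohort([], fast_cfg)
        assert trajs == []
        assert final.empty

    def test_non_desert_environment_forms_stronger_preferences(self):
        """Never-exposed agents out of food deserts draw gamma from (p1, p2)
        rather than (0, p1) and end with higher valuations."""
        cfg = SimulationConfig(seed=11, record_every=10_000)
        desert = make_pattern_cohort("0000000", "1111111", 300)
        non_desert = make_pattern_cohort("0000000", "0000000", 300, start_id=300)
        _, f_des = simulate_cohort(desert, cfg, keep_trajectories=False)
        _, f_nd = simulate_cohort(non_desert, cfg, keep_trajectories=False)
        assert f_nd["v_hat_final"].mean() > f_des["v_hat_final"].mean() + 0.01

    def test_servings_increase_with_exposure_years(self):
        """End-of-study servings rise across 0, 2, and 7 exposure years."""
        cfg = SimulationConfig(seed=13, record_every=10_000)
        means = []
        for i, pattern in enumerate(["0000000", "0001100", "1111111"]):
            cohort = make_pattern_cohort(pattern, "1111111", 300, start_id=1000 * i)
            _, final = simulate_cohort(cohort, cfg, keep_trajectories=False)
            means.append(final["mean_servings"].mean())
        assert means[0] < means[1] < means[2]


class TestTrajectoryFrames:
    def test_round_trip(self, fast_cfg):
        cohort = make_pattern_cohort("1110000", "0000111", 3)
        trajs, _ = simulate_cohort(cohort, fast_cfg)
        df = trajectories_to_frame(trajs)
        back = trajectories_from_frame(df)
        assert len(back) == len(trajs)
        for t1, t2 in zip(trajs, back):
            np.testing.assert_array_equal(t1.v_hat_H, t2.v_hat_H)
            np.testing.assert_array_equal(t1.step, t2.step)
            assert t1.final_v == t2.final_v

    def test_empty_frame(self):
        assert trajectories_from_frame(trajectories_to_frame([])) == []


def test_schedule_defaults_give_1260_steps():
    cfg = SimulationConfig()
    assert cfg.days_per_year == 180 and cfg.n_years == 7
    assert cfg.total_steps == 1260
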