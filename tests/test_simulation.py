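"""Trial loop, callback ordering, monitors, and session persistence."""

import numpy as np
import pytest

from navrl.agents import AgentConfig, DynaQAgent, MLPQNetwork
from navrl.envs import GridworldEnv, make_open_field, make_t_maze
from navrl.simulation import (
    CallbackSet,
    Monitor,
    SessionLog,
    TrialRecord,
    escape_latency_monitor,
    response_monitor,
    reward_monitor,
    run_session,
    trajectory_monitor,
    unit_response_monitor,
)


def make_agent_env(goal=8, h=3, w=3, **cfg):
    spec = make_open_field(h, w, goal_state=goal)
    agent = DynaQAgent(spec, AgentConfig(**cfg))
    return agent, GridworldEnv(spec)


class TestTrialLoop:
    def test_adjacent_goal_one_step_trials(self):
        spec = make_open_field(1, 2, goal_state=1)
        agent = DynaQAgent(spec, AgentConfig(epsilon=0.0))
        agent.Q[0, 3] = 1.0  # greedy right
        log = run_session(agent, GridworldEnv(spec), n_trials=5, max_steps=10, seed=0)
        assert all(r.steps == 1 and r.reached_terminal for r in log.records)

    def test_unreachable_goal_times_out(self):
        spec = make_open_field(2, 2, goal_state=3)
        spec.transitions[:, :, :] = 0.0
        for s in range(4):
            spec.transitions[s, :, s] = 1.0  # nothing moves
        agent = DynaQAgent(spec, AgentConfig())
        log = run_session(agent, GridworldEnv(spec), n_trials=3, max_steps=7, seed=0)
        assert all(r.steps == 7 and not r.reached_terminal for r in log.records)

    def test_same_seed_bit_identical(self):
        logs = []
        for _ in range(2):
            agent, env = make_agent_env(epsilon=0.3)
            logs.append(run_session(agent, env, n_trials=10, max_steps=30, seed=17))
        assert logs[0] == logs[1]

    def test_trajectory_invariant(self):
        agent, env = make_agent_env()
        log = run_session(agent, env, n_trials=5, max_steps=30, seed=3)
        for r in log.records:
            assert len(r.trajectory) == r.steps + 1
        assert [r.trial for r in log.records] == list(range(5))

    def test_n_trials_validation(self):
        agent, env = make_agent_env()
        with pytest.raises(ValueError):
            run_session(agent, env, n_trials=0)


class TestCallbacks:
    def test_ordering_and_counts(self):
        events = []
        cbs = {h: (lambda logs, h=h: events.append(h))
               for h in ("trial_begin", "trial_end", "step_begin", "step_end")}
        agent, env = make_agent_env()
        log = run_session(agent, env, n_trials=4, max_steps=20, callbacks=cbs, seed=2)
        total_steps = int(log.series("steps").sum())
        assert events.count("trial_begin") == events.count("trial_end") == 4
        assert events.count("step_begin") == events.count("step_end") == total_steps
        # ordering: trial_begin, (step_begin, step_end)*, trial_end
        i = 0
        for r in log.records:
            assert events[i] == "trial_begin"
            for _ in range(r.steps):
                assert events[i + 1] == "step_begin" and events[i + 2] == "step_end"
                i += 2
            assert events[i + 1] == "trial_end"
            i += 2

    def test_unknown_hook_rejected(self):
        with pytest.raises(ValueError, match="unknown hook"):
            CallbackSet({"after_everything": [lambda logs: None]})


class TestMonitors:
    def test_monitor_arithmetic(self):
        r = TrialRecord(0, 7, 0.9, 0, list(range(8)), True)
        assert escape_latency_monitor(r) == 7
        assert reward_monitor(r) == 0.9
        assert response_monitor(r) == 1
        assert response_monitor(TrialRecord(0, 3, 0.0, 0, [0] * 4, False)) == 0
        assert trajectory_monitor(r)[0] == 0

    def test_per_step_cost_reward_sum(self):
        """Step costs plus goal reward add up under reward-on-entry: a
        10-step run collects nine -0.01 costs and the goal's 1.0, i.e. 0.91
        (the start state's cost is never collected)."""
        spec = make_open_field(1, 11, goal_state=10)
        spec.rewards[:10] = -0.01
        spec.starting_states = [0]
        agent = DynaQAgent(spec, AgentConfig(epsilon=0.0))
        agent.Q[:, 3] = 1.0  # run right
        log = run_session(agent, GridworldEnv(spec), n_trials=1, max_steps=20, seed=0)
        assert np.isclose(log.records[0].reward, 0.91)
        assert log.records[0].steps == 10

    def test_monitors_reproducible_offline(self):
        """Monitors are pure functions of the log: recomputing offline matches
        the values collected live."""
        agent, env = make_agent_env(epsilon=0.5)
        live = Monitor(escape_latency_monitor)
        log = run_session(agent, env, n_trials=8, max_steps=30, monitors=[live], seed=4)
        offline = [escape_latency_monitor(r) for r in log.records]
        assert live.values == offline == list(log.series("steps"))

    def test_custom_response_coding_cumulative_curve(self):
        """Counting right-arm entries yields a non-decreasing cumulative curve."""
        spec = make_t_maze(2, 1)
        agent = DynaQAgent(spec, AgentConfig(epsilon=0.5, use_action_mask=True))
        right = spec.metadata["right_end"]
        log = run_session(agent, GridworldEnv(spec), n_trials=20, max_steps=30,
                          seed=6, response_fn=lambda r, e: int(r.trajectory[-1] == right))
        cum = np.cumsum(log.series("response"))
        assert (np.diff(cum) >= 0).all()

    def test_unit_response_monitor_linear_oracle(self, rng):
        """A single-layer linear network's activations equal the affine map."""
        net = MLPQNetwork(4, 3, hidden=(), seed=0)
        X = rng.normal(size=(6, 4))
        acts = unit_response_monitor(net, X)
        assert len(acts) == 1
        assert np.allclose(acts[0], X @ net.W[0] + net.b[0])


class TestPersistence:
    def test_jsonl_round_trip(self, tmp_path):
        agent, env = make_agent_env()
        log = run_session(agent, env, n_trials=5, max_steps=20, seed=9)
        path = tmp_path / "session.jsonl"
        log.to_jsonl(path)
        loaded = SessionLog.from_jsonl(path)
        assert loaded == log

    def test_summary_frame(self):
        agent, env = make_agent_env()
        log = run_session(agent, env, n_trials=4, max_steps=20, seed=9)
        df = log.summary_frame()
        assert list(df.columns) == ["trial", "steps", "reward", "response"]
        assert len(df) == 4
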