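"""Extinction-learning paradigm in a T-maze.

The agent is rewarded for choosing the right arm for the first ``n_acq``
trials; the reward then moves to the left arm for the remaining ``n_ext``
trials.  Responses are coded 1 when the trial ended in the right arm and 0
otherwise, so the cumulative response curve shows acquisition followed by
extinction of the right-arm choice.  The tabular Dyna-Q condition runs on the
bare gridworld; the DQN condition runs on the same maze with procedurally
synthesized per-state images as observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..agents.dqn import DQNAgent, DQNConfig
from ..agents.dynaq import DynaQAgent
from ..agents.policy import AgentConfig
from ..envs.discrete import DiscreteEnv, attach_observations
from ..envs.gridworld import GridworldEnv, make_t_maze
from ..observations import synthesize_state_images
from ..simulation import SessionLog, run_session


@dataclass
class ExtinctionResult:
    log: SessionLog
    responses: np.ndarray  # per-trial right-arm choice (0/1)
    latencies: np.ndarray  # per-trial escape latency


def run_extinction(
    agent_kind: str = "dynaq",
    n_acq: int = 100,
    n_ext: int = 100,
    seed: int = 0,
    stem_length: int = 3,
    arm_length: int = 2,
    max_steps: int = 50,
    image_size: tuple[int, int] = (16, 16),
) -> ExtinctionResult:
    """Run one extinction session; reward switches arms after trial ``n_acq``."""
    if agent_kind not in ("dynaq", "dqn"):
        raise ValueError(f"agent_kind must be 'dynaq' or 'dqn', got {agent_kind!r}")
    spec = make_t_maze(stem_length, arm_length, rewarded_arm="right")
    left_end = spec.metadata["left_end"]
    right_end = spec.metadata["right_end"]

    def switch_reward(logs):
        if logs["trial"] == n_acq:
            spec.rewards[right_end], spec.rewards[left_end] = 0.0, spec.rewards[right_end]

    if agent_kind == "dynaq":
        env = GridworldEnv(spec)
        agent = DynaQAgent(spec, AgentConfig(alpha=0.9, gamma=0.9, epsilon=0.1,
                                             replay_mode="per_step", replay_batch=20,
                                             use_action_mask=True))
    else:
        obs_set = synthesize_state_images(spec.n_states, image_size, seed=seed)
        obs_map = {s: obs_set.get(s).ravel() for s in range(spec.n_states)}
        env = DiscreteEnv(attach_observations(spec, obs_map))
        agent = DQNAgent(
            input_dim=image_size[0] * image_size[1], n_actions=spec.n_actions,
            config=DQNConfig(gamma=0.9, epsilon=0.1, lr=1e-2, hidden=(64, 64),
                             batch_size=32, buffer_capacity=5000, target_sync=50),
            seed=seed,
        )

    def right_arm_response(record, env_) -> int:
        return int(record.trajectory[-1] == right_end)

    log = run_session(agent, env, n_trials=n_acq + n_ext, max_steps=max_steps,
                      callbacks={"trial_begin": switch_reward}, seed=seed,
                      response_fn=right_arm_response)
    return ExtinctionResult(log, log.series("response"), log.series("steps"))


def perseveration_trials(result: ExtinctionResult, n_acq: int = 100) -> int:
    """Number of post-switch trials on which the agent still chose the old arm."""
    return int(result.responses[n_acq:].sum())
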