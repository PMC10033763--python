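"""Latent learning in the one-way alley maze.

Two groups of successor-representation agents are compared: the *latent*
group first explores the maze without any reward for ``n_explore`` trials and
then trains with the goal reward on, while the *direct* group receives the
goal reward from its very first trial.  Escape-latency curves of the direct
group are aligned to the latent group's point of reward introduction, so
faster post-reward learning in the latent group reveals knowledge acquired
during unrewarded exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..agents.dsr import DynaDSRAgent
from ..agents.policy import AgentConfig
from ..envs.gridworld import GridworldEnv, make_blodgett_maze
from ..simulation import run_session


ALPHA_R = 0.9  # reward weights learn fast; the successor map is the slow part


def _dsr_config() -> AgentConfig:
    return AgentConfig(alpha=0.1, gamma=0.9, epsilon=0.1,
                       replay_mode="per_step", replay_batch=10,
                       use_action_mask=True)


@dataclass
class LatentLearningResult:
    latent_latencies: np.ndarray  # (n_seeds, n_explore + n_reward)
    direct_latencies: np.ndarray  # (n_seeds, n_reward)
    explore_rewards: np.ndarray  # (n_seeds, n_explore) cumulative trial rewards
    n_explore: int
    #: start-state SR snapshots of seed 0's latent agent (end of exploration,
    #: end of run), for heat-map inspection
    sr_snapshots: dict = field(default_factory=dict)

    def post_reward_latencies(self, n: int = 10) -> tuple[np.ndarray, np.ndarray]:
        """Mean latency over the first ``n`` post-reward trials, per seed."""
        latent = self.latent_latencies[:, self.n_explore:self.n_explore + n].mean(axis=1)
        direct = self.direct_latencies[:, :n].mean(axis=1)
        return latent, direct


def _seed_for(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def run_latent_learning(
    n_explore: int = 100,
    n_reward: int = 100,
    n_seeds: int = 30,
    seed: int = 0,
    max_steps: int = 200,
    keep_sr_snapshots: bool = True,
) -> LatentLearningResult:
    """Run the latent- and direct-learning groups across ``n_seeds`` simulations."""
    latent_lat, direct_lat, explore_rew = [], [], []
    snapshots: dict = {}
    for i in range(n_seeds):
        # latent group: reward withheld for the exploration phase
        spec = make_blodgett_maze()
        goal = spec.metadata["goal"]
        goal_reward = spec.rewards[goal]
        spec.rewards[goal] = 0.0
        agent = DynaDSRAgent(spec, _dsr_config(), alpha_r=ALPHA_R)

        def introduce_reward(logs, spec=spec, goal=goal, agent=agent, i=i):
            if logs["trial"] == n_explore:
                spec.rewards[goal] = goal_reward
                if keep_sr_snapshots and i == 0:
                    snapshots["end_of_exploration"] = agent.model.psi.copy()

        log = run_session(agent, GridworldEnv(spec), n_trials=n_explore + n_reward,
                          max_steps=max_steps, callbacks={"trial_begin": introduce_reward},
                          seed=_seed_for(seed, i, 0))
        latent_lat.append(log.series("steps"))
        explore_rew.append(log.series("reward")[:n_explore])
        if keep_sr_snapshots and i == 0:
            snapshots["end_of_run"] = agent.model.psi.copy()
            snapshots["spec"] = spec
            snapshots["w"] = agent.model.w.copy()
        # direct group: reward present from trial 1
        spec_d = make_blodgett_maze()
        agent_d = DynaDSRAgent(spec_d, _dsr_config(), alpha_r=ALPHA_R)
        log_d = run_session(agent_d, GridworldEnv(spec_d), n_trials=n_reward,
                            max_steps=max_steps, seed=_seed_for(seed, i, 1))
        direct_lat.append(log_d.series("steps"))
    return LatentLearningResult(
        np.asarray(latent_lat), np.asarray(direct_lat), np.asarray(explore_rew),
        n_explore, snapshots,
    )
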