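"""One-shot learning with model-free episodic control (MFEC).

An MFEC agent stores the best discounted return observed for each projected
(state, action) pair and answers novel states by k-nearest-neighbor lookup.
On a small open field it typically locks onto a good route after the first
rewarded episode.
"""

import numpy as np

from navrl.agents import MFECAgent, MFECConfig
from navrl.envs import GridworldEnv, make_open_field
from navrl.simulation import run_session

spec = make_open_field(4, 4, goal_state=15, goal_reward=1.0)


class OneHotEnv(GridworldEnv):
    """Expose one-hot observations so the projection has something to chew on."""

    def reset(self, rng):
        return np.eye(self.spec.n_states)[super().reset(rng)]

    def step(self, a, rng):
        s, r, t = super().step(a, rng)
        return np.eye(self.spec.n_states)[s], r, t


agent = MFECAgent(obs_dim=16, n_actions=4,
                  config=MFECConfig(key_dim=8, k=3, gamma=0.99, epsilon=0.05,
                                    warmup_trials=3))
log = run_session(agent, OneHotEnv(spec), n_trials=30, max_steps=60, seed=2)
lat = log.series("steps")
print("escape latency per trial:", lat.tolist())
print(f"store size: {agent.store.size()} (state, action) pairs")
# After the exploratory warmup the latency typically collapses to a short
# route at once: the store replays the best episode seen so far.
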