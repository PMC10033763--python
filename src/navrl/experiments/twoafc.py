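"""Two-alternative forced-choice (2AFC) decision task.

Each choice trial pairs a rewarded (correct) stimulus with an unrewarded
(incorrect) one, both drawn from a fixed catalog of one-hot vectors.  On every
trial the interface picks one of the choice trials at random and presents the
two stimuli side by side in randomized order; the observation is their
concatenation and the agent chooses left or right.  A policy that ignores the
stimuli earns the reward on half the trials, so chance performance is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..agents.dqn import DQNAgent, DQNConfig
from ..simulation import run_session

LEFT, RIGHT = 0, 1


@dataclass
class ChoiceTrialSet:
    """Stimulus catalog plus the list of (correct, incorrect) choice trials."""

    n_stimuli: int
    trials: list[tuple[int, int]]
    reward: float = 1.0

    def __post_init__(self):
        for correct, incorrect in self.trials:
            if correct == incorrect:
                raise ValueError("correct and incorrect stimuli must differ")
            if not (0 <= correct < self.n_stimuli and 0 <= incorrect < self.n_stimuli):
                raise ValueError("choice-trial stimuli must be in the catalog")

    def stimulus(self, i: int) -> np.ndarray:
        vec = np.zeros(self.n_stimuli)
        vec[i] = 1.0
        return vec


def default_choice_set() -> ChoiceTrialSet:
    """Four one-hot stimuli in two disjoint choice trials, unit reward."""
    return ChoiceTrialSet(4, [(0, 1), (2, 3)])


class ChoiceTaskEnv:
    """Single-step 2AFC environment over a :class:`ChoiceTrialSet`.

    ``reset`` draws a random choice trial and a random left/right placement;
    the observation is the concatenation of the two placed stimuli.  Choosing
    the side holding the correct stimulus yields the reward; the trial ends
    after one choice either way.
    """

    n_actions = 2

    def __init__(self, choice_set: ChoiceTrialSet | None = None):
        self.choice_set = choice_set or default_choice_set()
        self.correct_side: int | None = None
        self.state = None  # (trial index, correct side)

    @property
    def obs_dim(self) -> int:
        return 2 * self.choice_set.n_stimuli

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        cs = self.choice_set
        i = int(rng.integers(len(cs.trials)))
        correct, incorrect = cs.trials[i]
        self.correct_side = int(rng.integers(2))
        pair = ([correct, incorrect] if self.correct_side == LEFT
                else [incorrect, correct])
        self.state = (i, self.correct_side)
        return np.concatenate([cs.stimulus(pair[0]), cs.stimulus(pair[1])])

    def step(self, action: int, rng: np.random.Generator):
        reward = self.choice_set.reward if action == self.correct_side else 0.0
        return np.zeros(self.obs_dim), reward, True


def make_choice_task(choice_set: ChoiceTrialSet | None = None) -> ChoiceTaskEnv:
    return ChoiceTaskEnv(choice_set)


def run_two_afc(
    n_agents: int = 100,
    n_trials: int = 50,
    seed: int = 0,
    choice_set: ChoiceTrialSet | None = None,
) -> np.ndarray:
    """Train independent DQN agents on the 2AFC task.

    Returns the (n_agents, n_trials) per-trial reward matrix; its column means
    are the average learning curve.
    """
    rewards = np.zeros((n_agents, n_trials))
    for i in range(n_agents):
        env = make_choice_task(choice_set)
        agent_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        agent = DQNAgent(
            input_dim=env.obs_dim, n_actions=2,
            config=DQNConfig(gamma=0.0, policy="softmax", tau=0.2, lr=3e-2,
                             hidden=(32, 32), batch_size=32, warmup=1,
                             grad_steps=16, buffer_capacity=1000),
            seed=agent_seed,
        )
        log = run_session(agent, env, n_trials=n_trials, max_steps=1, seed=agent_seed)
        rewards[i] = log.series("reward")
    return rewards
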