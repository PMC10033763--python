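"""Dyna-Q: tabular Q-learning with model-based experience replay.

The Q-function is a ``|S| x |A|`` table, updated online each step and
additionally via replay of experiences drawn from a tabular environment-model
memory.  The model memory stores, per visited (state, action) pair, the most
recently observed outcome (reward, next state, terminal); replay samples
uniformly among visited pairs and applies the same Q-learning update, which on
deterministic tasks drives the table to the value-iteration fixed point.
"""

from __future__ import annotations

import numpy as np

from ..envs.gridworld import GridworldSpec
from ..simulation import Experience
from .policy import AgentConfig, compute_action_mask, select_action


class EnvModelMemory:
    """Tabular one-step environment model over (state, action) pairs.

    Only the most recent outcome per pair is retained, which is exact for
    deterministic tasks (a known limitation for stochastic ones).  Sampling is
    uniform over visited pairs.
    """

    def __init__(self, n_states: int, n_actions: int):
        self.rewards = np.zeros((n_states, n_actions))
        self.next_states = np.zeros((n_states, n_actions), dtype=int)
        self.terminals = np.zeros((n_states, n_actions), dtype=bool)
        self.visited = np.zeros((n_states, n_actions), dtype=bool)

    def store(self, exp: Experience) -> None:
        s, a = exp.state, exp.action
        self.rewards[s, a] = exp.reward
        self.next_states[s, a] = exp.next_state
        self.terminals[s, a] = exp.terminal
        self.visited[s, a] = True

    def sample(self, n: int, rng: np.random.Generator) -> list[Experience]:
        pairs = np.argwhere(self.visited)
        if len(pairs) == 0:
            return []
        idx = rng.integers(len(pairs), size=n)
        return [
            Experience(int(s), int(a), float(self.rewards[s, a]),
                       int(self.next_states[s, a]), bool(self.terminals[s, a]))
            for s, a in pairs[idx]
        ]


def dynaq_update(Q: np.ndarray, exp: Experience, config: AgentConfig) -> np.ndarray:
    """One Q-learning update, in place: Q(s,a) += a*(r + g*(1-T)*max Q(s',.) - Q(s,a))."""
    s, a = exp.state, exp.action
    bootstrap = 0.0 if exp.terminal else Q[exp.next_state].max()
    Q[s, a] += config.alpha * (exp.reward + config.gamma * bootstrap - Q[s, a])
    return Q


def dynaq_replay(
    Q: np.ndarray,
    memory: EnvModelMemory,
    n: int,
    config: AgentConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replay ``n`` uniformly sampled stored transitions through :func:`dynaq_update`."""
    if config.replay_mode == "disabled":
        return Q
    for exp in memory.sample(n, rng):
        dynaq_update(Q, exp, config)
    return Q


class DynaQAgent:
    """Tabular Dyna-Q agent for discrete static environments."""

    def __init__(self, spec: GridworldSpec, config: AgentConfig | None = None):
        self.spec = spec
        self.config = config or AgentConfig()
        self.Q = np.zeros((spec.n_states, spec.n_actions))
        self.memory = EnvModelMemory(spec.n_states, spec.n_actions)
        self.replayed_updates = 0

    def begin_trial(self) -> None:
        pass

    def act(self, state: int, rng: np.random.Generator) -> int:
        mask = compute_action_mask(self.spec, state) if self.config.use_action_mask else None
        return select_action(self.Q[state], self.config, mask, rng)

    def predict(self, states) -> np.ndarray:
        return self.Q[np.asarray(states, dtype=int)]

    def observe(self, exp: Experience, rng: np.random.Generator) -> None:
        dynaq_update(self.Q, exp, self.config)
        self.memory.store(exp)
        if self.config.replay_mode == "per_step":
            self._replay(rng)

    def end_trial(self, rng: np.random.Generator) -> None:
        if self.config.replay_mode == "per_trial":
            self._replay(rng)

    def _replay(self, rng) -> None:
        dynaq_replay(self.Q, self.memory, self.config.replay_batch, self.config, rng)
        self.replayed_updates += self.config.replay_batch


def value_iteration(
    spec: GridworldSpec, gamma: float, tol: float = 1e-10, max_iter: int = 100_000
) -> np.ndarray:
    """Optimal action-value function Q* of a tabular environment.

    Terminal states have Q*(s, .) = 0 (no action is ever taken from them);
    bootstrapping stops at terminal successors.
    """
    T, R = spec.transitions, spec.rewards
    terminal = spec.terminals.astype(bool)
    cont = np.where(terminal, 0.0, 1.0)
    Q = np.zeros((spec.n_states, spec.n_actions))
    for _ in range(max_iter):
        V = Q.max(axis=1) * cont  # no value flows out of terminal states
        target = T @ (R + gamma * V)
        target[terminal] = 0.0
        if np.max(np.abs(target - Q)) < tol:
            return target
        Q = target
    return Q
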