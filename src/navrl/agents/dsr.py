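"""Successor-representation (SR) agents trained directly on observations.

The SR of a state is the expected discounted future occupancy of every state
under the current policy; its closed form under a fixed policy is
``M = (I - gamma * T_pi)^{-1}``.  The Dyna-style SR agent here learns a
per-action successor map ``psi`` by temporal differences together with a
linear reward model ``w``, and values actions as ``Q(s, a) = psi(s, a) . w``.
With one-hot observations (the default for discrete environments) the deep
successor map is exactly tabular, ``psi`` of shape ``|A| x |S| x |S|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..envs.gridworld import GridworldSpec, gridworld_reset, gridworld_step
from ..simulation import Experience
from .dynaq import EnvModelMemory
from .policy import AgentConfig, argmax_random_tie, compute_action_mask, select_action


@dataclass
class SRModel:
    """Tabular per-action successor map and linear reward weights."""

    psi: np.ndarray  # (A, S, S): psi[a, s] = discounted occupancy after (s, a)
    w: np.ndarray  # (S,) reward weights

    @classmethod
    def zeros(cls, n_states: int, n_actions: int) -> "SRModel":
        return cls(np.zeros((n_actions, n_states, n_states)), np.zeros(n_states))

    @property
    def n_states(self) -> int:
        return self.psi.shape[1]

    @property
    def n_actions(self) -> int:
        return self.psi.shape[0]


def dsr_q(model: SRModel, state: int) -> np.ndarray:
    """Action values Q(s, a) = psi(s, a) . w."""
    return model.psi[:, state, :] @ model.w


def dsr_td_update(
    model: SRModel,
    exp: Experience,
    config: AgentConfig,
    rng: np.random.Generator | None = None,
    alpha: float | None = None,
    alpha_r: float | None = None,
    next_action: int | None = None,
) -> SRModel:
    """One TD update of the successor map and reward weights, in place.

    ``psi(s, a) <- psi(s, a) + alpha * (e_s + gamma*(1-T)*psi(s', a*) - psi(s, a))``
    with ``a*`` the greedy action at the successor (ties uniform; override via
    ``next_action`` to learn the SR of a frozen policy), and
    ``w[s'] <- w[s'] + alpha_r * (r - w[s'])`` regressing reward on the entered
    state, matching the reward-on-entry convention.
    """
    alpha = config.alpha if alpha is None else alpha
    alpha_r = alpha if alpha_r is None else alpha_r
    s, a, s2 = exp.state, exp.action, exp.next_state
    target = np.zeros(model.n_states)
    target[s] = 1.0
    if exp.terminal:
        # absorbing successor: its SR is its own one-hot, no further bootstrap,
        # so the entered terminal state still contributes its occupancy
        target[s2] += config.gamma
    else:
        if next_action is None:
            q_next = dsr_q(model, s2)
            next_action = argmax_random_tie(q_next, rng or np.random.default_rng())
        target += config.gamma * model.psi[next_action, s2]
    model.psi[a, s] += alpha * (target - model.psi[a, s])
    model.w[s2] += alpha_r * (exp.reward - model.w[s2])
    return model


def sr_closed_form(T: np.ndarray, policy: np.ndarray | None, gamma: float) -> np.ndarray:
    """Closed-form state SR ``M = (I - gamma * T_pi)^{-1}``.

    ``T`` is the (S, A, S) transition tensor; ``policy`` is a (S, A) action
    distribution (uniform if None).
    """
    S, A, _ = T.shape
    if policy is None:
        policy = np.full((S, A), 1.0 / A)
    T_pi = np.einsum("sat,sa->st", T, policy)
    return np.linalg.inv(np.eye(S) - gamma * T_pi)


def fit_sr_random_walk(
    spec: GridworldSpec,
    gamma: float,
    n_steps: int,
    seed: int = 0,
    lr_offset: float = 50.0,
) -> SRModel:
    """Learn the SR of the uniform-random policy by TD on a sampled walk.

    Runs a single random walk of ``n_steps`` (restarting at terminal states),
    updating with Robbins-Monro step sizes ``alpha = c / (c + visits(s, a))``
    so the estimate converges to the closed form.  The bootstrap action is
    drawn uniformly, freezing the evaluated policy at uniform.
    """
    rng = np.random.default_rng(seed)
    model = SRModel.zeros(spec.n_states, spec.n_actions)
    visits = np.zeros((spec.n_states, spec.n_actions))
    config = AgentConfig(alpha=1.0, gamma=gamma, epsilon=1.0)
    state = gridworld_reset(spec, rng)
    for _ in range(n_steps):
        action = int(rng.integers(spec.n_actions))
        nxt, reward, terminal = gridworld_step(spec, state, action, rng)
        visits[state, action] += 1
        alpha = lr_offset / (lr_offset + visits[state, action])
        dsr_td_update(model, Experience(state, action, reward, nxt, terminal),
                      config, rng, alpha=alpha,
                      next_action=int(rng.integers(spec.n_actions)))
        state = gridworld_reset(spec, rng) if terminal else nxt
    return model


class DynaDSRAgent:
    """Dyna-style SR agent: online TD plus replay from the model memory."""

    def __init__(self, spec: GridworldSpec, config: AgentConfig | None = None,
                 alpha_r: float | None = None):
        self.spec = spec
        self.config = config or AgentConfig()
        self.alpha_r = self.config.alpha if alpha_r is None else alpha_r
        self.model = SRModel.zeros(spec.n_states, spec.n_actions)
        self.memory = EnvModelMemory(spec.n_states, spec.n_actions)

    def begin_trial(self) -> None:
        pass

    def act(self, state: int, rng: np.random.Generator) -> int:
        mask = compute_action_mask(self.spec, state) if self.config.use_action_mask else None
        return select_action(dsr_q(self.model, state), self.config, mask, rng)

    def observe(self, exp: Experience, rng: np.random.Generator) -> None:
        dsr_td_update(self.model, exp, self.config, rng, alpha_r=self.alpha_r)
        self.memory.store(exp)
        if self.config.replay_mode == "per_step":
            self._replay(rng)

    def end_trial(self, rng: np.random.Generator) -> None:
        if self.config.replay_mode == "per_trial":
            self._replay(rng)

    def _replay(self, rng: np.random.Generator) -> None:
        for exp in self.memory.sample(self.config.replay_batch, rng):
            dsr_td_update(self.model, exp, self.config, rng, alpha_r=self.alpha_r)
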