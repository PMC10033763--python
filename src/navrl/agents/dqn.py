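"""Deep Q-network agent with uniform or prioritized experience replay.

The agent keeps an online and a target network behind the
:class:`~navrl.agents.network.QNetwork` contract.  Each step's experience goes
into a capacity-bounded FIFO buffer; training samples a batch, regresses the
online network toward one-step TD targets computed with the target network,
and syncs the target network every ``target_sync`` training steps.
Prioritized replay follows the proportional scheme: sampling probability
``P(i) ~ (|delta_i| + eps_p)^alpha`` with importance weights
``(N * P(i))^(-beta)`` normalized by their maximum.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from ..simulation import Experience
from .network import MLPQNetwork, QNetwork
from .policy import AgentConfig, select_action


class ReplayBuffer:
    """Capacity-bounded FIFO of experience tuples with uniform sampling."""

    def __init__(self, capacity: int = 100_000):
        self.buffer: deque[Experience] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self.buffer)

    def add(self, exp: Experience) -> None:
        self.buffer.append(exp)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(len(self.buffer), size=batch_size)
        return [self.buffer[i] for i in idx], idx, np.ones(batch_size)


class PrioritizedReplayBuffer:
    """Proportional prioritized replay with importance-sampling weights."""

    def __init__(self, capacity: int = 100_000, alpha: float = 0.6,
                 beta: float = 0.4, eps: float = 1e-3):
        self.capacity = capacity
        self.alpha = alpha
        self.beta = beta
        self.eps = eps
        self.buffer: list[Experience] = []
        self.priorities = np.zeros(capacity)
        self._next = 0

    def __len__(self) -> int:
        return len(self.buffer)

    def add(self, exp: Experience) -> None:
        max_p = self.priorities[: len(self.buffer)].max() if self.buffer else 1.0
        if len(self.buffer) < self.capacity:
            self.buffer.append(exp)
        else:
            self.buffer[self._next] = exp
        self.priorities[self._next] = max_p
        self._next = (self._next + 1) % self.capacity

    def probabilities(self) -> np.ndarray:
        scaled = self.priorities[: len(self.buffer)] ** self.alpha
        return scaled / scaled.sum()

    def sample(self, batch_size: int, rng: np.random.Generator):
        """Sample ``(tuples, indices, importance weights)`` proportional to priority."""
        p = self.probabilities()
        idx = rng.choice(len(self.buffer), size=batch_size, p=p)
        weights = (len(self.buffer) * p[idx]) ** (-self.beta)
        weights /= weights.max()
        return [self.buffer[i] for i in idx], idx, weights

    def update_priorities(self, indices, td_errors) -> None:
        self.priorities[np.asarray(indices)] = (
            np.abs(np.asarray(td_errors, dtype=float)) + self.eps
        )


def dqn_td_targets(
    batch: list[Experience], online: QNetwork, target: QNetwork, gamma: float
) -> np.ndarray:
    """One-step TD target matrix for a batch.

    Taken actions get ``y = r + gamma * (1 - terminal) * max_a' Q_target(s', a')``;
    all other entries keep the online network's current predictions so that no
    gradient flows through them.
    """
    X = np.stack([np.asarray(e.state, dtype=float) for e in batch])
    Xn = np.stack([np.asarray(e.next_state, dtype=float) for e in batch])
    Y = online.predict(X).copy()
    q_next = target.predict(Xn).max(axis=1)
    for i, e in enumerate(batch):
        Y[i, e.action] = e.reward + gamma * (0.0 if e.terminal else q_next[i])
    return Y


@dataclass
class DQNConfig:
    """DQN hyperparameters (defaults sized for small behavioral tasks)."""

    gamma: float = 0.9
    epsilon: float = 0.1
    lr: float = 1e-3
    hidden: tuple[int, ...] = (64, 64)
    batch_size: int = 32
    buffer_capacity: int = 100_000
    target_sync: int = 100
    grad_steps: int = 1  # gradient steps per environment step
    warmup: int | None = None  # buffer size before training starts (default: batch_size)
    optimistic_init: float = 0.0  # initial output bias; > 0 drives directed exploration
    prioritized: bool = False
    per_alpha: float = 0.6
    per_beta: float = 0.4
    per_eps: float = 1e-3
    policy: str = "epsilon_greedy"
    tau: float = 1.0


class DQNAgent:
    """Deep Q-network agent over vector observations."""

    def __init__(self, input_dim: int, n_actions: int,
                 config: DQNConfig | None = None, seed: int = 0,
                 network: QNetwork | None = None):
        self.config = config or DQNConfig()
        c = self.config
        self.n_actions = n_actions
        self.online = network or MLPQNetwork(input_dim, n_actions, c.hidden, c.lr, seed)
        if c.optimistic_init and hasattr(self.online, "b"):
            self.online.b[-1][:] = c.optimistic_init
        self.target = self.online.clone()
        if c.prioritized:
            self.buffer = PrioritizedReplayBuffer(c.buffer_capacity, c.per_alpha,
                                                  c.per_beta, c.per_eps)
        else:
            self.buffer = ReplayBuffer(c.buffer_capacity)
        self._policy_cfg = AgentConfig(gamma=c.gamma, epsilon=c.epsilon,
                                       tau=c.tau, policy=c.policy)
        self.train_steps = 0

    def begin_trial(self) -> None:
        pass

    def act(self, obs, rng: np.random.Generator) -> int:
        values = self.online.predict(np.asarray(obs, dtype=float)[None])[0]
        return select_action(values, self._policy_cfg, None, rng)

    def predict(self, X) -> np.ndarray:
        return self.online.predict(X)

    def observe(self, exp: Experience, rng: np.random.Generator) -> None:
        self.buffer.add(exp)
        warmup = self.config.warmup if self.config.warmup is not None else self.config.batch_size
        if len(self.buffer) >= max(1, warmup):
            for _ in range(self.config.grad_steps):
                self.train_step(rng)

    def end_trial(self, rng: np.random.Generator) -> None:
        pass

    def train_step(self, rng: np.random.Generator) -> float:
        """Sample a batch, fit the online net to TD targets, sync periodically."""
        c = self.config
        batch, idx, weights = self.buffer.sample(c.batch_size, rng)
        Y = dqn_td_targets(batch, self.online, self.target, c.gamma)
        if c.prioritized:
            X = np.stack([np.asarray(e.state, dtype=float) for e in batch])
            pred = self.online.predict(X)
            deltas = [Y[i, e.action] - pred[i, e.action] for i, e in enumerate(batch)]
            self.buffer.update_priorities(idx, deltas)
            loss = self.online.fit(X, Y, sample_weight=weights)
        else:
            X = np.stack([np.asarray(e.state, dtype=float) for e in batch])
            loss = self.online.fit(X, Y)
        self.train_steps += 1
        if self.train_steps % c.target_sync == 0:
            self.target.copy_weights_from(self.online)
        return loss
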