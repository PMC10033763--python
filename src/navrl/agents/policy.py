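"""Action-selection policies and tabular agent configuration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..envs.gridworld import GridworldSpec


@dataclass
class AgentConfig:
    """Hyperparameters shared by the tabular agent families.

    alpha: learning rate in (0, 1]; gamma: discount in [0, 1); epsilon:
    exploration probability; tau: softmax temperature (> 0); policy is
    epsilon-greedy (default) or softmax; replay can run after each step, after
    each trial, or be disabled, drawing ``replay_batch`` samples per event.
    """

    alpha: float = 0.9
    gamma: float = 0.9
    epsilon: float = 0.3
    tau: float = 1.0
    policy: str = "epsilon_greedy"  # "epsilon_greedy" | "softmax"
    replay_mode: str = "per_step"  # "per_step" | "per_trial" | "disabled"
    replay_batch: int = 20
    use_action_mask: bool = False

    def __post_init__(self):
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must be in [0, 1)")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.policy not in ("epsilon_greedy", "softmax"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.replay_mode not in ("per_step", "per_trial", "disabled"):
            raise ValueError(f"unknown replay mode {self.replay_mode!r}")


def argmax_random_tie(values: np.ndarray, rng: np.random.Generator) -> int:
    """Argmax with exact ties broken uniformly at random."""
    values = np.asarray(values, dtype=float)
    best = np.flatnonzero(values == values.max())
    return int(best[0]) if len(best) == 1 else int(rng.choice(best))


def select_action(
    values: np.ndarray,
    config: AgentConfig,
    mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Select an action from Q-values under the configured policy.

    ``mask`` marks available actions with True; masked actions are excluded
    both from exploration and exploitation.  Epsilon-greedy picks the argmax
    (ties uniform) with probability ``1 - epsilon`` and otherwise a uniform
    available action; softmax samples with probability proportional to
    ``exp(value / tau)`` over available actions.
    """
    rng = rng if rng is not None else np.random.default_rng()
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(len(values), dtype=bool)
    available = np.flatnonzero(mask)
    if len(available) == 0:
        raise ValueError("all actions are masked")
    if config.policy == "softmax":
        z = values[available] / config.tau
        p = np.exp(z - z.max())
        p /= p.sum()
        return int(rng.choice(available, p=p))
    if rng.random() < config.epsilon:
        return int(rng.choice(available))
    return int(available[argmax_random_tie(values[available], rng)])


def compute_action_mask(spec: GridworldSpec, state: int) -> np.ndarray:
    """Mask out actions that cannot change the state.

    Action ``a`` is masked exactly when ``transitions[s, a, s] == 1``, i.e.,
    the action is a guaranteed self-transition (a wall or one-way door).
    """
    return spec.transitions[state, :, state] != 1.0
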