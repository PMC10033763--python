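"""Discrete environments: tabular dynamics with per-state observations.

Same dynamics as the gridworld interface, but `step`/`reset` return
observations (vectors or images) instead of state indices.  If no observation
map is supplied, a one-hot encoding of the states is generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridworld import GridworldSpec, gridworld_reset, gridworld_step, validate_spec


@dataclass
class DiscreteEnvSpec:
    """Tabular dynamics plus a complete state -> observation mapping."""

    base: GridworldSpec
    observations: dict[int, np.ndarray]

    def observation(self, state: int) -> np.ndarray:
        return self.observations[state]


def attach_observations(
    spec: GridworldSpec, obs_map: dict[int, np.ndarray] | None = None
) -> DiscreteEnvSpec:
    """Attach per-state observations to a tabular spec.

    ``obs_map`` must cover every state; if absent, observations default to the
    one-hot encoding of the state index (length ``|S|`` unit vectors).
    """
    validate_spec(spec)
    S = spec.n_states
    if obs_map is None:
        eye = np.eye(S)
        obs_map = {s: eye[s] for s in range(S)}
    else:
        missing = [s for s in range(S) if s not in obs_map]
        if missing:
            raise ValueError(f"observation map missing states {missing[:5]}")
        obs_map = {s: np.asarray(obs_map[s]) for s in range(S)}
    return DiscreteEnvSpec(spec, obs_map)


class DiscreteEnv:
    """Step/reset environment returning observations instead of indices.

    ``.state`` still exposes the underlying state index for monitoring.
    """

    def __init__(self, spec: DiscreteEnvSpec):
        self.spec = spec
        self.state: int | None = None

    @property
    def n_actions(self) -> int:
        return self.spec.base.n_actions

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        self.state = gridworld_reset(self.spec.base, rng)
        return self.spec.observation(self.state)

    def step(self, action: int, rng: np.random.Generator):
        self.state, reward, terminal = gridworld_step(self.spec.base, self.state, action, rng)
        return self.spec.observation(self.state), reward, terminal
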