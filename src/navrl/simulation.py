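"""Closed-loop, trial-based simulation core.

Learning is structured into trials: each trial runs until the environment
reports a terminal state or a step timeout (the time horizon) is reached, and
every step yields an experience tuple ``(s_t, a_t, r_t, s_{t+1}, terminal)``
that the agent learns from.  Callbacks fire at trial/step boundaries in the
fixed order ``trial_begin, (step_begin, step_end) * steps, trial_end`` and
receive the current trial information; monitors are pure observers updated
from those callback calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class Experience:
    """One agent-environment step: (state, action, reward, next state, terminal).

    ``state``/``next_state`` are whatever the environment emits (a state index
    for tabular interfaces, an observation vector for discrete/deep ones).
    """

    state: object
    action: int
    reward: float
    next_state: object
    terminal: bool


@dataclass
class TrialRecord:
    """Monitored outcome of a single trial."""

    trial: int
    steps: int
    reward: float
    response: int
    trajectory: list
    reached_terminal: bool


@dataclass
class SessionLog:
    """Ordered trial records plus run metadata (seed, config description)."""

    records: list[TrialRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def series(self, name: str) -> np.ndarray:
        return np.asarray([getattr(r, name) for r in self.records])

    # -- persistence ------------------------------------------------------
    def to_jsonl(self, path) -> None:
        """One JSON trial record per line, with a metadata header line."""
        with open(path, "w") as fh:
            fh.write(json.dumps({"metadata": self.metadata}) + "\n")
            for r in self.records:
                d = asdict(r)
                d["trajectory"] = [list(p) if isinstance(p, (tuple, list)) else p
                                   for p in d["trajectory"]]
                fh.write(json.dumps(d) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "SessionLog":
        with open(path) as fh:
            lines = [json.loads(line) for line in fh if line.strip()]
        log = cls(metadata=lines[0]["metadata"])
        for d in lines[1:]:
            d["trajectory"] = [tuple(p) if isinstance(p, list) else p
                               for p in d["trajectory"]]
            log.records.append(TrialRecord(**d))
        return log

    def summary_frame(self):
        """Per-trial summary table (trial, steps, reward, response)."""
        import pandas as pd

        return pd.DataFrame({
            "trial": self.series("trial"),
            "steps": self.series("steps"),
            "reward": self.series("reward"),
            "response": self.series("response"),
        })


HOOKS = ("trial_begin", "trial_end", "step_begin", "step_end")


class CallbackSet:
    """Keyed lists of procedures fired at trial/step boundaries."""

    def __init__(self, callbacks: dict | None = None):
        self.hooks: dict[str, list] = {h: [] for h in HOOKS}
        for name, fns in (callbacks or {}).items():
            if name not in HOOKS:
                raise ValueError(f"unknown hook {name!r}; valid hooks: {HOOKS}")
            self.hooks[name] = list(fns) if isinstance(fns, (list, tuple)) else [fns]

    def fire(self, hook: str, logs: dict) -> None:
        for fn in self.hooks[hook]:
            fn(logs)


# -- monitors --------------------------------------------------------------

def escape_latency_monitor(record: TrialRecord) -> int:
    """Steps needed to complete the trial (the escape latency)."""
    return record.steps


def reward_monitor(record: TrialRecord) -> float:
    """Cumulative reward received in the trial."""
    return record.reward


def response_monitor(record: TrialRecord, coding_fn=None) -> int:
    """Trial response code: default 1 if reward was collected, else 0."""
    if coding_fn is not None:
        return coding_fn(record)
    return int(record.reward > 0)


def trajectory_monitor(record: TrialRecord) -> list:
    """The agent's position at each step (length steps + 1, starts at reset)."""
    return record.trajectory


def unit_response_monitor(network, probe_batch: np.ndarray) -> list[np.ndarray]:
    """Per-layer activation tensors of a network for a batch of probe observations."""
    return network.activations(np.asarray(probe_batch, dtype=float))


class Monitor:
    """Base observer: collects one value per trial via a pure record function."""

    def __init__(self, fn):
        self.fn = fn
        self.values: list = []

    def on_trial_end(self, record: TrialRecord) -> None:
        self.values.append(self.fn(record))


# -- session loop ----------------------------------------------------------

def run_session(
    agent,
    env,
    n_trials: int,
    max_steps: int = 100,
    callbacks: CallbackSet | dict | None = None,
    monitors: list[Monitor] | None = None,
    seed: int = 0,
    response_fn=None,
) -> SessionLog:
    """Run a trial-based closed-loop training session.

    One master seed fans out to separate environment and agent generators so
    runs are reproducible component by component.  ``response_fn(record, env)``
    may override the default reward-collected response coding.  Returns a
    :class:`SessionLog`; re-running with the same configuration and seed
    reproduces it bit-identically.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cbs = callbacks if isinstance(callbacks, CallbackSet) else CallbackSet(callbacks)
    monitors = monitors or []
    env_seed, agent_seed = np.random.SeedSequence(seed).spawn(2)
    env_rng = np.random.default_rng(env_seed)
    agent_rng = np.random.default_rng(agent_seed)
    log = SessionLog(metadata={"seed": seed, "n_trials": n_trials, "max_steps": max_steps})
    for trial in range(n_trials):
        cbs.fire("trial_begin", {"trial": trial, "env": env, "agent": agent})
        obs = env.reset(env_rng)
        agent.begin_trial()
        trajectory = [getattr(env, "state", obs)]
        total_reward = 0.0
        reached_terminal = False
        steps = 0
        for _ in range(max_steps):
            cbs.fire("step_begin", {"trial": trial, "step": steps, "env": env,
                                    "agent": agent})
            action = agent.act(obs, agent_rng)
            next_obs, reward, terminal = env.step(action, env_rng)
            exp = Experience(obs, action, reward, next_obs, terminal)
            agent.observe(exp, agent_rng)
            steps += 1
            total_reward += reward
            trajectory.append(getattr(env, "state", next_obs))
            cbs.fire("step_end", {"trial": trial, "step": steps - 1, "env": env,
                                  "agent": agent, "experience": exp})
            obs = next_obs
            if terminal:
                reached_terminal = True
                break
        agent.end_trial(agent_rng)
        record = TrialRecord(trial, steps, total_reward, 0, trajectory, reached_terminal)
        record.response = (response_fn(record, env) if response_fn
                           else response_monitor(record))
        log.records.append(record)
        for m in monitors:
            m.on_trial_end(record)
        cbs.fire("trial_end", {"trial": trial, "record": record, "env": env,
                               "agent": agent})
    return log
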