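"""Tabular gridworld environments.

A gridworld is described by a state-action-state transition tensor of shape
``|S| x |A| x |S|`` with ``|A| = 4`` actions (up, down, left, right), a real
reward table and a binary terminal table of length ``|S|``, a list of starting
states, and per-state grid coordinates.  States are indexed row-major with row
0 at the top; action "up" decreases the row index.  Invalid moves (off the
grid, or through a blocked edge) are self-transitions rather than errors, which
lets an action mask be derived directly from the transition tensor.

Rewards follow the reward-on-entry convention: the reward collected on a step
is ``rewards[next_state]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

N_ACTIONS = 4
UP, DOWN, LEFT, RIGHT = 0, 1, 2, 3
#: (row delta, col delta) per action, in action order (up, down, left, right).
ACTION_DELTAS = ((-1, 0), (1, 0), (0, -1), (0, 1))

FORMAT_VERSION = 1


@dataclass
class GridworldSpec:
    """Complete tabular description of a gridworld environment."""

    height: int
    width: int
    transitions: np.ndarray  # (S, 4, S) row-stochastic
    rewards: np.ndarray  # (S,)
    terminals: np.ndarray  # (S,) 0/1
    starting_states: list[int]
    coordinates: np.ndarray  # (S, 2) (x, y) in grid units
    invalid_transitions: list[tuple[int, int]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.transitions.shape[0]

    @property
    def n_actions(self) -> int:
        return self.transitions.shape[1]

    def copy(self) -> "GridworldSpec":
        return replace(
            self,
            transitions=self.transitions.copy(),
            rewards=self.rewards.copy(),
            terminals=self.terminals.copy(),
            starting_states=list(self.starting_states),
            coordinates=self.coordinates.copy(),
            invalid_transitions=list(self.invalid_transitions),
            metadata=dict(self.metadata),
        )


def validate_spec(spec: GridworldSpec, atol: float = 1e-9) -> None:
    """Check the structural invariants of a :class:`GridworldSpec`.

    Raises ``ValueError`` on the first violated invariant: transition rows must
    sum to one, probabilities must lie in [0, 1], terminals must be binary, the
    starting set must be a subset of the states and disjoint from the terminal
    set, and the action count must be four.
    """
    T = np.asarray(spec.transitions, dtype=float)
    if T.ndim != 3 or T.shape[0] != T.shape[2]:
        raise ValueError(f"transition tensor must be (S, A, S), got {T.shape}")
    if T.shape[1] != N_ACTIONS:
        raise ValueError(f"gridworlds have exactly {N_ACTIONS} actions, got {T.shape[1]}")
    if np.any(T < -atol) or np.any(T > 1 + atol):
        raise ValueError("transition probabilities must lie in [0, 1]")
    row_sums = T.sum(axis=2)
    if not np.allclose(row_sums, 1.0, atol=atol):
        bad = np.argwhere(~np.isclose(row_sums, 1.0, atol=atol))[0]
        raise ValueError(
            f"transition row (s={bad[0]}, a={bad[1]}) sums to {row_sums[tuple(bad)]}, not 1"
        )
    S = T.shape[0]
    terminals = np.asarray(spec.terminals)
    if terminals.shape != (S,) or not np.isin(terminals, (0, 1)).all():
        raise ValueError("terminals must be a binary table of length |S|")
    if np.asarray(spec.rewards).shape != (S,):
        raise ValueError("rewards must be a table of length |S|")
    starts = list(spec.starting_states)
    if any(s < 0 or s >= S for s in starts):
        raise ValueError("starting states must be valid state indices")
    if any(terminals[s] for s in starts):
        raise ValueError("starting states must be disjoint from terminal states")
    if np.asarray(spec.coordinates).shape != (S, 2):
        raise ValueError("coordinates must be (S, 2)")


def _deterministic_transitions(
    cells: list[tuple[int, int]],
    blocked: set[tuple[int, int, int, int]] | None = None,
    one_way: set[tuple[int, int, int, int]] | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Build a deterministic transition tensor over an explicit cell list.

    ``cells`` lists the (row, col) of every state, in state-index order.  Moves
    to a cell not in the list, through a ``blocked`` edge, or against a
    ``one_way`` edge are self-transitions.  Edges are keyed (r, c, r2, c2) for
    the move from (r, c) to (r2, c2).
    """
    blocked = blocked or set()
    one_way = one_way or set()
    index = {cell: i for i, cell in enumerate(cells)}
    S = len(cells)
    T = np.zeros((S, N_ACTIONS, S))
    invalid: list[tuple[int, int]] = []
    for s, (r, c) in enumerate(cells):
        for a, (dr, dc) in enumerate(ACTION_DELTAS):
            edge = (r, c, r + dr, c + dc)
            target = index.get((r + dr, c + dc))
            ok = target is not None and edge not in blocked
            if ok and one_way and (r + dr, c + dc, r, c) in one_way:
                ok = False  # moving against a one-way door
            if ok:
                T[s, a, target] = 1.0
            else:
                T[s, a, s] = 1.0
                invalid.append((s, a))
    return T, invalid


def make_open_field(
    height: int,
    width: int,
    goal_state: int | None = None,
    goal_reward: float = 1.0,
) -> GridworldSpec:
    """Open rectangular field, optionally with a single terminal goal.

    Off-grid moves are self-transitions.  With a goal, the goal state is
    terminal, carries ``goal_reward``, and every other state is a possible
    starting state.  With ``goal_state=None`` the field has no terminal and all
    states are starting states (useful for free-exploration tasks).
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be positive")
    S = height * width
    if goal_state is not None and not (0 <= goal_state < S):
        raise ValueError(f"goal state {goal_state} out of range for {S} states")
    cells = [(r, c) for r in range(height) for c in range(width)]
    T, invalid = _deterministic_transitions(cells)
    rewards = np.zeros(S)
    terminals = np.zeros(S, dtype=int)
    if goal_state is not None:
        rewards[goal_state] = goal_reward
        terminals[goal_state] = 1
    starts = [s for s in range(S) if not terminals[s]]
    coords = np.array([(c, r) for r, c in cells], dtype=float)
    spec = GridworldSpec(
        height, width, T, rewards, terminals, starts, coords, invalid,
        metadata={"template": "open_field"},
    )
    validate_spec(spec)
    return spec


def make_t_maze(
    stem_length: int = 3,
    arm_length: int = 2,
    rewarded_arm: str = "right",
    reward: float = 1.0,
) -> GridworldSpec:
    """T-maze: a vertical stem joined to a horizontal crossbar.

    Both arm ends are terminal; only the rewarded end carries reward.  The
    agent starts at the stem base.  States are the maze cells only (crossbar
    row first, then the stem, top to bottom), ``2*arm_length + 1 +
    stem_length`` in total.
    """
    if stem_length < 1 or arm_length < 1:
        raise ValueError("stem and arm lengths must be >= 1")
    if rewarded_arm not in ("left", "right"):
        raise ValueError(f"rewarded_arm must be 'left' or 'right', got {rewarded_arm!r}")
    mid = arm_length
    crossbar = [(0, c) for c in range(2 * arm_length + 1)]
    stem = [(r, mid) for r in range(1, stem_length + 1)]
    cells = crossbar + stem
    T, invalid = _deterministic_transitions(cells)
    S = len(cells)
    left_end, right_end = 0, 2 * arm_length
    rewards = np.zeros(S)
    terminals = np.zeros(S, dtype=int)
    terminals[[left_end, right_end]] = 1
    rewards[right_end if rewarded_arm == "right" else left_end] = reward
    start = S - 1  # stem base
    coords = np.array([(c, r) for r, c in cells], dtype=float)
    spec = GridworldSpec(
        stem_length + 1, 2 * arm_length + 1, T, rewards, terminals, [start], coords,
        invalid,
        metadata={
            "template": "t_maze",
            "left_end": left_end,
            "right_end": right_end,
            "rewarded_arm": rewarded_arm,
        },
    )
    validate_spec(spec)
    return spec


# Serpentine alley-maze layout used for latent-learning simulations: ALLEYS
# stacked alleys of width ALLEY_SPAN, connected at alternating ends by one-way
# vertical doors (forward passage only), with a dead-end stub past each
# junction.  This is a parameterized abstraction of the classic 6-unit alley
# maze used in latent-learning experiments; the historical apparatus' exact
# cell geometry is not reproduced.
ALLEYS = 7
ALLEY_SPAN = 5


def make_blodgett_maze(goal_reward: float = 1.0) -> GridworldSpec:
    """Six-junction one-way alley maze for latent-learning experiments.

    The maze is a serpentine of seven alleys.  At the end of each alley a
    T-junction offers a dead-end stub straight ahead and a one-way door upward
    into the next alley; the reverse action at a door is a self-transition, so
    the agent cannot retrace its path past a junction.  The start is the
    bottom-left cell and the goal (terminal, rewarded) is the far end of the
    top alley.
    """
    right_junction, right_stub = ALLEY_SPAN - 2, ALLEY_SPAN - 1
    left_junction, left_stub = 1, 0
    cells: list[tuple[int, int]] = []
    one_way: set[tuple[int, int, int, int]] = set()
    bottom = ALLEYS - 1
    for row in range(ALLEYS):
        rightward = (bottom - row) % 2 == 0  # bottom alley runs left-to-right
        if row == bottom:
            cols = range(ALLEY_SPAN)
        elif rightward:
            cols = range(left_junction, ALLEY_SPAN)
        else:
            cols = range(0, right_stub)
        cells.extend((row, c) for c in cols)
        if row < bottom:  # one-way door up from the alley below
            junction = right_junction if (bottom - row) % 2 == 1 else left_junction
            one_way.add((row + 1, junction, row, junction))
    # Alleys are walled off from each other: every vertical edge that is not a
    # one-way door is blocked in both directions.
    cell_set = set(cells)
    blocked: set[tuple[int, int, int, int]] = set()
    for (r, c) in cells:
        if (r + 1, c) in cell_set:
            down, up = (r, c, r + 1, c), (r + 1, c, r, c)
            if up not in one_way:
                blocked.update((down, up))
    T, invalid = _deterministic_transitions(cells, blocked=blocked, one_way=one_way)
    index = {cell: i for i, cell in enumerate(cells)}
    S = len(cells)
    start = index[(bottom, 0)]
    goal = index[(0, max(c for r, c in cells if r == 0))]
    rewards = np.zeros(S)
    terminals = np.zeros(S, dtype=int)
    rewards[goal] = goal_reward
    terminals[goal] = 1
    coords = np.array([(c, r) for r, c in cells], dtype=float)
    spec = GridworldSpec(
        ALLEYS, ALLEY_SPAN, T, rewards, terminals, [start], coords, invalid,
        metadata={"template": "blodgett", "start": start, "goal": goal,
                  "n_one_way_doors": len(one_way)},
    )
    validate_spec(spec)
    return spec


def gridworld_step(
    spec: GridworldSpec, state: int, action: int, rng: np.random.Generator
) -> tuple[int, float, bool]:
    """Sample one environmental transition.

    Returns ``(next_state, reward, terminal)`` with the next state drawn from
    ``transitions[state, action]``, reward indexed by the next state, and the
    terminal flag read from the terminal table.
    """
    if spec.terminals[state]:
        raise ValueError(f"cannot step from terminal state {state}")
    if not (0 <= action < spec.n_actions):
        raise ValueError(f"action {action} out of range")
    row = spec.transitions[state, action]
    next_state = int(rng.choice(spec.n_states, p=row))
    return next_state, float(spec.rewards[next_state]), bool(spec.terminals[next_state])


def gridworld_reset(spec: GridworldSpec, rng: np.random.Generator) -> int:
    """Draw a starting state uniformly from the starting set."""
    if not spec.starting_states:
        raise ValueError("starting set is empty")
    return int(rng.choice(spec.starting_states))


def save_env(spec: GridworldSpec, path) -> None:
    """Serialize a gridworld to the portable JSON schema."""
    payload = {
        "format_version": FORMAT_VERSION,
        "height": spec.height,
        "width": spec.width,
        "transitions": spec.transitions.tolist(),
        "rewards": spec.rewards.tolist(),
        "terminals": spec.terminals.astype(int).tolist(),
        "starting_states": [int(s) for s in spec.starting_states],
        "coordinates": spec.coordinates.tolist(),
        "invalid_transitions": [[int(s), int(a)] for s, a in spec.invalid_transitions],
        "metadata": spec.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_env(path) -> GridworldSpec:
    """Load a gridworld from JSON, re-running all invariant checks."""
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported format_version {version!r}")
    spec = GridworldSpec(
        height=int(payload["height"]),
        width=int(payload["width"]),
        transitions=np.asarray(payload["transitions"], dtype=float),
        rewards=np.asarray(payload["rewards"], dtype=float),
        terminals=np.asarray(payload["terminals"], dtype=int),
        starting_states=[int(s) for s in payload["starting_states"]],
        coordinates=np.asarray(payload["coordinates"], dtype=float),
        invalid_transitions=[(int(s), int(a)) for s, a in payload["invalid_transitions"]],
        metadata=payload.get("metadata", {}),
    )
    validate_spec(spec)
    return spec


class GridworldEnv:
    """Minimal step/reset environment over a :class:`GridworldSpec`.

    Observations are raw state indices; use :class:`~navrl.envs.discrete.DiscreteEnv`
    for vector or image observations.
    """

    def __init__(self, spec: GridworldSpec):
        validate_spec(spec)
        self.spec = spec
        self.state: int | None = None

    @property
    def n_actions(self) -> int:
        return self.spec.n_actions

    def reset(self, rng: np.random.Generator) -> int:
        self.state = gridworld_reset(self.spec, rng)
        return self.state

    def step(self, action: int, rng: np.random.Generator) -> tuple[int, float, bool]:
        nxt, reward, terminal = gridworld_step(self.spec, self.state, action, rng)
        self.state = nxt
        return nxt, reward, terminal
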