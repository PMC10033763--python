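"""Topology-graph environments: rectangular and hexagonal lattices.

A topology graph abstracts navigable space into nodes and edges.  Movement is
either translation to the neighboring node lying in one of ``n_headings``
evenly spaced compass directions (4 for rectangular, 6 for hexagonal lattices),
or — in rotation mode — turning in place to face one of those directions.
Rotation mode doubles the action space: actions ``0..n-1`` translate toward
direction ``k``, actions ``n..2n-1`` rotate the agent to face direction
``k - n``.  Translations toward a missing neighbor leave the state unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TopologyGraph:
    """Node/edge description of navigable space with optional rotations."""

    nodes: np.ndarray  # (N, 2) positions
    kind: str  # "rect" | "hex"
    n_headings: int
    spacing: float
    rotation_mode: bool = False
    #: neighbors[i][d] = node index of i's neighbor in heading direction d, or -1
    neighbors: np.ndarray = field(default=None)  # (N, n_headings)
    goal_node: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_actions(self) -> int:
        return 2 * self.n_headings if self.rotation_mode else self.n_headings

    def heading_angle(self, heading: int) -> float:
        """Angle (radians, CCW from +x) of a heading slot."""
        return 2.0 * np.pi * heading / self.n_headings

    def degree(self, node: int) -> int:
        return int((self.neighbors[node] >= 0).sum())

    def edges(self) -> list[tuple[int, int]]:
        out = set()
        for i in range(self.n_nodes):
            for j in self.neighbors[i]:
                if j >= 0:
                    out.add((min(i, int(j)), max(i, int(j))))
        return sorted(out)


def build_topology_graph(
    kind: str,
    nx: int,
    ny: int,
    spacing: float = 1.0,
    rotation_mode: bool = False,
    goal_node: int | None = None,
) -> TopologyGraph:
    """Build a rectangular (4 headings) or hexagonal (6 headings) lattice.

    Hexagonal lattices use offset rows a distance ``spacing * sqrt(3)/2``
    apart, so every interior node has six equidistant neighbors 60 degrees
    apart; rectangular lattices give four neighbors 90 degrees apart.
    """
    if kind not in ("rect", "hex"):
        raise ValueError(f"kind must be 'rect' or 'hex', got {kind!r}")
    if nx < 2 or ny < 2:
        raise ValueError("lattice needs at least 2x2 nodes")
    positions = []
    for j in range(ny):
        for i in range(nx):
            if kind == "rect":
                positions.append((i * spacing, j * spacing))
            else:
                positions.append(((i + 0.5 * (j % 2)) * spacing,
                                  j * spacing * np.sqrt(3) / 2))
    nodes = np.asarray(positions, dtype=float)
    n_headings = 4 if kind == "rect" else 6
    angles = 2.0 * np.pi * np.arange(n_headings) / n_headings
    offsets = spacing * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    neighbors = np.full((len(nodes), n_headings), -1, dtype=int)
    lookup = {tuple(np.round(p / spacing * 4).astype(int)): i
              for i, p in enumerate(nodes)}
    for i, p in enumerate(nodes):
        for d in range(n_headings):
            key = tuple(np.round((p + offsets[d]) / spacing * 4).astype(int))
            neighbors[i, d] = lookup.get(key, -1)
    return TopologyGraph(nodes, kind, n_headings, spacing, rotation_mode,
                         neighbors, goal_node)


def graph_step(
    graph: TopologyGraph, node: int, heading: int, action: int
) -> tuple[int, int]:
    """Apply one graph action; returns the new ``(node, heading)``.

    Translation action ``k`` (k < n_headings) moves to the neighbor in compass
    direction ``k`` and leaves the heading unchanged; missing neighbors make
    the move a no-op.  In rotation mode, action ``n_headings + k`` turns the
    agent in place to face direction ``k``.
    """
    n = graph.n_headings
    if not (0 <= action < graph.n_actions):
        raise ValueError(f"action {action} out of range for {graph.n_actions} actions")
    if not (0 <= node < graph.n_nodes and 0 <= heading < n):
        raise ValueError("invalid node or heading")
    if action < n:
        target = graph.neighbors[node, action]
        return (int(target), heading) if target >= 0 else (node, heading)
    return node, action - n


def shortest_path_length(graph: TopologyGraph, a: int, b: int) -> int:
    """Breadth-first shortest path (in edges) between two nodes."""
    import networkx as netx

    g = netx.Graph(graph.edges())
    g.add_nodes_from(range(graph.n_nodes))
    return netx.shortest_path_length(g, a, b)


class GraphEnv:
    """Goal-finding environment on a topology graph.

    State is a ``(node, heading)`` pair.  Each trial starts at a random
    non-goal node (and random heading); reaching the goal node ends the trial
    with reward ``goal_reward``.  Observations are produced by ``obs_fn(node,
    heading)``; by default the raw ``(node, heading)`` pair is returned.
    """

    def __init__(self, graph: TopologyGraph, goal_node: int | None = None,
                 goal_reward: float = 1.0, obs_fn=None):
        self.graph = graph
        self.goal_node = goal_node if goal_node is not None else graph.goal_node
        if self.goal_node is None:
            raise ValueError("goal node required")
        self.goal_reward = goal_reward
        self.obs_fn = obs_fn or (lambda node, heading: (node, heading))
        self.state: tuple[int, int] | None = None

    @property
    def n_actions(self) -> int:
        return self.graph.n_actions

    def reset(self, rng: np.random.Generator):
        starts = [i for i in range(self.graph.n_nodes) if i != self.goal_node]
        node = int(rng.choice(starts))
        heading = int(rng.integers(self.graph.n_headings))
        self.state = (node, heading)
        return self.obs_fn(node, heading)

    def step(self, action: int, rng: np.random.Generator):
        node, heading = graph_step(self.graph, *self.state, action)
        self.state = (node, heading)
        terminal = node == self.goal_node
        reward = self.goal_reward if terminal else 0.0
        return self.obs_fn(node, heading), reward, terminal
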