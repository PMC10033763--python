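"""Place-field emergence during goal learning on a hexagonal topology graph.

A DQN agent learns to navigate to an unmarked goal node from random starting
positions on a hexagonal graph with rotations (six translations plus six
rotations, twelve actions).  Observations combine a procedurally rendered
per-(node, heading) image with a pose channel.  At fixed trial checkpoints the
spatial activity maps of all units preceding the output layer are recorded on
a probe grid for all six headings, and the number of place-cell-like units is
counted; with learning, spatially confined firing tends to emerge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..agents.dqn import DQNAgent, DQNConfig
from ..analysis import (
    PlaceFieldParams,
    SpatialActivityMap,
    compute_activity_maps,
    network_probe,
    place_cell_trajectory,
)
from ..envs.topology import GraphEnv, build_topology_graph
from ..observations import synthesize_state_images
from ..simulation import SessionLog, run_session


@dataclass
class PlaceFieldEmergenceResult:
    counts: list[int]  # place-cell count per checkpoint
    checkpoint_trials: list[int]
    checkpoints: list[SpatialActivityMap]
    log: SessionLog


def _make_graph_env(nx: int, ny: int, image_size, seed: int):
    graph = build_topology_graph("hex", nx, ny, spacing=1.0, rotation_mode=True)
    goal = (ny // 2) * nx + nx // 2  # central node
    obs_set = synthesize_state_images(graph.n_nodes, image_size, seed=seed,
                                      n_headings=graph.n_headings)
    xmax, ymax = graph.nodes.max(axis=0)

    def node_obs(node: int, heading: int) -> np.ndarray:
        x, y = graph.nodes[node]
        return _pose_image_obs(obs_set.get(node, heading), x, y, heading,
                               xmax, ymax, graph.n_headings)

    def probe_obs(x: float, y: float, heading: int) -> np.ndarray:
        node = int(np.argmin(np.linalg.norm(graph.nodes - [x, y], axis=1)))
        return _pose_image_obs(obs_set.get(node, heading), x, y, heading,
                               xmax, ymax, graph.n_headings)

    env = GraphEnv(graph, goal_node=goal, obs_fn=node_obs)
    return env, graph, probe_obs


def _pose_image_obs(image, x, y, heading, xmax, ymax, n_headings) -> np.ndarray:
    angle = 2.0 * np.pi * heading / n_headings
    pose = np.array([x / xmax, y / ymax, np.cos(angle), np.sin(angle)])
    return np.concatenate([image.ravel(), pose])


def run_place_field_emergence(
    n_trials: int = 2400,
    checkpoint_every: int = 800,
    seed: int = 0,
    nx: int = 6,
    ny: int = 5,
    image_size: tuple[int, int] = (8, 8),
    resolution: int = 25,
    max_steps: int = 60,
    params: PlaceFieldParams | None = None,
) -> PlaceFieldEmergenceResult:
    """Train a DQN on the hexagonal goal task, mapping units at checkpoints.

    Checkpoints fall at trials 0, ``checkpoint_every``, ... plus one after the
    final trial, ``n_trials // checkpoint_every + 1`` in total.  Maps are
    recorded on a ``resolution x resolution`` probe grid for all six headings
    from the last hidden layer (the units preceding the action-selection
    output layer).
    """
    env, graph, probe_obs = _make_graph_env(nx, ny, image_size, seed)
    obs_dim = image_size[0] * image_size[1] + 4
    agent = DQNAgent(
        input_dim=obs_dim, n_actions=graph.n_actions,
        config=DQNConfig(gamma=0.9, epsilon=0.2, lr=2e-3, hidden=(64, 64),
                         batch_size=32, buffer_capacity=20_000, target_sync=100),
        seed=seed,
    )
    pad = 1e-6  # keep probe points within the node hull
    xmax, ymax = graph.nodes.max(axis=0)
    extent = (0.0, float(xmax) - pad, 0.0, float(ymax) - pad)
    headings = tuple(range(graph.n_headings))
    checkpoints: list[SpatialActivityMap] = []
    checkpoint_trials: list[int] = []

    def snapshot(trial: int) -> None:
        fn = network_probe(agent.online, probe_obs, layer=-2)
        checkpoints.append(compute_activity_maps(fn, extent, resolution, headings))
        checkpoint_trials.append(trial)

    def checkpoint_cb(logs):
        if logs["trial"] % checkpoint_every == 0:
            snapshot(logs["trial"])

    log = run_session(agent, env, n_trials=n_trials, max_steps=max_steps,
                      callbacks={"trial_begin": checkpoint_cb}, seed=seed)
    snapshot(n_trials)
    counts = place_cell_trajectory(checkpoints, params)
    return PlaceFieldEmergenceResult(counts, checkpoint_trials, checkpoints, log)
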