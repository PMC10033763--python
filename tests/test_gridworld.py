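"""Gridworld construction, stepping, one-way mazes, and serialization."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from navrl.envs import (
    GridworldEnv,
    gridworld_reset,
    gridworld_step,
    load_env,
    make_blodgett_maze,
    make_open_field,
    make_t_maze,
    save_env,
    validate_spec,
)
from navrl.envs.gridworld import GridworldSpec, UP, DOWN, LEFT, RIGHT


def digraph_of(spec):
    g = nx.DiGraph()
    g.add_nodes_from(range(spec.n_states))
    for s in range(spec.n_states):
        for a in range(spec.n_actions):
            t = int(np.argmax(spec.transitions[s, a]))
            if spec.transitions[s, a, t] == 1.0 and t != s:
                g.add_edge(s, t)
    return g


class TestOpenField:
    def test_construction(self):
        spec = make_open_field(5, 5, 24, 1.0)
        assert spec.n_states == 25
        expected_r = np.zeros(25)
        expected_r[24] = 1.0
        assert np.array_equal(spec.rewards, expected_r)
        assert spec.terminals.sum() == 1 and spec.terminals[24] == 1
        assert sorted(spec.starting_states) == list(range(24))

    def test_boundary_self_transitions(self):
        spec = make_open_field(1, 2, 1, 1.0)
        # action right from state 0 reaches state 1; up stays put
        assert np.argmax(spec.transitions[0, RIGHT]) == 1
        assert spec.transitions[0, UP, 0] == 1.0

    @given(h=st.integers(1, 6), w=st.integers(1, 6))
    @settings(max_examples=20, deadline=None)
    def test_rows_stochastic_any_size(self, h, w):
        spec = make_open_field(h, w, goal_state=h * w - 1)
        assert np.allclose(spec.transitions.sum(axis=2), 1.0)
        validate_spec(spec)

    def test_errors(self):
        with pytest.raises(ValueError):
            make_open_field(0, 5)
        with pytest.raises(ValueError):
            make_open_field(2, 2, goal_state=4)


class TestTMaze:
    def test_construction(self, t_maze):
        assert t_maze.n_states == 8
        left, right = t_maze.metadata["left_end"], t_maze.metadata["right_end"]
        assert t_maze.terminals[left] == 1 and t_maze.terminals[right] == 1
        assert t_maze.rewards[right] == 1.0 and t_maze.rewards[left] == 0.0

    def test_reward_swap_keeps_transitions(self, t_maze):
        other = make_t_maze(3, 2, "left", 1.0)
        left, right = t_maze.metadata["left_end"], t_maze.metadata["right_end"]
        assert other.rewards[left] == 1.0 and other.rewards[right] == 0.0
        assert np.array_equal(other.transitions, t_maze.transitions)

    @pytest.mark.parametrize("stem,arm", [(3, 2), (1, 1), (4, 3)])
    def test_shortest_path_length(self, stem, arm):
        """BFS distance start -> rewarded end equals stem + arm length."""
        spec = make_t_maze(stem, arm, "right")
        g = digraph_of(spec)
        d = nx.shortest_path_length(g, spec.starting_states[0],
                                    spec.metadata["right_end"])
        assert d == stem + arm

    def test_invalid_arm(self):
        with pytest.raises(ValueError):
            make_t_maze(3, 2, "up")


class TestBlodgettMaze:
    def test_one_way_door_semantics(self, blodgett):
        """Forward passage through a door succeeds; the reverse action is a
        self-transition."""
        doors = [
            (s, a, int(np.argmax(blodgett.transitions[s, a])))
            for s in range(blodgett.n_states)
            for a in (UP,)
            if blodgett.transitions[s, a].argmax() != s
            and blodgett.transitions[int(np.argmax(blodgett.transitions[s, a])), DOWN,
                                     int(np.argmax(blodgett.transitions[s, a]))] == 1.0
        ]
        assert len(doors) == blodgett.metadata["n_one_way_doors"] == 6
        for s, a, t in doors:
            assert blodgett.transitions[s, a, t] == 1.0  # forward allowed
            assert blodgett.transitions[t, DOWN, t] == 1.0  # reverse blocked

    def test_start_and_goal(self, blodgett):
        start, goal = blodgett.metadata["start"], blodgett.metadata["goal"]
        assert blodgett.starting_states == [start]
        assert blodgett.terminals[goal] == 1 and blodgett.rewards[goal] == 1.0

    def test_reachability(self, blodgett):
        """Goal reachable from start; start unreachable once past the first
        one-way door."""
        g = digraph_of(blodgett)
        start, goal = blodgett.metadata["start"], blodgett.metadata["goal"]
        assert nx.has_path(g, start, goal)
        # states beyond the first door: everything not in the bottom alley
        bottom = [s for s, (x, y) in enumerate(blodgett.coordinates)
                  if y == blodgett.coordinates[:, 1].max()]
        beyond = set(range(blodgett.n_states)) - set(bottom)
        assert beyond and not any(nx.has_path(g, s, start) for s in beyond)


class TestStepAndReset:
    def test_step_semantics(self, open_field_5x5, rng):
        # interior state 12: action up decreases index by width
        nxt, r, t = gridworld_step(open_field_5x5, 12, UP, rng)
        assert (nxt, r, t) == (7, 0.0, False)
        # wall bump: same state, not terminal
        nxt, r, t = gridworld_step(open_field_5x5, 0, UP, rng)
        assert (nxt, t) == (0, False)
        # entering the goal yields its reward and ends the trial
        nxt, r, t = gridworld_step(open_field_5x5, 23, RIGHT, rng)
        assert (nxt, r, t) == (24, 1.0, True)

    def test_step_errors(self, open_field_5x5, rng):
        with pytest.raises(ValueError):
            gridworld_step(open_field_5x5, 24, UP, rng)  # terminal
        with pytest.raises(ValueError):
            gridworld_step(open_field_5x5, 0, 7, rng)  # bad action

    def test_stochastic_row_frequencies(self, rng):
        """Sampling a (0.5, 0.5) row matches the binomial 99% CI."""
        spec = make_open_field(1, 3)
        spec.transitions[0, RIGHT] = [0.0, 0.5, 0.5]
        n = 10_000
        hits = sum(gridworld_step(spec, 0, RIGHT, rng)[0] == 1 for _ in range(n))
        ci = 2.576 * np.sqrt(0.25 * n)
        assert abs(hits - n / 2) < ci

    def test_reset_distribution(self, rng):
        single = make_t_maze(2, 1)
        assert all(gridworld_reset(single, rng) == single.starting_states[0]
                   for _ in range(20))
        two = make_open_field(1, 3, goal_state=2)
        draws = np.array([gridworld_reset(two, rng) for _ in range(10_000)])
        assert abs((draws == 0).mean() - 0.5) < 0.013  # binomial 99% CI
        empty = make_open_field(2, 2)
        empty.starting_states = []
        with pytest.raises(ValueError):
            gridworld_reset(empty, rng)


class TestSerialization:
    def test_round_trip(self, blodgett, tmp_path):
        path = tmp_path / "env.json"
        save_env(blodgett, path)
        loaded = load_env(path)
        assert np.array_equal(loaded.transitions, blodgett.transitions)
        assert np.array_equal(loaded.rewards, blodgett.rewards)
        assert np.array_equal(loaded.terminals, blodgett.terminals)
        assert loaded.starting_states == blodgett.starting_states
        assert loaded.invalid_transitions == blodgett.invalid_transitions

    def test_load_rejects_bad_rows(self, open_field_5x5, tmp_path):
        path = tmp_path / "bad.json"
        open_field_5x5.transitions[3, 0] *= 0.9
        save_env(open_field_5x5, path)
        with pytest.raises(ValueError, match="sums to"):
            load_env(path)

    def test_validate_rejects_terminal_start(self, open_field_5x5):
        open_field_5x5.starting_states = [24]
        with pytest.raises(ValueError, match="disjoint"):
            validate_spec(open_field_5x5)


def test_deterministic_specs_step_pure(open_field_5x5):
    """On a deterministic spec, step outcome is a pure function of (s, a)."""
    r1 = np.random.default_rng(0)
    r2 = np.random.default_rng(99)
    for s in range(24):
        for a in range(4):
            assert gridworld_step(open_field_5x5, s, a, r1) == \
                gridworld_step(open_field_5x5, s, a, r2)
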