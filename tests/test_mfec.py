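"""Model-free episodic control: projection, one-shot updates, k-NN lookup."""

import numpy as np
import pytest

from navrl.agents import (
    EpisodicStore,
    MFECConfig,
    mfec_episode_update,
    mfec_project,
    mfec_q_estimate,
)


@pytest.fixture
def store():
    return EpisodicStore(obs_dim=32, n_actions=3, config=MFECConfig(key_dim=8, k=3))


class TestProjection:
    def test_reproducible_keys(self, store, rng):
        obs = rng.normal(size=32)
        other = EpisodicStore(32, 3, MFECConfig(key_dim=8, k=3))
        assert np.array_equal(mfec_project(store, obs), mfec_project(other, obs))

    def test_linearity(self, store, rng):
        obs = rng.normal(size=32)
        assert np.allclose(mfec_project(store, 2 * obs), 2 * mfec_project(store, obs))

    def test_distance_distortion_moderate(self, store, rng):
        """Median pairwise distance ratio after projection stays in a loose
        band around 1 (Gaussian projections roughly preserve distances)."""
        pairs = rng.normal(size=(100, 2, 32))
        ratios = [np.linalg.norm(mfec_project(store, a) - mfec_project(store, b))
                  / np.linalg.norm(a - b) for a, b in pairs]
        assert 0.4 < np.median(ratios) < 1.6


class TestEpisodeUpdate:
    def test_novel_pair_inserted(self, store):
        key = np.ones(8)
        mfec_episode_update(store, [(key, 1, 2.0)], gamma=0.9)
        assert mfec_q_estimate(store, key, 1) == 2.0

    def test_lower_return_keeps_best(self, store):
        key = np.ones(8)
        mfec_episode_update(store, [(key, 0, 5.0)], gamma=0.9)
        mfec_episode_update(store, [(key, 0, 1.0)], gamma=0.9)
        assert mfec_q_estimate(store, key, 0) == 5.0

    def test_discounted_returns_backward(self, store):
        keys = [np.full(8, float(i)) for i in range(3)]
        episode = [(keys[0], 0, 0.0), (keys[1], 0, 0.0), (keys[2], 0, 1.0)]
        mfec_episode_update(store, episode, gamma=0.5)
        assert mfec_q_estimate(store, keys[0], 0) == 0.25
        assert mfec_q_estimate(store, keys[1], 0) == 0.5
        assert mfec_q_estimate(store, keys[2], 0) == 1.0

    def test_values_never_decrease_over_random_episodes(self, store, rng):
        """Monotonicity across 100 random episodes with colliding keys."""
        key_pool = [np.full(8, float(i)) for i in range(10)]
        snapshots = {}
        for _ in range(100):
            episode = [(key_pool[rng.integers(10)], int(rng.integers(3)),
                        float(rng.normal())) for _ in range(rng.integers(1, 8))]
            mfec_episode_update(store, episode, gamma=0.9)
            for a, s in enumerate(store.stores):
                for token, i in s.exact.items():
                    prev = snapshots.get((a, token), -np.inf)
                    assert s.values[i] >= prev - 1e-12
                    snapshots[(a, token)] = s.values[i]


class TestNearestNeighbors:
    def test_exact_hit_returns_stored_value(self, store, rng):
        key = rng.normal(size=8)
        mfec_episode_update(store, [(key, 2, 3.5)], gamma=0.9)
        assert mfec_q_estimate(store, key, 2) == 3.5

    def test_small_store_means_over_all(self, store):
        for v, k in [(1.0, np.zeros(8)), (3.0, np.ones(8))]:
            mfec_episode_update(store, [(k, 0, v)], gamma=0.9)
        assert mfec_q_estimate(store, np.full(8, 9.0), 0) == 2.0

    def test_kdtree_equals_brute_force(self, rng):
        """Neighbor sets from the (lazily rebuilt) KD-tree match a brute-force
        scan for 500 random query keys."""
        cfg = MFECConfig(key_dim=6, k=4)
        store = EpisodicStore(obs_dim=6, n_actions=1, config=cfg)
        s = store.stores[0]
        # interleave inserts and queries so the pending tail is exercised
        all_keys = rng.normal(size=(300, 6))
        values = rng.normal(size=300)
        for i, (k, v) in enumerate(zip(all_keys, values)):
            s.insert_or_max(k, float(v))
            if i > 10 and i % 3 == 0:
                q = rng.normal(size=6)
                got = mfec_q_estimate(store, q, 0)
                d = np.linalg.norm(all_keys[: i + 1] - q, axis=1)
                brute = values[: i + 1][np.argsort(d)[:4]].mean()
                assert np.isclose(got, brute)
        for _ in range(500 - 96):
            q = rng.normal(size=6)
            d = np.linalg.norm(all_keys - q, axis=1)
            brute = values[np.argsort(d)[:4]].mean()
            assert np.isclose(mfec_q_estimate(store, q, 0), brute)


def test_one_shot_learning_on_corridor(rng):
    """After one rewarded episode on a deterministic corridor, greedily
    replaying the stored values reproduces the observed return exactly."""
    gamma = 0.9
    obs = np.eye(5)
    store = EpisodicStore(obs_dim=5, n_actions=4,
                          config=MFECConfig(key_dim=4, k=1, gamma=gamma))
    keys = [mfec_project(store, obs[s]) for s in range(5)]
    RIGHT = 3
    episode = [(keys[s], RIGHT, 1.0 if s == 3 else 0.0) for s in range(4)]
    observed_return = gamma**3 * 1.0  # reward discounted back to the start
    mfec_episode_update(store, episode, gamma)
    # greedy replay from the start: at each state pick the best stored action
    state, replay_return, discount = 0, 0.0, 1.0
    for _ in range(4):
        values = [mfec_q_estimate(store, keys[state], a) for a in range(4)]
        action = int(np.argmax(values))
        assert action == RIGHT
        reward = 1.0 if state == 3 else 0.0
        replay_return += discount * reward
        discount *= gamma
        state += 1
    assert replay_return == observed_return
    assert mfec_q_estimate(store, keys[0], RIGHT) == observed_return
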