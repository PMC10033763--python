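"""Model-free episodic control (MFEC).

MFEC learns in one shot: at the end of each episode the discounted return
``R_t`` of every visited (state, action) pair is computed backward, and the
episodic store keeps the best return encountered so far per pair.  Novel
high-dimensional observations are first projected to a low-dimensional key by
a fixed Gaussian random projection; value estimates for unseen keys are the
mean over the k nearest stored keys (Euclidean distance), indexed with a
KD-tree for efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KDTree

from ..simulation import Experience
from .policy import AgentConfig, select_action


@dataclass
class MFECConfig:
    """MFEC hyperparameters: key dimension d, neighbor count k, discount, exploration."""

    key_dim: int = 64
    k: int = 5
    gamma: float = 0.99
    epsilon: float = 0.1
    warmup_trials: int = 0  # trials with epsilon = 1 before the fixed schedule
    projection_seed: int = 12345


class _ActionStore:
    """Growing (key, Q_EC) array for one action with an exact-match index.

    The KD-tree over stored keys is rebuilt lazily once pending insertions
    exceed 10% of the indexed size; queries merge tree hits with a linear scan
    over the pending tail, so k-NN answers always equal a brute-force scan.
    """

    def __init__(self):
        self.keys: list[np.ndarray] = []
        self.values: list[float] = []
        self.exact: dict[bytes, int] = {}
        self._tree: KDTree | None = None
        self._indexed = 0

    def __len__(self) -> int:
        return len(self.keys)

    def insert_or_max(self, key: np.ndarray, value: float) -> None:
        token = key.tobytes()
        if token in self.exact:
            i = self.exact[token]
            self.values[i] = max(self.values[i], value)
        else:
            self.exact[token] = len(self.keys)
            self.keys.append(key)
            self.values.append(value)

    def lookup_exact(self, key: np.ndarray) -> float | None:
        i = self.exact.get(key.tobytes())
        return None if i is None else self.values[i]

    def _maybe_rebuild(self) -> None:
        pending = len(self.keys) - self._indexed
        if self._tree is None or pending > max(1, 0.1 * self._indexed):
            self._tree = KDTree(np.asarray(self.keys))
            self._indexed = len(self.keys)

    def knn_mean(self, key: np.ndarray, k: int) -> float:
        """Mean stored value over the k nearest keys (all entries if fewer)."""
        n = len(self.keys)
        if n <= k:
            return float(np.mean(self.values))
        self._maybe_rebuild()
        kk = min(k, self._indexed)
        dist, idx = self._tree.query(key[None], k=kk)
        candidates = list(zip(dist[0], idx[0]))
        for j in range(self._indexed, n):  # pending tail not yet in the tree
            candidates.append((float(np.linalg.norm(self.keys[j] - key)), j))
        candidates.sort(key=lambda t: t[0])
        chosen = [self.values[j] for _, j in candidates[:k]]
        return float(np.mean(chosen))


class EpisodicStore:
    """Per-action episodic value stores behind one fixed random projection."""

    def __init__(self, obs_dim: int, n_actions: int, config: MFECConfig | None = None):
        self.config = config or MFECConfig()
        c = self.config
        rng = np.random.default_rng(c.projection_seed)
        #: fixed Gaussian projection (key_dim x obs_dim), entries ~ N(0, 1/key_dim)
        self.projection = rng.normal(0.0, 1.0 / np.sqrt(c.key_dim), (c.key_dim, obs_dim))
        self.stores = [_ActionStore() for _ in range(n_actions)]

    @property
    def n_actions(self) -> int:
        return len(self.stores)

    def size(self) -> int:
        return sum(len(s) for s in self.stores)


def mfec_project(store: EpisodicStore, obs: np.ndarray) -> np.ndarray:
    """Project an observation to its low-dimensional key."""
    return store.projection @ np.ravel(np.asarray(obs, dtype=float))


def mfec_q_estimate(store: EpisodicStore, key: np.ndarray, action: int) -> float:
    """Episodic value of (key, action): exact hit, else k-NN mean (0 if empty)."""
    s = store.stores[action]
    if len(s) == 0:
        return 0.0
    exact = s.lookup_exact(key)
    if exact is not None:
        return exact
    return s.knn_mean(key, store.config.k)


def mfec_episode_update(
    store: EpisodicStore, episode: list[tuple[np.ndarray, int, float]], gamma: float
) -> EpisodicStore:
    """One-shot update from a finished episode of (key, action, reward) steps.

    Discounted returns ``R_t = sum_{k>=t} gamma^(k-t) r_k`` are computed
    backward; each (key, action) pair is inserted if novel, otherwise its
    stored value is raised to ``max(existing, R_t)`` — stored values never
    decrease.
    """
    G = 0.0
    for key, action, reward in reversed(episode):
        G = reward + gamma * G
        store.stores[action].insert_or_max(np.asarray(key), float(G))
    return store


class MFECAgent:
    """Episodic-control agent over vector observations."""

    def __init__(self, obs_dim: int, n_actions: int, config: MFECConfig | None = None):
        self.config = config or MFECConfig()
        self.store = EpisodicStore(obs_dim, n_actions, self.config)
        self._episode: list[tuple[np.ndarray, int, float]] = []
        self._trial = 0
        self._policy_cfg = AgentConfig(gamma=self.config.gamma,
                                       epsilon=self.config.epsilon)

    def begin_trial(self) -> None:
        self._episode = []

    def act(self, obs, rng: np.random.Generator) -> int:
        key = mfec_project(self.store, obs)
        values = [mfec_q_estimate(self.store, key, a)
                  for a in range(self.store.n_actions)]
        eps = 1.0 if self._trial < self.config.warmup_trials else self.config.epsilon
        cfg = AgentConfig(gamma=self.config.gamma, epsilon=eps)
        return select_action(np.asarray(values), cfg, None, rng)

    def observe(self, exp: Experience, rng: np.random.Generator) -> None:
        key = mfec_project(self.store, exp.state)
        self._episode.append((key, exp.action, exp.reward))

    def end_trial(self, rng: np.random.Generator) -> None:
        mfec_episode_update(self.store, self._episode, self.config.gamma)
        self._trial += 1
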