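"""Backend-agnostic Q-network contract and the bundled NumPy MLP backend.

Deep agents talk to their function approximator only through the small
behavioral contract below (predict / fit / clone / activations), so any
network library can be slotted in by implementing it.  The bundled backend is
a fully connected multi-layer perceptron with rectifier hidden units trained
by Adam on a mean-squared-error loss, which is sufficient for the small
networks used in trial-based behavioral simulations.
"""

from __future__ import annotations

import numpy as np


class QNetwork:
    """Behavioral contract for Q-function approximators.

    predict(X) -> (n, n_actions) value matrix; fit(X, Y[, sample_weight]) does
    one training step toward the target matrix and returns the loss;
    copy_weights_from(other) syncs parameters (target networks); activations(X)
    returns the per-layer activation tensors for unit-level monitoring.
    """

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def fit(self, X: np.ndarray, Y: np.ndarray, sample_weight=None) -> float:
        raise NotImplementedError

    def clone(self) -> "QNetwork":
        raise NotImplementedError

    def copy_weights_from(self, other: "QNetwork") -> None:
        raise NotImplementedError

    def activations(self, X: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError


class MLPQNetwork(QNetwork):
    """Fully connected ReLU network trained with Adam on squared error.

    Weights use He-normal initialization from a seeded generator, so two
    networks built with the same seed are bit-identical.
    """

    def __init__(
        self,
        input_dim: int,
        n_actions: int,
        hidden: tuple[int, ...] = (64, 64),
        lr: float = 1e-3,
        seed: int = 0,
    ):
        self.input_dim = input_dim
        self.n_actions = n_actions
        self.hidden = tuple(hidden)
        self.lr = lr
        self.seed = seed
        rng = np.random.default_rng(seed)
        sizes = (input_dim, *hidden, n_actions)
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._adam_t = 0
        self._m = [np.zeros_like(w) for w in self.W + self.b]
        self._v = [np.zeros_like(w) for w in self.W + self.b]

    # -- forward ----------------------------------------------------------
    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [np.atleast_2d(np.asarray(X, dtype=float))]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = acts[-1] @ W + b
            acts.append(np.maximum(z, 0.0) if i < len(self.W) - 1 else z)
        return acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)[-1]

    def activations(self, X: np.ndarray) -> list[np.ndarray]:
        """Per-layer activations (hidden layers post-ReLU, then linear output)."""
        return self._forward(X)[1:]

    # -- training ---------------------------------------------------------
    def fit(self, X: np.ndarray, Y: np.ndarray, sample_weight=None) -> float:
        """One Adam step minimizing (weighted) mean squared error; returns the loss."""
        acts = self._forward(X)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        n = len(Y)
        err = acts[-1] - Y
        if sample_weight is not None:
            wts = np.asarray(sample_weight, dtype=float)[:, None]
            loss = float(np.mean(wts * err**2))
            delta = 2.0 * wts * err / (n * self.n_actions)
        else:
            loss = float(np.mean(err**2))
            delta = 2.0 * err / (n * self.n_actions)
        grads_W, grads_b = [], []
        for i in range(len(self.W) - 1, -1, -1):
            grads_W.append(acts[i].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        self._adam_step(grads_W[::-1] + grads_b[::-1])
        return loss

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        params = self.W + self.b
        for i, (p, g) in enumerate(zip(params, grads)):
            self._m[i] = beta1 * self._m[i] + (1 - beta1) * g
            self._v[i] = beta2 * self._v[i] + (1 - beta2) * g**2
            m_hat = self._m[i] / (1 - beta1**self._adam_t)
            v_hat = self._v[i] / (1 - beta2**self._adam_t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + eps)

    # -- cloning ----------------------------------------------------------
    def clone(self) -> "MLPQNetwork":
        other = MLPQNetwork(self.input_dim, self.n_actions, self.hidden, self.lr, self.seed)
        other.copy_weights_from(self)
        return other

    def copy_weights_from(self, other: "MLPQNetwork") -> None:
        self.W = [w.copy() for w in other.W]
        self.b = [b.copy() for b in other.b]
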