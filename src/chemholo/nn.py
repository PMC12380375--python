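"""Minimal dense feed-forward regression network in numpy.

Architecture used throughout the inverse-Mie experiments: a flattened real
input vector, one or more tanh hidden layers, a linear output layer.  Weights
are initialised from the Glorot normal distribution, zero mean and standard
deviation ``sigma = sqrt(2 / (N_in + N_out))`` computed from the actual
fan-in/fan-out of each layer; biases start at zero.  Training minimises the
mean-squared error with the Adam optimiser on shuffled mini-batches.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

__all__ = ["TrainConfig", "DenseNetwork", "glorot_sigma"]


def glorot_sigma(n_in: int, n_out: int) -> float:
    """Glorot-normal standard deviation sqrt(2 / (N_in + N_out))."""
    return float(np.sqrt(2.0 / (n_in + n_out)))


@dataclass
class TrainConfig:
    """Training protocol for the inverse-Mie networks.

    Defaults follow the reference protocol: 400 epochs, batch 200, a 1/10
    test split with 1/5 of the remaining training data held out for
    validation, Adam at 1e-3.
    """

    epochs: int = 400
    batch_size: int = 200
    test_fraction: float = 0.1
    validation_fraction: float = 0.2
    learning_rate: float = 1e-3
    seed: int = 0
    hidden: Sequence[int] = (5,)

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch size must be positive")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test fraction must be in (0, 1)")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation fraction must be in (0, 1)")


# architecture presets: the 5-hidden-unit shallow net and a deeper variant
PRESETS = {"shallow": (5,), "deep": (64, 64, 64)}


class DenseNetwork:
    """Tanh-hidden, linear-output dense network trained with Adam on MSE."""

    def __init__(self, layer_sizes: Sequence[int], seed: int = 0):
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.layer_sizes = list(int(s) for s in layer_sizes)
        rng = np.random.default_rng(seed)
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []
        for n_in, n_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            sigma = glorot_sigma(n_in, n_out)
            self.weights.append(rng.normal(0.0, sigma, (n_in, n_out)))
            self.biases.append(np.zeros(n_out))
        self._adam_state = None
        self.history: dict = {"loss": [], "val_loss": []}

    # -- forward / backward --------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        a = np.asarray(x, dtype=float)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ w + b
            if i != last:
                a = np.tanh(a)
        return a

    def _forward_cache(self, x):
        acts = [x]
        last = len(self.weights) - 1
        a = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            a = z if i == last else np.tanh(z)
            acts.append(a)
        return acts

    def _gradients(self, x, y):
        acts = self._forward_cache(x)
        n = x.shape[0]
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.weights)
        # dL/dout for MSE (mean over samples and outputs)
        delta = 2.0 * (acts[-1] - y) / (n * y.shape[1])
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (1.0 - acts[i] ** 2)
        return grads_w, grads_b

    def _adam_step(self, grads_w, grads_b, lr, t, beta1=0.9, beta2=0.999,
                   eps=1e-8):
        if self._adam_state is None:
            self._adam_state = {
                "mw": [np.zeros_like(w) for w in self.weights],
                "vw": [np.zeros_like(w) for w in self.weights],
                "mb": [np.zeros_like(b) for b in self.biases],
                "vb": [np.zeros_like(b) for b in self.biases],
            }
        st = self._adam_state
        for i in range(len(self.weights)):
            for key, grad, param in (("w", grads_w[i], self.weights[i]),
                                     ("b", grads_b[i], self.biases[i])):
                m = st["m" + key][i] = beta1 * st["m" + key][i] + (1 - beta1) * grad
                v = st["v" + key][i] = beta2 * st["v" + key][i] + (1 - beta2) * grad**2
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training ------------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray,
            x_val: Optional[np.ndarray] = None,
            y_val: Optional[np.ndarray] = None,
            epochs: int = 400, batch_size: int = 200,
            learning_rate: float = 1e-3, seed: int = 0) -> "DenseNetwork":
        """Mini-batch Adam on MSE; raises on divergence (NaN loss)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        rng = np.random.default_rng(seed)
        n = x.shape[0]
        t = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                gw, gb = self._gradients(x[idx], y[idx])
                t += 1
                self._adam_step(gw, gb, learning_rate, t)
            loss = float(np.mean((self.predict(x) - y) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (NaN/inf loss) at epoch {epoch}, "
                    f"seed {seed}")
            self.history["loss"].append(loss)
            if x_val is not None:
                self.history["val_loss"].append(
                    float(np.mean((self.predict(x_val) - y_val) ** 2)))
        return self

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict:
        out = {"layer_sizes": np.asarray(self.layer_sizes)}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_state_dict(cls, state: dict) -> "DenseNetwork":
        sizes = [int(s) for s in np.asarray(state["layer_sizes"])]
        net = cls(sizes, seed=0)
        for i in range(len(net.weights)):
            net.weights[i] = np.asarray(state[f"w{i}"], float)
            net.biases[i] = np.asarray(state[f"b{i}"], float)
        return net
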