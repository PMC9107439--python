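"""A small numpy convolutional network for K x 1 RGB strips.

Architecture: rescale 1/255 -> conv with a 1 x 3 sliding window along
the band axis (valid padding, ReLU) -> flatten -> dense ReLU layer ->
single sigmoid output.  Trained with Adam on binary cross-entropy.
The network is tiny (a few hundred parameters), so plain numpy training
is fast and exactly reproducible from the seed.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class TinyCnn:
    def __init__(
        self,
        n_bands: int,
        n_channels: int = 3,
        n_filters: int = 8,
        dense_units: int = 4,
        window: int = 3,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> None:
        if n_bands < window:
            raise ValueError(f"need at least {window} bands for a {window}-wide window")
        self.n_bands = n_bands
        self.window = window
        rng = np.random.default_rng(seed)
        L = n_bands - window + 1
        flat = L * n_filters

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, shape)

        self.params: Dict[str, np.ndarray] = {
            "Wc": glorot((window, n_channels, n_filters), window * n_channels, n_filters),
            "bc": np.zeros(n_filters),
            "W1": glorot((flat, dense_units), flat, dense_units),
            "b1": np.zeros(dense_units),
            "W2": glorot((dense_units, 1), dense_units, 1),
            "b2": np.zeros(1),
        }
        self.lr = learning_rate
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def _forward(self, X: np.ndarray):
        x = np.asarray(X, dtype=float) / 255.0
        Xw = sliding_window_view(x, self.window, axis=1)  # (n, L, C, w)
        z1 = np.einsum("nlcw,wcf->nlf", Xw, self.params["Wc"]) + self.params["bc"]
        a1 = np.maximum(z1, 0.0)
        flat = a1.reshape(a1.shape[0], -1)
        z2 = flat @ self.params["W1"] + self.params["b1"]
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ self.params["W2"] + self.params["b2"]
        p = 1.0 / (1.0 + np.exp(-z3[:, 0]))
        return p, (Xw, z1, a1, flat, z2, a2)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)[0]

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(self.predict_proba(X), 1e-12, 1 - 1e-12)
        y = np.asarray(y, dtype=float)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def gradients(self, X: np.ndarray, y: np.ndarray) -> Dict[str, np.ndarray]:
        y = np.asarray(y, dtype=float)
        p, (Xw, z1, a1, flat, z2, a2) = self._forward(X)
        n = len(y)
        dz3 = ((p - y) / n)[:, None]
        g = {
            "W2": a2.T @ dz3,
            "b2": dz3.sum(axis=0),
        }
        da2 = dz3 @ self.params["W2"].T
        dz2 = da2 * (z2 > 0)
        g["W1"] = flat.T @ dz2
        g["b1"] = dz2.sum(axis=0)
        dflat = dz2 @ self.params["W1"].T
        dz1 = dflat.reshape(a1.shape) * (z1 > 0)
        g["Wc"] = np.einsum("nlcw,nlf->wcf", Xw, dz1)
        g["bc"] = dz1.sum(axis=(0, 1))
        return g

    def _adam_step(self, grads: Dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-7) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk**2
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 100,
        batch_size: int = 8,
        seed: int = 0,
    ) -> "TinyCnn":
        rng = np.random.default_rng(seed)
        n = len(y)
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                self._adam_step(self.gradients(X[idx], y[idx]))
        return self
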