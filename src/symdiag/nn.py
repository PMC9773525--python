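"""Minimal feed-forward value network: one rectified hidden layer, plain SGD.

Deliberately small — Q-value regression over a few hundred features does not
need more, and keeping the forward/backward pass in plain numpy makes target
synchronization and determinism trivial.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP"]


class MLP:
    """y = W2 @ relu(W1 @ x + b1) + b2, trained with masked squared TD error."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        # He initialization for the rectified layer, small output weights
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0.0, np.sqrt(1.0 / n_hidden), size=(n_hidden, n_out))
        self.b2 = np.zeros(n_out)

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        h = np.maximum(X @ self.W1 + self.b1, 0.0)
        return h @ self.W2 + self.b2

    def sgd_q_step(
        self, X: np.ndarray, actions: np.ndarray, targets: np.ndarray, lr: float
    ) -> float:
        """One gradient-descent step on mean (Q(s, a) - target)^2; returns pre-update loss."""
        X = np.atleast_2d(X)
        B = X.shape[0]
        pre = X @ self.W1 + self.b1
        h = np.maximum(pre, 0.0)
        out = h @ self.W2 + self.b2
        q = out[np.arange(B), actions]
        err = q - targets
        loss = float(np.mean(err ** 2))

        d_out = np.zeros_like(out)
        d_out[np.arange(B), actions] = 2.0 * err / B
        dW2 = h.T @ d_out
        db2 = d_out.sum(axis=0)
        d_h = d_out @ self.W2.T
        d_pre = d_h * (pre > 0.0)
        dW1 = X.T @ d_pre
        db1 = d_pre.sum(axis=0)

        self.W1 -= lr * dW1
        self.b1 -= lr * db1
        self.W2 -= lr * dW2
        self.b2 -= lr * db2
        return loss

    def get_params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1.copy(), "b1": self.b1.copy(),
                "W2": self.W2.copy(), "b2": self.b2.copy()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.W1 = params["W1"].copy()
        self.b1 = params["b1"].copy()
        self.W2 = params["W2"].copy()
        self.b2 = params["b2"].copy()

    def clone(self) -> "MLP":
        twin = MLP.__new__(MLP)
        twin.n_in, twin.n_hidden, twin.n_out = self.n_in, self.n_hidden, self.n_out
        twin.set_params(self.get_params())
        return twin
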