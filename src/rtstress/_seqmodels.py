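"""Compact numpy sequence models for multi-label prediction.

The prediction stage compares tabular learners against sequence
learners that read the case's feature vector as an ordered univariate
sequence.  To keep the package dependency-light these are implemented
directly in numpy with manual backpropagation and full-batch Adam:

* :class:`RecurrentNet` — an Elman-style tanh recurrent network whose
  final hidden state feeds seven independent logistic outputs.
* :class:`AttentionNet` — a single-head scaled dot-product
  self-attention encoder over learned position + value embeddings,
  mean-pooled into seven logistic outputs.

Both are deliberately small (default 16 hidden units): the datasets
here are a few hundred cases of length <= 10.  Gradients are verified
against numerical differentiation in the test-suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RecurrentNet", "AttentionNet"]

_EPS = 1e-8


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))


def _bce(logits: np.ndarray, y: np.ndarray) -> float:
    p = _sigmoid(logits)
    return float(-np.mean(y * np.log(p + _EPS) + (1 - y) * np.log(1 - p + _EPS)))


class _AdamState:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = 0.9, 0.999
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + _EPS)


class RecurrentNet:
    """Elman recurrent network: h_t = tanh(w x_t + W h_{t-1} + b)."""

    def __init__(
        self,
        n_outputs: int = 7,
        hidden: int = 16,
        epochs: int = 300,
        lr: float = 0.02,
        seed: int = 0,
    ):
        self.n_outputs = n_outputs
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self.params: dict[str, np.ndarray] | None = None

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        H, O = self.hidden, self.n_outputs
        s = 1.0 / np.sqrt(H)
        return {
            "wx": rng.normal(0, s, H),
            "Wh": rng.normal(0, s, (H, H)),
            "b": np.zeros(H),
            "Wo": rng.normal(0, s, (H, O)),
            "bo": np.zeros(O),
        }

    def _forward(self, X: np.ndarray, params: dict) -> tuple[np.ndarray, list]:
        n, T = X.shape
        H = self.hidden
        hs = [np.zeros((n, H))]
        for t in range(T):
            a = (
                X[:, t:t + 1] * params["wx"][None, :]
                + hs[-1] @ params["Wh"]
                + params["b"]
            )
            hs.append(np.tanh(a))
        logits = hs[-1] @ params["Wo"] + params["bo"]
        return logits, hs

    def loss_and_grads(
        self, X: np.ndarray, Y: np.ndarray, params: dict
    ) -> tuple[float, dict]:
        n, T = X.shape
        logits, hs = self._forward(X, params)
        loss = _bce(logits, Y)
        dlogits = (_sigmoid(logits) - Y) / (n * self.n_outputs)
        g = {k: np.zeros_like(v) for k, v in params.items()}
        g["Wo"] = hs[-1].T @ dlogits
        g["bo"] = dlogits.sum(0)
        dh = dlogits @ params["Wo"].T
        for t in range(T - 1, -1, -1):
            da = dh * (1.0 - hs[t + 1] ** 2)
            g["wx"] += (da * X[:, t:t + 1]).sum(0)
            g["Wh"] += hs[t].T @ da
            g["b"] += da.sum(0)
            dh = da @ params["Wh"].T
        return loss, g

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RecurrentNet":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        rng = np.random.default_rng(self.seed)
        params = self._init_params(rng)
        adam = _AdamState(params, self.lr)
        for _ in range(self.epochs):
            _, grads = self.loss_and_grads(X, Y, params)
            adam.step(params, grads)
        self.params = params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        logits, _ = self._forward(np.asarray(X, dtype=float), self.params)
        return _sigmoid(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


class AttentionNet:
    """Single-head self-attention encoder with mean pooling."""

    def __init__(
        self,
        n_outputs: int = 7,
        dim: int = 8,
        epochs: int = 300,
        lr: float = 0.02,
        seed: int = 0,
    ):
        self.n_outputs = n_outputs
        self.dim = dim
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self.params: dict[str, np.ndarray] | None = None
        self._T: int | None = None

    def _init_params(self, rng: np.random.Generator, T: int) -> dict:
        D, O = self.dim, self.n_outputs
        s = 1.0 / np.sqrt(D)
        return {
            "v": rng.normal(0, s, D),       # value embedding of the scalar
            "P": rng.normal(0, s, (T, D)),  # learned position embeddings
            "Wq": rng.normal(0, s, (D, D)),
            "Wk": rng.normal(0, s, (D, D)),
            "Wv": rng.normal(0, s, (D, D)),
            "Wo": rng.normal(0, s, (D, O)),
            "bo": np.zeros(O),
        }

    def _forward(self, X: np.ndarray, params: dict):
        n, T = X.shape
        D = self.dim
        E = X[:, :, None] * params["v"][None, None, :] + params["P"][None, :, :]
        Q = E @ params["Wq"]
        K = E @ params["Wk"]
        V = E @ params["Wv"]
        S = Q @ K.transpose(0, 2, 1) / np.sqrt(D)
        S = S - S.max(axis=-1, keepdims=True)
        expS = np.exp(S)
        A = expS / expS.sum(axis=-1, keepdims=True)
        Z = A @ V
        pooled = Z.mean(axis=1)
        logits = pooled @ params["Wo"] + params["bo"]
        return logits, (E, Q, K, V, A, Z, pooled)

    def loss_and_grads(self, X, Y, params) -> tuple[float, dict]:
        n, T = X.shape
        D = self.dim
        logits, (E, Q, K, V, A, Z, pooled) = self._forward(X, params)
        loss = _bce(logits, Y)
        dlogits = (_sigmoid(logits) - Y) / (n * self.n_outputs)
        g = {k: np.zeros_like(v) for k, v in params.items()}
        g["Wo"] = pooled.T @ dlogits
        g["bo"] = dlogits.sum(0)
        dpooled = dlogits @ params["Wo"].T          # (n, D)
        dZ = np.repeat(dpooled[:, None, :] / T, T, axis=1)
        dA = dZ @ V.transpose(0, 2, 1)              # (n, T, T)
        dV = A.transpose(0, 2, 1) @ dZ              # (n, T, D)
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = dS @ K / np.sqrt(D)
        dK = dS.transpose(0, 2, 1) @ Q / np.sqrt(D)
        g["Wq"] = np.einsum("ntd,nte->de", E, dQ)
        g["Wk"] = np.einsum("ntd,nte->de", E, dK)
        g["Wv"] = np.einsum("ntd,nte->de", E, dV)
        dE = (
            dQ @ params["Wq"].T
            + dK @ params["Wk"].T
            + dV @ params["Wv"].T
        )
        g["v"] = np.einsum("nt,ntd->d", X, dE)
        g["P"] = dE.sum(axis=0)
        return loss, g

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "AttentionNet":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self._T = X.shape[1]
        rng = np.random.default_rng(self.seed)
        params = self._init_params(rng, self._T)
        adam = _AdamState(params, self.lr)
        for _ in range(self.epochs):
            _, grads = self.loss_and_grads(X, Y, params)
            adam.step(params, grads)
        self.params = params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._T:
            raise ValueError("sequence length differs from training")
        logits, _ = self._forward(X, self.params)
        return _sigmoid(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)
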