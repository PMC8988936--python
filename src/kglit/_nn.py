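"""Minimal feed-forward networks trained with RMSprop.

Two architectures used by the pair classifiers: a single-hidden-layer MLP
(hidden width = 2x input, ReLU hidden, sigmoid output, binary cross-entropy)
and a Siamese network with one shared dense tower per entity vector, an
absolute-difference merge and a sigmoid head.
"""

from __future__ import annotations

import numpy as np


class _RMSprop:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, c in zip(self.params, grads, self.cache):
            c *= self.rho
            c += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


class MLPBinaryClassifier:
    """input -> dense(2*input, ReLU) -> dense(1, sigmoid), cross-entropy loss."""

    def __init__(self, epochs: int = 100, batch_size: int = 128, lr: float = 1e-3, seed: int = 0):
        self.epochs, self.batch_size, self.lr, self.seed = epochs, batch_size, lr, seed
        self.hidden_width: int | None = None
        self.loss_trace: list[float] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPBinaryClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        rng = np.random.Generator(np.random.PCG64(self.seed))
        n, d = X.shape
        h = 2 * d
        self.hidden_width = h
        self.W1 = rng.normal(0, np.sqrt(2.0 / d), size=(d, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0, np.sqrt(1.0 / h), size=(h, 1))
        self.b2 = np.zeros(1)
        opt = _RMSprop([self.W1, self.b1, self.W2, self.b2], lr=self.lr)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                z1 = xb @ self.W1 + self.b1
                a1 = np.maximum(z1, 0.0)
                p = _sigmoid(a1 @ self.W2 + self.b2).ravel()
                losses.append(_bce(p, yb))
                delta = ((p - yb) / len(idx))[:, None]
                gW2 = a1.T @ delta
                gb2 = delta.sum(axis=0)
                d1 = (delta @ self.W2.T) * (z1 > 0)
                gW1 = xb.T @ d1
                gb1 = d1.sum(axis=0)
                opt.step([gW1, gb1, gW2, gb2])
            self.loss_trace.append(float(np.mean(losses)))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        a1 = np.maximum(np.asarray(X, dtype=np.float64) @ self.W1 + self.b1, 0.0)
        return _sigmoid(a1 @ self.W2 + self.b2).ravel()


class SiameseBinaryClassifier:
    """Twin weight-shared encoders with |h1 - h2| merge and sigmoid head.

    The input feature vector is split in half: first block the drug, second
    block the candidate entity.  Each half passes through the same dense+ReLU
    tower, and the absolute difference of the two encodings feeds a logistic
    output — a distance-flavoured head trained with cross-entropy.
    """

    def __init__(self, epochs: int = 100, batch_size: int = 128, lr: float = 1e-3, seed: int = 0):
        self.epochs, self.batch_size, self.lr, self.seed = epochs, batch_size, lr, seed
        self.loss_trace: list[float] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SiameseBinaryClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n, d2 = X.shape
        if d2 % 2:
            raise ValueError("siamese input must split into two equal entity blocks")
        d = d2 // 2
        rng = np.random.Generator(np.random.PCG64(self.seed))
        self.W = rng.normal(0, np.sqrt(2.0 / d), size=(d, d))
        self.b = np.zeros(d)
        self.w_out = rng.normal(0, np.sqrt(1.0 / d), size=(d, 1))
        self.b_out = np.zeros(1)
        opt = _RMSprop([self.W, self.b, self.w_out, self.b_out], lr=self.lr)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xa, xb_, yb = X[idx, :d], X[idx, d:], y[idx]
                za, zb = xa @ self.W + self.b, xb_ @ self.W + self.b
                ha, hb = np.maximum(za, 0.0), np.maximum(zb, 0.0)
                m = np.abs(ha - hb)
                p = _sigmoid(m @ self.w_out + self.b_out).ravel()
                losses.append(_bce(p, yb))
                delta = ((p - yb) / len(idx))[:, None]
                g_wout = m.T @ delta
                g_bout = delta.sum(axis=0)
                dm = delta @ self.w_out.T
                sign = np.sign(ha - hb)
                da = dm * sign * (za > 0)
                db = -dm * sign * (zb > 0)
                gW = xa.T @ da + xb_.T @ db
                gb = da.sum(axis=0) + db.sum(axis=0)
                opt.step([gW, gb, g_wout, g_bout])
            self.loss_trace.append(float(np.mean(losses)))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        d = X.shape[1] // 2
        ha = np.maximum(X[:, :d] @ self.W + self.b, 0.0)
        hb = np.maximum(X[:, d:] @ self.W + self.b, 0.0)
        return _sigmoid(np.abs(ha - hb) @ self.w_out + self.b_out).ravel()
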