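"""Minimal dense/convolutional/recurrent regressors in NumPy.

Four tiny architectures back the nonlinear learners: a single-hidden-layer
perceptron (ReLU or Morlet-wavelet activation), a one-block 1-d CNN
(conv -> activation -> max/avg pool -> linear head), a vanilla RNN and an
LSTM, each with a single linear output unit.  All are trained by Adam on
mean-squared error with analytic gradients, full determinism from a seed,
and float64 throughout.  Sizes here are a handful of dozens of weights,
so plain NumPy is both adequate and exactly auditable — the trainable
parameter counts are closed-form and checked against the architecture
tables the package documents.

Inputs are expected pre-scaled (the public layer handles min-max scaling);
rows of X are lag vectors ordered most-recent-first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "relu",
    "relu_grad",
    "morlet",
    "morlet_grad",
    "AdamState",
    "MLPNet",
    "CNNNet",
    "RNNNet",
    "LSTMNet",
    "TrainingDivergence",
]


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


def relu(y):
    """Rectified linear unit max(0, y)."""
    return np.maximum(0.0, y)


def relu_grad(y):
    return (y > 0.0).astype(float)


def morlet(y):
    """Morlet wavelet exp(-y^2) * cos(5y) — the wavelon activation."""
    y = np.asarray(y, dtype=float)
    out = np.exp(-(y**2)) * np.cos(5.0 * y)
    return out if out.ndim else float(out)


def morlet_grad(y):
    y = np.asarray(y, dtype=float)
    return np.exp(-(y**2)) * (-2.0 * y * np.cos(5.0 * y) - 5.0 * np.sin(5.0 * y))


def _tanh_grad_from_out(t):
    return 1.0 - t**2


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class AdamState:
    """Adam moment buffers over a flat parameter vector."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def like(cls, theta: np.ndarray) -> "AdamState":
        return cls(m=np.zeros_like(theta), v=np.zeros_like(theta))

    def step(self, theta, grad, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        self.m = beta1 * self.m + (1 - beta1) * grad
        self.v = beta2 * self.v + (1 - beta2) * grad**2
        mhat = self.m / (1 - beta1**self.t)
        vhat = self.v / (1 - beta2**self.t)
        return theta - lr * mhat / (np.sqrt(vhat) + eps)


class _BaseNet:
    """Shared training loop: seeded init, Adam, minibatch MSE."""

    def __init__(self) -> None:
        self.loss_history: list[float] = []

    # subclasses: n_params, _init(rng), _get/_set flat theta,
    # _forward(X) -> yhat, _backward(X, err) -> grad (flat)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 300,
        batch_size: int = 1,
        lr: float = 0.01,
        seed: int = 0,
        patience: Optional[int] = None,
    ) -> "_BaseNet":
        rng = np.random.default_rng(seed)
        self._init(rng)
        theta = self._get_theta()
        adam = AdamState.like(theta)
        n = X.shape[0]
        batch_size = min(batch_size, n)
        best_loss, best_theta, stall = np.inf, theta.copy(), 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                yhat = self._forward(X[idx])
                err = yhat - y[idx]
                grad = self._backward(X[idx], err / idx.size)
                theta = adam.step(self._get_theta(), grad, lr)
                self._set_theta(theta)
            epoch_loss = float(np.mean((self._forward(X) - y) ** 2))
            if not math.isfinite(epoch_loss):
                raise TrainingDivergence(epoch)
            self.loss_history.append(epoch_loss)
            if epoch_loss < best_loss - 1e-12:
                best_loss, best_theta, stall = epoch_loss, theta.copy(), 0
            else:
                stall += 1
                if patience is not None and stall >= patience:
                    break
        self._set_theta(best_theta)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)


class MLPNet(_BaseNet):
    """One hidden layer of q units, activation ReLU or Morlet, linear output.

    Trainable parameters: q*(p+1) + (q+1).  With the Morlet activation the
    hidden units are wavelons Psi(w.x + b): the bias plays the translation
    and the dilation is absorbed into the input weights, so the counting
    is identical to the ReLU perceptron.
    """

    def __init__(self, p: int, q: int, activation: str = "relu"):
        super().__init__()
        if activation not in {"relu", "morlet"}:
            raise ValueError("activation must be 'relu' or 'morlet'")
        self.p, self.q, self.activation = p, q, activation
        self._act: Callable = relu if activation == "relu" else morlet
        self._act_grad: Callable = relu_grad if activation == "relu" else morlet_grad

    @property
    def n_params(self) -> int:
        return self.q * (self.p + 1) + (self.q + 1)

    def _init(self, rng) -> None:
        s1 = 1.0 / math.sqrt(self.p)
        self.W1 = rng.uniform(-s1, s1, size=(self.q, self.p))
        self.b1 = rng.uniform(-s1, s1, size=self.q)
        s2 = 1.0 / math.sqrt(self.q)
        self.w2 = rng.uniform(-s2, s2, size=self.q)
        self.b2 = 0.0

    def _get_theta(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.w2, [self.b2]])

    def _set_theta(self, th: np.ndarray) -> None:
        k = self.q * self.p
        self.W1 = th[:k].reshape(self.q, self.p)
        self.b1 = th[k : k + self.q]
        self.w2 = th[k + self.q : k + 2 * self.q]
        self.b2 = float(th[-1])

    def _forward(self, X):
        self._z = X @ self.W1.T + self.b1
        self._h = self._act(self._z)
        return self._h @ self.w2 + self.b2

    def _backward(self, X, err):
        d_w2 = err @ self._h
        d_b2 = float(err.sum())
        dh = np.outer(err, self.w2) * self._act_grad(self._z)
        d_W1 = dh.T @ X
        d_b1 = dh.sum(axis=0)
        return np.concatenate([d_W1.ravel(), d_b1, d_w2, [d_b2]])


class CNNNet(_BaseNet):
    """1-d conv (f filters, kernel k) -> activation -> pool (size s) -> head.

    The p lags form a length-p single-channel sequence; pooling is
    non-overlapping with stride s (max by default, mean optionally) and
    truncates the remainder.  Trainable parameters:
    f*(k+1) + f*floor((p-k+1)/s) + 1.
    """

    def __init__(
        self,
        p: int,
        filters: int,
        kernel_size: int,
        pool_size: int,
        activation: str = "relu",
        pooling: str = "max",
    ):
        super().__init__()
        if p - kernel_size + 1 < 1:
            raise ValueError("kernel larger than the input window")
        if (p - kernel_size + 1) // pool_size < 1:
            raise ValueError("pool size larger than the convolution output")
        if activation not in {"relu", "tanh"}:
            raise ValueError("activation must be 'relu' or 'tanh'")
        if pooling not in {"max", "avg"}:
            raise ValueError("pooling must be 'max' or 'avg'")
        self.p, self.f, self.k, self.s = p, filters, kernel_size, pool_size
        self.activation, self.pooling = activation, pooling
        self.L = p - kernel_size + 1
        self.M = self.L // pool_size

    @property
    def n_params(self) -> int:
        return self.f * (self.k + 1) + self.f * self.M + 1

    def _init(self, rng) -> None:
        s1 = 1.0 / math.sqrt(self.k)
        self.K = rng.uniform(-s1, s1, size=(self.f, self.k))
        self.bK = rng.uniform(-s1, s1, size=self.f)
        s2 = 1.0 / math.sqrt(max(self.f * self.M, 1))
        self.w = rng.uniform(-s2, s2, size=self.f * self.M)
        self.b = 0.0

    def _get_theta(self):
        return np.concatenate([self.K.ravel(), self.bK, self.w, [self.b]])

    def _set_theta(self, th):
        k = self.f * self.k
        self.K = th[:k].reshape(self.f, self.k)
        self.bK = th[k : k + self.f]
        self.w = th[k + self.f : k + self.f + self.f * self.M]
        self.b = float(th[-1])

    def _windows(self, X):
        # (n, L, k) sliding windows of each input row
        return np.lib.stride_tricks.sliding_window_view(X, self.k, axis=1)

    def _forward(self, X):
        Xw = self._windows(X)  # (n, L, k)
        self._z = np.einsum("nlk,fk->nfl", Xw, self.K) + self.bK[None, :, None]
        if self.activation == "relu":
            self._a = relu(self._z)
        else:
            self._a = np.tanh(self._z)
        trimmed = self._a[:, :, : self.M * self.s].reshape(X.shape[0], self.f, self.M, self.s)
        if self.pooling == "max":
            self._argmax = trimmed.argmax(axis=3)
            pooled = trimmed.max(axis=3)
        else:
            pooled = trimmed.mean(axis=3)
        self._pooled = pooled.reshape(X.shape[0], self.f * self.M)
        return self._pooled @ self.w + self.b

    def _backward(self, X, err):
        n = X.shape[0]
        d_w = err @ self._pooled
        d_b = float(err.sum())
        d_pool = np.outer(err, self.w).reshape(n, self.f, self.M)
        d_a = np.zeros_like(self._a)
        if self.pooling == "max":
            ni, fi, mi = np.meshgrid(
                np.arange(n), np.arange(self.f), np.arange(self.M), indexing="ij"
            )
            pos = mi * self.s + self._argmax
            d_a[ni, fi, pos] = d_pool
        else:
            for j in range(self.s):
                d_a[:, :, : self.M * self.s][:, :, j :: self.s][:, :, : self.M] += (
                    d_pool / self.s
                )
        if self.activation == "relu":
            d_z = d_a * relu_grad(self._z)
        else:
            d_z = d_a * _tanh_grad_from_out(self._a)
        Xw = self._windows(X)
        d_K = np.einsum("nfl,nlk->fk", d_z, Xw)
        d_bK = d_z.sum(axis=(0, 2))
        return np.concatenate([d_K.ravel(), d_bK, d_w, [d_b]])


class RNNNet(_BaseNet):
    """Vanilla tanh RNN over the p lags as a length-p sequence of 1 feature.

    h_t = tanh(U h_{t-1} + W s_t + b), output = v . h_p + c.
    Trainable parameters: n^2 + 3n + 1, independent of p.
    """

    def __init__(self, p: int, n_hidden: int):
        super().__init__()
        self.p, self.nh = p, n_hidden

    @property
    def n_params(self) -> int:
        n = self.nh
        return n * n + 3 * n + 1

    def _init(self, rng) -> None:
        n = self.nh
        s = 1.0 / math.sqrt(n)
        self.U = rng.uniform(-s, s, size=(n, n))
        self.W = rng.uniform(-1.0, 1.0, size=n)
        self.b = np.zeros(n)
        self.v = rng.uniform(-s, s, size=n)
        self.c = 0.0

    def _get_theta(self):
        return np.concatenate([self.U.ravel(), self.W, self.b, self.v, [self.c]])

    def _set_theta(self, th):
        n = self.nh
        self.U = th[: n * n].reshape(n, n)
        self.W = th[n * n : n * n + n]
        self.b = th[n * n + n : n * n + 2 * n]
        self.v = th[n * n + 2 * n : n * n + 3 * n]
        self.c = float(th[-1])

    def _sequence(self, X):
        # feed lags chronologically: rows are most-recent-first, so reverse
        return X[:, ::-1]

    def _forward(self, X):
        S = self._sequence(X)
        nb = X.shape[0]
        self._hs = np.zeros((self.p + 1, nb, self.nh))
        for t in range(self.p):
            pre = self._hs[t] @ self.U.T + np.outer(S[:, t], self.W) + self.b
            self._hs[t + 1] = np.tanh(pre)
        return self._hs[-1] @ self.v + self.c

    def _backward(self, X, err):
        S = self._sequence(X)
        d_U = np.zeros_like(self.U)
        d_W = np.zeros_like(self.W)
        d_b = np.zeros_like(self.b)
        d_v = err @ self._hs[-1]
        d_c = float(err.sum())
        dh = np.outer(err, self.v)
        for t in range(self.p - 1, -1, -1):
            dpre = dh * _tanh_grad_from_out(self._hs[t + 1])
            d_U += dpre.T @ self._hs[t]
            d_W += dpre.T @ S[:, t]
            d_b += dpre.sum(axis=0)
            dh = dpre @ self.U
        return np.concatenate([d_U.ravel(), d_W, d_b, d_v, [d_c]])


class LSTMNet(_BaseNet):
    """Single-layer LSTM over the p lags as a length-p sequence of 1 feature.

    Gates (sigmoid forget/input/output, tanh candidate) act on the
    concatenation [h_{t-1}, y_t]; the head is linear on h_p.  Trainable
    parameters: 4*(n*(n+1) + n) + (n + 1).
    """

    def __init__(self, p: int, n_hidden: int):
        super().__init__()
        self.p, self.nh = p, n_hidden

    @property
    def n_params(self) -> int:
        n = self.nh
        return 4 * (n * (n + 1) + n) + (n + 1)

    def _init(self, rng) -> None:
        n = self.nh
        s = 1.0 / math.sqrt(n + 1)
        self.Wf = rng.uniform(-s, s, size=(n, n + 1))
        self.Wi = rng.uniform(-s, s, size=(n, n + 1))
        self.Wc = rng.uniform(-s, s, size=(n, n + 1))
        self.Wo = rng.uniform(-s, s, size=(n, n + 1))
        self.bf = np.ones(n)  # standard forget-gate bias init
        self.bi = np.zeros(n)
        self.bc = np.zeros(n)
        self.bo = np.zeros(n)
        self.v = rng.uniform(-s, s, size=n)
        self.c = 0.0

    def _get_theta(self):
        return np.concatenate(
            [
                self.Wf.ravel(), self.Wi.ravel(), self.Wc.ravel(), self.Wo.ravel(),
                self.bf, self.bi, self.bc, self.bo, self.v, [self.c],
            ]
        )

    def _set_theta(self, th):
        n = self.nh
        sz = n * (n + 1)
        self.Wf = th[0 * sz : 1 * sz].reshape(n, n + 1)
        self.Wi = th[1 * sz : 2 * sz].reshape(n, n + 1)
        self.Wc = th[2 * sz : 3 * sz].reshape(n, n + 1)
        self.Wo = th[3 * sz : 4 * sz].reshape(n, n + 1)
        off = 4 * sz
        self.bf = th[off : off + n]
        self.bi = th[off + n : off + 2 * n]
        self.bc = th[off + 2 * n : off + 3 * n]
        self.bo = th[off + 3 * n : off + 4 * n]
        self.v = th[off + 4 * n : off + 5 * n]
        self.c = float(th[-1])

    def _forward(self, X):
        S = X[:, ::-1]  # chronological order
        nb = X.shape[0]
        n, p = self.nh, self.p
        self._cache = []
        h = np.zeros((nb, n))
        cst = np.zeros((nb, n))
        for t in range(p):
            z = np.concatenate([h, S[:, t : t + 1]], axis=1)  # [h_{t-1}, y_t]
            f = _sigmoid(z @ self.Wf.T + self.bf)
            i = _sigmoid(z @ self.Wi.T + self.bi)
            g = np.tanh(z @ self.Wc.T + self.bc)
            o = _sigmoid(z @ self.Wo.T + self.bo)
            c_new = f * cst + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((z, f, i, g, o, cst, c_new, tc))
            h, cst = h_new, c_new
        self._h_last = h
        return h @ self.v + self.c

    def _backward(self, X, err):
        n = self.nh
        d = {k: np.zeros_like(getattr(self, k)) for k in
             ("Wf", "Wi", "Wc", "Wo", "bf", "bi", "bc", "bo")}
        d_v = err @ self._h_last
        d_c = float(err.sum())
        dh = np.outer(err, self.v)
        dc = np.zeros_like(dh)
        for t in range(self.p - 1, -1, -1):
            z, f, i, g, o, c_prev, c_new, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dzf = df * f * (1 - f)
            dzi = di * i * (1 - i)
            dzg = dg * (1 - g**2)
            dzo = do * o * (1 - o)
            d["Wf"] += dzf.T @ z
            d["Wi"] += dzi.T @ z
            d["Wc"] += dzg.T @ z
            d["Wo"] += dzo.T @ z
            d["bf"] += dzf.sum(axis=0)
            d["bi"] += dzi.sum(axis=0)
            d["bc"] += dzg.sum(axis=0)
            d["bo"] += dzo.sum(axis=0)
            dz = dzf @ self.Wf + dzi @ self.Wi + dzg @ self.Wc + dzo @ self.Wo
            dh = dz[:, :n]
            dc = dc * f
        return np.concatenate(
            [
                d["Wf"].ravel(), d["Wi"].ravel(), d["Wc"].ravel(), d["Wo"].ravel(),
                d["bf"], d["bi"], d["bc"], d["bo"], d_v, [d_c],
            ]
        )
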