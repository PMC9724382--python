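"""A compact 1-D convolutional regression network, implemented in numpy.

Architecture (stand-in for the Siamese-style epigenetics arm, without a
sequence arm): two 1-D convolutions over the 13 base-pair-resolved
score channels x 23 positions (13 -> 32 -> 64, kernel 3, same padding),
each followed by batch normalization and ReLU; global average pooling;
concatenation with the per-site scalar features; two dense layers
(-> 64 -> 1).  Trained with Adam on mean squared error, optional early
stopping on a validation carve-out.  Forward and backward passes are
hand-written numpy; the network is intentionally small enough to train
on one CPU in seconds to minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d:
    """Same-padding 1-D convolution via im2col."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3):
        self.k = k
        self.W = _he_init(rng, (c_out, c_in * k), c_in * k)
        self.b = np.zeros(c_out)
        self.params = [("W", self.W), ("b", self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # (n, c, L, k) -> (n, L, c*k)
        return cols.transpose(0, 2, 1, 3).reshape(n, L, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.W.T + self.b  # (n, L, c_out)
        return out.transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c_out, L = grad.shape
        g = grad.transpose(0, 2, 1)  # (n, L, c_out)
        self.dW = np.einsum("nlo,nlc->oc", g, self._cols) / n
        self.db = g.sum(axis=(0, 1)) / n
        dcols = g @ self.W  # (n, L, c_in*k)
        c_in = self._x_shape[1]
        p = self.k // 2
        dxp = np.zeros((n, c_in, L + 2 * p))
        dc = dcols.reshape(n, L, c_in, self.k)
        for j in range(self.k):
            dxp[:, :, j : j + L] += dc[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p : p + L]

    def grads(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class BatchNorm1d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # x: (n, c, L)
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, L = grad.shape
        m = n * L
        self.dgamma = (grad * self._xhat).sum(axis=(0, 2)) / n
        self.dbeta = grad.sum(axis=(0, 2)) / n
        gxhat = grad * self.gamma[None, :, None]
        sum_g = gxhat.sum(axis=(0, 2), keepdims=True)
        sum_gx = (gxhat * self._xhat).sum(axis=(0, 2), keepdims=True)
        dx = (gxhat - sum_g / m - self._xhat * sum_gx / m) / self._std[None, :, None]
        return dx

    def grads(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class Dense:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = _he_init(rng, (d_in, d_out), d_in)
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        self.dW = self._x.T @ grad / n
        self.db = grad.sum(axis=0) / n
        return grad @ self.W.T

    def grads(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, param, grad in layer.grads():
                key = (li, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(param)
                    self.v[key] = np.zeros_like(param)
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * grad
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * grad**2
                mhat = self.m[key] / (1 - self.b1**self.t)
                vhat = self.v[key] / (1 - self.b2**self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class CnnHyperparams:
    lr: float = 0.001
    batchnorm_momentum: float = 0.1
    epochs: int = 70
    batch_size: int = 35_000
    minibatch: int = 256
    early_stopping: bool = True
    patience: int = 5
    val_fraction: float = 0.1


class ConvRegressor:
    """13-channel x 23-position convolutional regressor with scalar inputs."""

    def __init__(self, n_channels: int, length: int, n_scalars: int,
                 hp: CnnHyperparams, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hp = hp
        self.n_channels, self.length, self.n_scalars = n_channels, length, n_scalars
        self.conv1 = Conv1d(rng, n_channels, 32)
        self.bn1 = BatchNorm1d(32, momentum=hp.batchnorm_momentum)
        self.conv2 = Conv1d(rng, 32, 64)
        self.bn2 = BatchNorm1d(64, momentum=hp.batchnorm_momentum)
        self.fc1 = Dense(rng, 64 + n_scalars, 64)
        self.fc2 = Dense(rng, 64, 1)
        self._layers = [self.conv1, self.bn1, self.conv2, self.bn2, self.fc1, self.fc2]
        self._rng = rng

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        bp = X[:, : self.n_channels * self.length].reshape(
            -1, self.n_channels, self.length
        )
        sc = X[:, self.n_channels * self.length :]
        return bp, sc

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        bp, sc = self._split(X)
        h = self.conv1.forward(bp)
        h = self.bn1.forward(h, training)
        self._m1 = h > 0
        h = h * self._m1
        h = self.conv2.forward(h)
        h = self.bn2.forward(h, training)
        self._m2 = h > 0
        h = h * self._m2
        self._pool_in_L = h.shape[2]
        g = h.mean(axis=2)  # global average pool -> (n, 64)
        z = np.concatenate([g, sc], axis=1)
        h2 = self.fc1.forward(z)
        self._m3 = h2 > 0
        h2 = h2 * self._m3
        return self.fc2.forward(h2)[:, 0]

    def _backward(self, grad_out: np.ndarray) -> None:
        g = self.fc2.backward(grad_out[:, None])
        g = g * self._m3
        g = self.fc1.backward(g)
        g_pool, _g_sc = g[:, :64], g[:, 64:]
        gh = np.repeat(g_pool[:, :, None], self._pool_in_L, axis=2) / self._pool_in_L
        gh = gh * self._m2
        gh = self.bn2.backward(gh)
        gh = self.conv2.backward(gh)
        gh = gh * self._m1
        gh = self.bn1.backward(gh)
        self.conv1.backward(gh)

    def fit(self, batches, X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None, verbose: bool = False) -> list[float]:
        """Train on an iterable of (X, y) epoch batches; returns val losses."""
        opt = Adam(self._layers, lr=self.hp.lr)
        best_loss, best_state, patience_left = np.inf, None, self.hp.patience
        history: list[float] = []
        for epoch, (Xb, yb) in enumerate(batches):
            order = self._rng.permutation(len(Xb))
            for lo in range(0, len(Xb), self.hp.minibatch):
                idx = order[lo : lo + self.hp.minibatch]
                if idx.size < 2:
                    continue
                pred = self.forward(Xb[idx], training=True)
                grad = 2.0 * (pred - yb[idx])
                self._backward(grad)
                opt.step()
            if X_val is not None and len(X_val):
                val_pred = self.forward(X_val, training=False)
                val_loss = float(np.mean((val_pred - y_val) ** 2))
                history.append(val_loss)
                if self.hp.early_stopping:
                    if val_loss < best_loss - 1e-6:
                        best_loss = val_loss
                        best_state = self.get_state()
                        patience_left = self.hp.patience
                    else:
                        patience_left -= 1
                        if patience_left <= 0:
                            break
        if best_state is not None:
            self.set_state(best_state)
        return history

    def predict(self, X: np.ndarray, chunk: int = 8192) -> np.ndarray:
        out = np.empty(len(X))
        for lo in range(0, len(X), chunk):
            out[lo : lo + chunk] = self.forward(X[lo : lo + chunk], training=False)
        return out

    # -- state (save/load) ----------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, la in enumerate(self._layers):
            if isinstance(la, Conv1d) or isinstance(la, Dense):
                state[f"{i}.W"] = la.W.copy()
                state[f"{i}.b"] = la.b.copy()
            elif isinstance(la, BatchNorm1d):
                state[f"{i}.gamma"] = la.gamma.copy()
                state[f"{i}.beta"] = la.beta.copy()
                state[f"{i}.rmean"] = la.running_mean.copy()
                state[f"{i}.rvar"] = la.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, la in enumerate(self._layers):
            if isinstance(la, (Conv1d, Dense)):
                la.W[...] = state[f"{i}.W"]
                la.b[...] = state[f"{i}.b"]
            elif isinstance(la, BatchNorm1d):
                la.gamma[...] = state[f"{i}.gamma"]
                la.beta[...] = state[f"{i}.beta"]
                la.running_mean[...] = state[f"{i}.rmean"]
                la.running_var[...] = state[f"{i}.rvar"]
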