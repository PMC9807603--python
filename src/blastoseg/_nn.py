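"""Compact NumPy neural-network backend.

Implements exactly the two architectures the segmentation pipeline needs — a
fully connected softmax classifier and a small convolutional encoder–decoder —
together with Adam / RMSprop optimisers and Keras-style callbacks
(early stopping and learning-rate reduction on a validation-loss plateau).
Everything is deterministic under a seed: weight initialisation, the
train/validation split and per-epoch shuffling all derive from one
``numpy.random.Generator``.

The backend is intentionally minimal: NHWC tensors, 3x3 'same' convolutions,
2x2 max-pooling and nearest-neighbour up-sampling, float32 throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Sigmoid",
    "Conv2D",
    "MaxPool2",
    "Upsample2",
    "Adam",
    "RMSprop",
    "Sequential",
    "make_mlp",
    "make_encoder_decoder",
]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base class; stateless layers keep empty parameter lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialisation (ReLU hidden units)
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class Sigmoid(Layer):
    def forward(self, x):
        out = np.clip(x, -60.0, 60.0)    # avoid float32 exp overflow
        np.negative(out, out=out)
        np.exp(out, out=out)
        out += 1.0
        np.reciprocal(out, out=out)
        self._out = out
        return out

    def backward(self, g):
        return g * self._out * (1.0 - self._out)


class Conv2D(Layer):
    """3x3 (by default) 'same' convolution on NHWC tensors, zero padding.

    Implemented as a sum of nine shifted matrix products, which keeps memory
    flat and routes all heavy lifting through BLAS.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, ksize: int = 3):
        fan_in = ksize * ksize * c_in
        self.ksize = ksize
        self.W = (rng.standard_normal((ksize, ksize, c_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        k, p = self.ksize, self.ksize // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        self._shape = x.shape
        out = np.empty((n, h, w, self.W.shape[-1]), dtype=np.float32)
        out[...] = self.b
        for i in range(k):
            for j in range(k):
                out += xp[:, i:i + h, j:j + w, :] @ self.W[i, j]
        return out

    def backward(self, g):
        k = self.ksize
        n, h, w, _ = self._shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        gf = g.reshape(-1, g.shape[-1])
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + h, j:j + w, :].reshape(-1, xp.shape[-1])
                self.dW[i, j] = patch.T @ gf
                dxp[:, i:i + h, j:j + w, :] += g @ self.W[i, j].T
        self.db[...] = gf.sum(axis=0)
        p = k // 2
        return dxp[:, p:p + h, p:p + w, :]


class MaxPool2(Layer):
    def forward(self, x):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        gb = np.broadcast_to(g[:, :, None, :, None, :], self._mask.shape)
        return np.where(self._mask, gb, 0.0).reshape(n, h, w, c)


class Upsample2(Layer):
    """Nearest-neighbour 2x up-sampling."""

    def forward(self, x):
        self._shape = x.shape
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, g):
        n, h, w, c = self._shape
        return g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# optimisers
# ---------------------------------------------------------------------------

class Optimizer:
    lr: float

    def attach(self, params: Sequence[np.ndarray]) -> None:  # pragma: no cover
        raise NotImplementedError

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        raise NotImplementedError  # pragma: no cover


class Adam(Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def attach(self, params):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps

    def attach(self, params):
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        for p, g, v in zip(params, grads, self.v):
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=-1, keepdims=True)
    return z


class Sequential:
    """A feed-forward stack with a fused loss.

    ``loss='softmax_cce'`` expects the final layer to emit logits (softmax is
    applied inside the loss and in :meth:`predict`); ``loss='mse'`` compares
    the final layer's output directly with the target tensor.
    """

    def __init__(self, layers: Iterable[Layer], loss: str, optimizer: Optimizer):
        if loss not in ("softmax_cce", "mse"):
            raise ValueError(f"unknown loss {loss!r}")
        self.layers = list(layers)
        self.loss = loss
        self.optimizer = optimizer
        self._params = [p for layer in self.layers for p in layer.params()]
        self._grads = [g for layer in self.layers for g in layer.grads()]
        optimizer.attach(self._params)

    # -- inference ----------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        outs = []
        for start in range(0, len(x), batch_size):
            out = self.forward(np.asarray(x[start:start + batch_size], dtype=np.float32))
            if self.loss == "softmax_cce":
                out = _softmax(out)
            outs.append(out)
        return np.concatenate(outs, axis=0)

    # -- training -----------------------------------------------------------

    def _loss_and_grad(self, out: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        if self.loss == "softmax_cce":
            p = _softmax(out.copy())
            eps = 1e-12
            loss = float(-np.mean(np.sum(y * np.log(p + eps), axis=-1)))
            grad = (p - y) / out.shape[0]
        else:
            diff = out - y
            loss = float(np.mean(diff * diff))
            grad = 2.0 * diff / diff.size
        return loss, grad.astype(np.float32)

    def evaluate(self, x: np.ndarray, y: np.ndarray, batch_size: int = 4096) -> float:
        total, count = 0.0, 0
        for start in range(0, len(x), batch_size):
            xb = np.asarray(x[start:start + batch_size], dtype=np.float32)
            yb = np.asarray(y[start:start + batch_size], dtype=np.float32)
            loss, _ = self._loss_and_grad(self.forward(xb), yb)
            total += loss * len(xb)
            count += len(xb)
        return total / max(count, 1)

    def fit(self, x: np.ndarray, y: np.ndarray, *, epochs: int, batch_size: int,
            validation_split: float = 0.1, seed: int = 0,
            early_stopping_patience: int | None = None,
            early_stopping_min_delta: float = 0.0,
            reduce_lr_factor: float | None = None,
            reduce_lr_patience: int = 10,
            verbose: bool = False) -> dict[str, list[float]]:
        rng = np.random.default_rng(seed)
        n = len(x)
        perm = rng.permutation(n)
        n_val = int(round(validation_split * n)) if validation_split > 0 else 0
        n_val = min(n_val, n - 1)
        train_idx, val_idx = perm[:n - n_val], perm[n - n_val:]
        xv, yv = x[val_idx], y[val_idx]

        history: dict[str, list[float]] = {"loss": [], "val_loss": [], "lr": []}
        best_val = np.inf
        best_weights: list[np.ndarray] | None = None
        es_wait = 0
        lr_wait = 0

        for epoch in range(epochs):
            order = rng.permutation(len(train_idx))
            epoch_loss, seen = 0.0, 0
            for start in range(0, len(order), batch_size):
                idx = train_idx[order[start:start + batch_size]]
                xb = np.asarray(x[idx], dtype=np.float32)
                yb = np.asarray(y[idx], dtype=np.float32)
                loss, grad = self._loss_and_grad(self.forward(xb), yb)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                self.optimizer.step(self._params, self._grads)
                epoch_loss += loss * len(xb)
                seen += len(xb)
            train_loss = epoch_loss / max(seen, 1)
            val_loss = self.evaluate(xv, yv) if n_val else train_loss
            history["loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            history["lr"].append(self.optimizer.lr)
            if verbose:  # pragma: no cover - cosmetic
                print(f"epoch {epoch + 1:3d}  loss {train_loss:.5f}  val {val_loss:.5f}")

            improved = val_loss < best_val - early_stopping_min_delta
            if improved:
                best_val = val_loss
                best_weights = [p.copy() for p in self._params]
                es_wait = 0
                lr_wait = 0
            else:
                es_wait += 1
                lr_wait += 1
                if reduce_lr_factor is not None and lr_wait >= reduce_lr_patience:
                    self.optimizer.lr *= reduce_lr_factor
                    lr_wait = 0
                if early_stopping_patience is not None and es_wait >= early_stopping_patience:
                    break

        if best_weights is not None:
            for p, w in zip(self._params, best_weights):
                p[...] = w
        return history

    # -- (de)serialisation ---------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        if len(weights) != len(self._params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self._params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = np.asarray(w, dtype=p.dtype)


# ---------------------------------------------------------------------------
# architecture builders
# ---------------------------------------------------------------------------

def make_mlp(n_in: int, n_classes: int, *, hidden_layers: int = 3, units: int = 400,
             lr: float = 1e-3, seed: int = 0) -> Sequential:
    """Fully connected softmax classifier (Adam, categorical cross-entropy)."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    width = n_in
    for _ in range(hidden_layers):
        layers += [Dense(width, units, rng), ReLU()]
        width = units
    layers.append(Dense(width, n_classes, rng))
    return Sequential(layers, loss="softmax_cce", optimizer=Adam(lr=lr))


def make_encoder_decoder(c_in: int = 5, c_out: int = 5,
                         widths: tuple[int, int, int] = (16, 32, 64), *,
                         lr: float = 1e-3, seed: int = 0) -> Sequential:
    """Encoder–decoder: 3 conv + 3 max-pool encoding, 4 conv + 3 up-sampling
    decoding, sigmoid output, MSE loss, RMSprop optimiser."""
    rng = np.random.default_rng(seed)
    w1, w2, w3 = widths
    layers: list[Layer] = [
        Conv2D(c_in, w1, rng), ReLU(), MaxPool2(),
        Conv2D(w1, w2, rng), ReLU(), MaxPool2(),
        Conv2D(w2, w3, rng), ReLU(), MaxPool2(),
        Conv2D(w3, w3, rng), ReLU(), Upsample2(),
        Conv2D(w3, w2, rng), ReLU(), Upsample2(),
        Conv2D(w2, w1, rng), ReLU(), Upsample2(),
        Conv2D(w1, c_out, rng), Sigmoid(),
    ]
    return Sequential(layers, loss="mse", optimizer=RMSprop(lr=lr))
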