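"""Minimal seeded NumPy neural-network stack.

Implements exactly the layers the spectral classifier needs — 1D valid
convolution, ReLU, inverted dropout, max-pooling, dense layers, a fused
softmax/cross-entropy head — plus Adam and a reduce-on-plateau learning
rate scheduler. Everything is float32 and driven by an explicit
``numpy.random.Generator``, so training is reproducible bit-for-bit on
one machine.

Gradients propagate all the way to the input, which the interpretability
layer uses for input-gradient saliency.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "ReLU", "LeakyReLU", "Dropout", "ReLUDropout",
           "MaxPool1D", "Flatten", "Dense", "Network", "Adam",
           "ReduceLROnPlateau", "softmax", "softmax_cross_entropy"]

F32 = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits.

    ``weights`` are optional per-class weights (e.g. inverse frequency).
    """
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    w = np.ones(n) if weights is None else weights[labels]
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    loss = float(-(w * logp).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad.astype(logits.dtype)


class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid 1D convolution, single input channel -> ``filters`` channels.

    Input (B, L) -> output (B, L - kernel + 1, filters).
    """

    def __init__(self, filters: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1):
        if stride != 1:
            raise NotImplementedError("stride 1 only")
        self.kernel = kernel
        scale = np.sqrt(2.0 / kernel)
        self.W = (rng.standard_normal((filters, kernel)) * scale).astype(F32)
        self.b = np.zeros(filters, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        xw = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        self._xw = xw  # (B, Lo, k), view
        return np.tensordot(xw, self.W, axes=([2], [1])) + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # dout: (B, Lo, F)
        self.grads[0][...] = np.tensordot(dout, self._xw,
                                          axes=([0, 1], [0, 1]))
        self.grads[1][...] = dout.sum(axis=(0, 1))
        B, L = self._x.shape
        Lo = dout.shape[1]
        dx = np.zeros((B, L), dtype=dout.dtype)
        for k in range(self.kernel):
            dx[:, k:k + Lo] += dout @ self.W[:, k]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class LeakyReLU(Layer):
    """max(x, alpha*x); the leak lets a fully-off layer recover, which a
    hard ReLU after a wide dense layer cannot."""

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, x * x.dtype.type(self.alpha))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout,
                        dout * dout.dtype.type(self.alpha))


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = F32(1.0 - self.rate)
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep)
        mask = mask.astype(F32)
        mask /= keep
        self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class ReLUDropout(Layer):
    """Fused ReLU + inverted dropout: one mask, one multiply per pass."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train and self.rate > 0:
            keep = 1.0 - self.rate
            mask = self.rng.random(x.shape, dtype=np.float32) < F32(keep)
            mask &= x > 0
            fmask = mask.astype(F32)
            fmask *= F32(1.0 / keep)
        else:
            fmask = (x > 0).astype(F32)
        self._mask = fmask
        return x * fmask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Pool size 2, stride 2 along axis 1; trailing odd element dropped."""

    def __init__(self, size: int = 2, stride: int = 2):
        if size != 2 or stride != 2:
            raise NotImplementedError("pool size/stride 2 only")

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L = x.shape[0], x.shape[1]
        self._L = L
        Lp = L // 2
        xr = x[:, :2 * Lp].reshape(B, Lp, 2, -1)
        a = xr[:, :, 0]
        b = xr[:, :, 1]
        self._left = a >= b  # ties go left, matching argmax
        return np.where(self._left, a, b)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, Lp, Fc = dout.shape
        dxr = np.zeros((B, Lp, 2, Fc), dtype=dout.dtype)
        np.copyto(dxr[:, :, 0], dout, where=self._left)
        np.subtract(dout, dxr[:, :, 0], out=dxr[:, :, 1])
        dx = np.zeros((B, self._L, Fc), dtype=dout.dtype)
        dx[:, :2 * Lp] = dxr.reshape(B, 2 * Lp, Fc)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Network:
    """A plain layer sequence ending in logits (softmax applied outside)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate; returns the gradient w.r.t. the network input."""
        d = dlogits
        for l in reversed(self.layers):
            d = l.backward(d)
        return d

    def predict_proba(self, x: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size], train=False)))
        return np.vstack(out) if out else np.empty((0, 0))

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(argmax logit)/d(input) per spectrum (evaluation mode)."""
        logits = self.forward(x, train=False)
        onehot = np.zeros_like(logits)
        onehot[np.arange(x.shape[0]), logits.argmax(axis=1)] = 1.0
        return self.backward(onehot.astype(F32))


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = F32(self.beta1), F32(self.beta2)
        # fold bias correction into the step size (standard reformulation)
        lr_t = F32(self.lr * np.sqrt(1 - self.beta2 ** self.t)
                   / (1 - self.beta1 ** self.t))
        one_m_b1, one_m_b2 = F32(1 - self.beta1), F32(1 - self.beta2)
        eps = F32(self.eps)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            np.multiply(m, b1, out=m)
            m += one_m_b1 * g
            np.multiply(v, b2, out=v)
            v += one_m_b2 * g * g
            denom = np.sqrt(v)
            denom += eps
            denom = np.divide(m, denom, out=denom)
            denom *= lr_t
            p -= denom


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer lr when the monitored loss has
    not improved for ``patience`` epochs."""

    def __init__(self, optimizer: Adam, patience: int = 5,
                 factor: float = 0.5, min_delta: float = 1e-4):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0

    def step(self, loss: float) -> None:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.opt.lr *= self.factor
                self.stale = 0
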