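"""Minimal feed-forward neural-network core in numpy.

Implements exactly the pieces the age regressor needs — valid 1-D
convolution, ReLU, flatten, dense, inverted dropout, mean-squared-error
loss and the Adam optimizer — with hand-written backpropagation.  Keeping
the core this small makes every gradient checkable against finite
differences (see the test suite) and keeps training fully deterministic
from a seed, which the cross-validation contract requires.

Shapes follow the (batch, channels, length) convention for convolutional
layers and (batch, features) after flattening.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv1D", "ReLU", "Flatten", "Dense", "Dropout", "Network",
           "Adam", "mse_loss"]


class Layer:
    """Base layer: stateless unless it has weights."""

    #: parameter arrays, updated in place by the optimizer
    params: list
    #: gradient arrays aligned with ``params``
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []
        self.last_output = None

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution with stride 1.

    Weights: (out_channels, in_channels, kernel); He-normal initialized.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, scale, (out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        # x: (N, C_in, L) -> (N, C_out, L - k + 1)
        self._x = x
        windows = sliding_window_view(x, self.kernel, axis=2)
        y = np.einsum("nilk,oik->nol", windows, self.W, optimize=True)
        y += self.b[None, :, None]
        self.last_output = y
        return y

    def backward(self, dout):
        windows = sliding_window_view(self._x, self.kernel, axis=2)
        self.grads[0][...] = np.einsum("nilk,nol->oik", windows, dout,
                                       optimize=True)
        self.grads[1][...] = dout.sum(axis=(0, 2))
        k = self.kernel
        pad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
        dwin = sliding_window_view(pad, k, axis=2)
        # full correlation with the flipped kernel gives dL/dx
        return np.einsum("nolj,oij->nil", dwin, self.W[:, :, ::-1],
                         optimize=True)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        y = x * self._mask
        self.last_output = y
        return y

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        y = x.reshape(x.shape[0], -1)
        self.last_output = y
        return y

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; He-normal initialized weights (in, out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        y = x @ self.W + self.b
        self.last_output = y
        return y

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout: active only in training mode with an rng."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if train and self.rate > 0.0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
            y = x * self._mask
        else:
            self._mask = None
            y = x
        self.last_output = y
        return y

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Network:
    """A plain sequential stack with access to per-layer activations and
    per-layer output gradients (needed for Grad-CAM)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.output_grads: list | None = None

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        """Backpropagate; records the gradient at every layer's output."""
        self.output_grads = [None] * len(self.layers)
        g = dout
        for i in reversed(range(len(self.layers))):
            self.output_grads[i] = g
            g = self.layers[i].backward(g)
        return g

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    pred = pred.reshape(-1)
    target = np.asarray(target, dtype=float).reshape(-1)
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    dpred = (2.0 / len(diff)) * diff
    return loss, dpred.reshape(-1, 1)


class Adam:
    """Adam optimizer over a flat parameter list, updating in place."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
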