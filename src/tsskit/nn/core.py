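"""Minimal feed-forward/recurrent network engine on numpy.

Layers implement ``forward(x, train)`` / ``backward(grad)`` with explicit
parameter and gradient lists; the Adam optimizer updates them in place. The
engine supports exactly what the five TSS architectures need: 1-D valid
convolutions, max pooling, dense layers, inverted dropout, (bi)directional
LSTMs returning their final hidden state, and a sigmoid + binary
cross-entropy head computed stably on logits.

Shapes: sequence inputs are (batch, length, channels); dense inputs are
(batch, features).
"""

from __future__ import annotations

import numpy as np

from ..errors import ContractError


def _glorot(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer, optional ReLU."""

    def __init__(self, n_in: int, n_out: int, rng, activation: str | None = None):
        super().__init__()
        self.W = _glorot(rng, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train: bool):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._z = z
            return relu(z)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Flatten(Layer):
    def forward(self, x, train: bool):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ContractError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Conv1D(Layer):
    """1-D convolution, stride 1, valid padding, optional ReLU.

    Input (N, L, C_in) -> output (N, L - width + 1, filters).
    """

    def __init__(self, n_in: int, filters: int, width: int, rng, activation: str = "relu"):
        super().__init__()
        self.W = _glorot(rng, (width, n_in, filters))
        self.b = np.zeros(filters)
        self.width = width
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train: bool):
        if x.shape[1] < self.width:
            raise ContractError(
                f"input length {x.shape[1]} shorter than convolution width {self.width}"
            )
        self._x = x
        L_out = x.shape[1] - self.width + 1
        z = np.tile(self.b, (x.shape[0], L_out, 1))
        for w in range(self.width):
            z += x[:, w : w + L_out, :] @ self.W[w]
        if self.activation == "relu":
            self._z = z
            return relu(z)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        x = self._x
        L_out = grad.shape[1]
        dx = np.zeros_like(x)
        for w in range(self.width):
            # (w, c_in, f) gradient: sum over batch and output positions
            self.grads[0][w] = np.einsum("nlc,nlf->cf", x[:, w : w + L_out, :], grad)
            dx[:, w : w + L_out, :] += grad @ self.W[w].T
        self.grads[1][...] = grad.sum(axis=(0, 1))
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the sequence axis (stride = size);
    a trailing remainder shorter than the pool is dropped."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x, train: bool):
        n, L, c = x.shape
        L_out = L // self.size
        if L_out == 0:
            raise ContractError(f"input length {L} shorter than pool size {self.size}")
        x_trim = x[:, : L_out * self.size, :].reshape(n, L_out, self.size, c)
        self._argmax = x_trim.argmax(axis=2)
        self._in_shape = x.shape
        return x_trim.max(axis=2)

    def backward(self, grad):
        n, L_out, c = grad.shape
        dx = np.zeros((n, L_out, self.size, c))
        n_idx, l_idx, c_idx = np.meshgrid(
            np.arange(n), np.arange(L_out), np.arange(c), indexing="ij"
        )
        dx[n_idx, l_idx, self._argmax, c_idx] = grad
        full = np.zeros(self._in_shape)
        full[:, : L_out * self.size, :] = dx.reshape(n, L_out * self.size, c)
        return full


class LSTM(Layer):
    """Single-direction LSTM returning the final hidden state (N, units).

    Gate order i, f, g, o in one stacked weight matrix; forget-gate bias
    initialized to 1 (standard remedy against early forgetting).
    """

    def __init__(self, n_in: int, units: int, rng, reverse: bool = False):
        super().__init__()
        self.units = units
        self.reverse = reverse
        self.W = _glorot(rng, (n_in + units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train: bool):
        if self.reverse:
            x = x[:, ::-1, :]
        n, L, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._cache = []
        self._x = x
        for t in range(L):
            z = np.concatenate([x[:, t, :], h], axis=1)
            gates = z @ self.W + self.b
            i = sigmoid(gates[:, :u])
            f = sigmoid(gates[:, u : 2 * u])
            g = np.tanh(gates[:, 2 * u : 3 * u])
            o = sigmoid(gates[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            self._cache.append((z, i, f, g, o, c_prev, tanh_c))
        self._L = L
        return h

    def backward(self, grad_h):
        u = self.units
        n, L = grad_h.shape[0], self._L
        dW = self.grads[0]
        db = self.grads[1]
        dW[...] = 0.0
        db[...] = 0.0
        dh = grad_h
        dc = np.zeros((n, u))
        dx = np.zeros_like(self._x)
        for t in range(L - 1, -1, -1):
            z, i, f, g, o, c_prev, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += z.T @ dgates
            db += dgates.sum(axis=0)
            dz = dgates @ self.W.T
            dx[:, t, :] = dz[:, : dz.shape[1] - u]
            dh = dz[:, dz.shape[1] - u :]
            dc = dc * f
        if self.reverse:
            dx = dx[:, ::-1, :]
        return dx


class Bidirectional(Layer):
    """Concatenates the final states of a forward and a backward LSTM."""

    def __init__(self, n_in: int, units: int, rng):
        super().__init__()
        self.fwd = LSTM(n_in, units, rng)
        self.bwd = LSTM(n_in, units, rng, reverse=True)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x, train: bool):
        return np.concatenate(
            [self.fwd.forward(x, train), self.bwd.forward(x, train)], axis=1
        )

    def backward(self, grad):
        u = self.fwd.units
        return self.fwd.backward(grad[:, :u]) + self.bwd.backward(grad[:, u:])


class Network:
    """An ordered layer stack ending in a single logit unit.

    ``predict_proba`` applies the sigmoid; training couples the sigmoid with
    binary cross-entropy on logits for numerical stability.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward_logits(self, x, train: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out.reshape(-1)

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = grad_logits.reshape(-1, 1)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        if len(x) == 0:
            return np.zeros(0)
        chunks = [
            sigmoid(self.forward_logits(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient d loss / d logits."""
    p = sigmoid(logits)
    # softplus(z) - y z, computed stably
    loss = float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))
    grad = (p - y) / len(y)
    return loss, grad


class Adam:
    """Adam with the standard bias correction (beta1 0.9, beta2 0.999)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
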