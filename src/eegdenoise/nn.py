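"""Minimal numpy neural-network core for the recurrent adversarial pair.

Implements exactly the layers the denoiser needs — LSTM (full-sequence
output), PReLU, LeakyReLU, per-timestep dense with tanh, flatten +
dense with sigmoid — with hand-written reverse-mode gradients and an
Adam optimizer.  Single-threaded numpy keeps training bit-reproducible
for a fixed seed.

Shapes follow the sequence convention (batch, time, features).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "LSTM", "PReLU", "LeakyReLU", "TimeDistributedDense",
           "FlattenDense", "Sequential", "Adam", "mse_loss", "bce_loss",
           "lstm_param_count"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_param_count(input_dim: int, units: int) -> int:
    """Trainable parameters of one LSTM layer: 4 ((D + H) H + H)."""
    return 4 * ((input_dim + units) * units + units)


class Layer:
    """Base class: subclasses fill ``params``/``grads`` with aligned lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class LSTM(Layer):
    """Standard LSTM returning the full hidden-state sequence.

    Gate order along the last weight axis is (i, f, g, o).  Glorot-uniform
    input weights, orthogonal recurrent weights, forget-gate bias 1.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.units = units
        h = units
        lim = np.sqrt(6.0 / (input_dim + 4 * h))
        self.Wx = rng.uniform(-lim, lim, size=(input_dim, 4 * h))
        # Orthogonal init per gate block.
        blocks = []
        for _ in range(4):
            a = rng.standard_normal((h, h))
            q, r = np.linalg.qr(a)
            blocks.append(q * np.sign(np.diag(r)))
        self.Wh = np.concatenate(blocks, axis=1)
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        h = self.units
        H = np.zeros((B, T, h))
        C = np.zeros((B, T, h))
        gates = np.zeros((B, T, 4 * h))
        # Precompute the input projection for all timesteps at once.
        xw = x.reshape(B * T, D) @ self.Wx
        xw = xw.reshape(B, T, 4 * h)
        h_prev = np.zeros((B, h))
        c_prev = np.zeros((B, h))
        for t in range(T):
            z = xw[:, t] + h_prev @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c = f * c_prev + i * g
            ht = o * np.tanh(c)
            gates[:, t, :h] = i
            gates[:, t, h : 2 * h] = f
            gates[:, t, 2 * h : 3 * h] = g
            gates[:, t, 3 * h :] = o
            C[:, t] = c
            H[:, t] = ht
            h_prev, c_prev = ht, c
        self._cache = (x, H, C, gates)
        return H

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, H, C, gates = self._cache
        B, T, D = x.shape
        h = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        WhT = self.Wh.T
        WxT = self.Wx.T
        dz_all = np.zeros((B, T, 4 * h))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :h]
            f = gates[:, t, h : 2 * h]
            g = gates[:, t, 2 * h : 3 * h]
            o = gates[:, t, 3 * h :]
            c = C[:, t]
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, h))
            tanh_c = np.tanh(c)
            dh = dout[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g**2),
                do * o * (1 - o),
            ], axis=1)
            dz_all[:, t] = dz
            h_prev = H[:, t - 1] if t > 0 else np.zeros((B, h))
            dWh += h_prev.T @ dz
            dh_next = dz @ WhT
            dc_next = dc * f
        # Batched input-weight gradient and input gradient.
        dz_flat = dz_all.reshape(B * T, 4 * h)
        dWx += x.reshape(B * T, D).T @ dz_flat
        db += dz_flat.sum(axis=0)
        dx = (dz_flat @ WxT).reshape(B, T, D)
        self.grads[0] += dWx
        self.grads[1] += dWh
        self.grads[2] += db
        return dx


class PReLU(Layer):
    """Parametric rectifier with one learnable slope per feature."""

    def __init__(self, n_features: int, init: float = 0.25):
        self.alpha = np.full(n_features, init)
        self.params = [self.alpha]
        self.grads = [np.zeros_like(self.alpha)]
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        neg = x <= 0
        self.grads[0] += np.sum(dout * np.where(neg, x, 0.0),
                                axis=tuple(range(x.ndim - 1)))
        return dout * np.where(neg, self.alpha, 1.0)


class LeakyReLU(Layer):
    """Fixed-slope rectifier (slope 0.2 in the discriminator)."""

    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self.params = []
        self.grads = []
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x > 0
        return np.where(self._cache, x, self.alpha * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * np.where(self._cache, 1.0, self.alpha)


class TimeDistributedDense(Layer):
    """Per-timestep affine map, optionally through tanh.

    Maps (B, T, D) -> (B, T, units); with ``activation='tanh'`` outputs
    are confined to (-1, 1), the generator's output range.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 activation: str | None = "tanh"):
        lim = np.sqrt(6.0 / (input_dim + units))
        self.W = rng.uniform(-lim, lim, size=(input_dim, units))
        self.b = np.zeros(units)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x @ self.W + self.b
        out = np.tanh(y) if self.activation == "tanh" else y
        self._cache = (x, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out = self._cache
        dy = dout * (1.0 - out**2) if self.activation == "tanh" else dout
        B, T, D = x.shape
        dy_flat = dy.reshape(B * T, -1)
        self.grads[0] += x.reshape(B * T, D).T @ dy_flat
        self.grads[1] += dy_flat.sum(axis=0)
        return (dy_flat @ self.W.T).reshape(B, T, D)


class FlattenDense(Layer):
    """Flatten (B, T, D) to (B, T*D), then dense to one sigmoid unit.

    ``forward`` returns probabilities in (0, 1); ``backward`` expects the
    gradient w.r.t. the pre-sigmoid logit (dL/dlogit = p - y for binary
    cross-entropy), which keeps the loss gradient numerically stable.
    """

    def __init__(self, flat_dim: int, rng: np.random.Generator):
        self.flat_dim = flat_dim
        lim = np.sqrt(6.0 / (flat_dim + 1))
        self.W = rng.uniform(-lim, lim, size=(flat_dim, 1))
        self.b = np.zeros(1)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        flat = x.reshape(B, -1)
        if flat.shape[1] != self.flat_dim:
            raise ValueError(
                f"flatten width {flat.shape[1]} != configured {self.flat_dim}")
        logit = flat @ self.W + self.b
        self._cache = (x.shape, flat)
        return _sigmoid(logit)

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        shape, flat = self._cache
        self.grads[0] += flat.T @ dlogit
        self.grads[1] += dlogit.sum(axis=0)
        return (dlogit @ self.W.T).reshape(shape)


class Sequential:
    """Ordered layer stack with shared parameter/gradient views."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for lay in self.layers for g in lay.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params
        if len(weights) != len(own):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    def checksum(self) -> float:
        """Cheap fingerprint of all weights (freeze-contract assertions)."""
        return float(sum(np.sum(np.abs(p)) for p in self.params))


class Adam:
    """Adam optimizer over a Sequential's parameter views."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in model.params]
        self.v = [np.zeros_like(p) for p in model.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.model.params, self.model.grads,
                              self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray
             ) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


def bce_loss(prob: np.ndarray, target: np.ndarray
             ) -> tuple[float, np.ndarray]:
    """Binary cross-entropy and its gradient w.r.t. the *logit*.

    The returned gradient is (p - y) / B, to be fed to
    :meth:`FlattenDense.backward`, which expects a logit gradient.
    """
    eps = 1e-12
    p = np.clip(prob, eps, 1.0 - eps)
    loss = float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))
    return loss, (prob - target) / prob.shape[0]
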