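"""A compact NumPy LSTM engine: layers, backprop through time, and Adam.

The cell follows the standard gated recurrence.  With input x(t), previous
hidden state h(t-1) and previous cell state c(t-1):

    i(t) = sigmoid(Wxi x(t) + Whi h(t-1) + bi)      input gate
    f(t) = sigmoid(Wxf x(t) + Whf h(t-1) + bf)      forget gate
    o(t) = sigmoid(Wxo x(t) + Who h(t-1) + bo)      output gate
    c(t) = f(t) * c(t-1) + i(t) * tanh(Wxc x(t) + Whc h(t-1) + bc)
    h(t) = o(t) * tanh(c(t))

All weights of one layer are stored as two stacked matrices ``W`` (input)
and ``U`` (recurrent) of shape (dim, 4H) with gate blocks ordered
[i, f, g, o] (g is the tanh candidate), plus a bias of length 4H.  Training
uses full backpropagation through time and the Adam update.  Everything is
float32; gradients are exact, not truncated.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_cell_step(
    x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    W: np.ndarray,
    U: np.ndarray,
    b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; returns (h, c).

    Shapes: x (B, D), h_prev/c_prev (B, H), W (D, 4H), U (H, 4H), b (4H,).
    Exposed separately so the gate arithmetic can be checked against hand
    computation on a pinned-weight cell.
    """
    H = h_prev.shape[-1]
    z = x @ W + h_prev @ U + b
    i = sigmoid(z[..., :H])
    f = sigmoid(z[..., H:2 * H])
    g = np.tanh(z[..., 2 * H:3 * H])
    o = sigmoid(z[..., 3 * H:])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Dense:
    """Affine layer applied position-wise, optionally with ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, relu: bool = False):
        self.W = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.relu = relu
        self._x: np.ndarray | None = None
        self._z: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        self._z = z
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * (self._z > 0)
        flat_x = self._x.reshape(-1, self.W.shape[0])
        flat_d = dout.reshape(-1, self.W.shape[1])
        self.dW[...] = flat_x.T @ flat_d
        self.db[...] = flat_d.sum(axis=0)
        return dout @ self.W.T


class LSTMLayer:
    """A full-sequence LSTM layer with exact BPTT."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.H = hidden
        self.W = _glorot(rng, d_in, hidden, (d_in, 4 * hidden))
        self.U = _glorot(rng, hidden, hidden, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden, dtype=DTYPE)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias: remember by default
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)
        self._cache: dict | None = None

    @property
    def params(self):
        return [self.W, self.U, self.b]

    @property
    def grads(self):
        return [self.dW, self.dU, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, D) -> hidden states (B, T, H)."""
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        gates = np.empty((B, T, 4 * H), dtype=DTYPE)
        cs = np.empty((B, T, H), dtype=DTYPE)
        c_prevs = np.empty((B, T, H), dtype=DTYPE)
        h_prevs = np.empty((B, T, H), dtype=DTYPE)
        for t in range(T):
            z = x[:, t] @ self.W + h @ self.U + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_prevs[:, t] = c
            h_prevs[:, t] = h
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[:, t, :H] = i
            gates[:, t, H:2 * H] = f
            gates[:, t, 2 * H:3 * H] = g
            gates[:, t, 3 * H:] = o
            cs[:, t] = c
            hs[:, t] = h
        self._cache = dict(x=x, hs=hs, gates=gates, cs=cs,
                           c_prevs=c_prevs, h_prevs=h_prevs)
        return hs

    def backward(self, dh_seq: np.ndarray) -> np.ndarray:
        """dh_seq: (B, T, H) upstream gradient per step -> dx (B, T, D)."""
        cache = self._cache
        x, gates, cs = cache["x"], cache["gates"], cache["cs"]
        c_prevs, h_prevs = cache["c_prevs"], cache["h_prevs"]
        B, T, _ = x.shape
        H = self.H
        self.dW[...] = 0.0
        self.dU[...] = 0.0
        self.db[...] = 0.0
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H:2 * H]
            g = gates[:, t, 2 * H:3 * H]
            o = gates[:, t, 3 * H:]
            tanh_c = np.tanh(cs[:, t])
            dh = dh_seq[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g * i * (1.0 - i)
            df = dc * c_prevs[:, t] * f * (1.0 - f)
            dg = dc * i * (1.0 - g ** 2)
            do = dh * tanh_c * o * (1.0 - o)
            dz = np.concatenate([di, df, dg, do], axis=1)
            self.dW += x[:, t].T @ dz
            self.dU += h_prevs[:, t].T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dx


class Adam:
    """Adam with bias-corrected moments."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood; labels are integer class indices."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.log(p).mean())
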