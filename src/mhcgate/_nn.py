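"""Minimal numpy neural-network core: dense layers, LSTM/BiLSTM stacks with
hand-written backpropagation through time, and a decoupled-weight-decay Adam
(AdamW) optimizer.

Layers keep parameters and accumulated gradients in plain ``{name: ndarray}``
dicts so a model can expose a flat, ordered parameter view for checkpointing
and for per-task gradient surgery on shared parameters.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    # clipping keeps exp() in range; saturation error is below 1e-26
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _xavier(rng, d_in, d_out, (d_in, d_out))
        self.params["b"] = np.zeros(d_out, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x: np.ndarray):
        cache = x
        return x @ self.params["W"] + self.params["b"], cache

    def backward(self, dout: np.ndarray, cache) -> np.ndarray:
        x = cache
        self.grads["W"] += x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class LSTM(Layer):
    """Single-direction LSTM over (B, T, D) inputs; gate order i, f, g, o."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.params["Wx"] = _xavier(rng, d_in, hidden, (d_in, 4 * hidden))
        self.params["Wh"] = _xavier(rng, hidden, hidden, (hidden, 4 * hidden))
        b = np.zeros(4 * hidden, dtype=DTYPE)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias init
        self.params["b"] = b
        self.zero_grad()

    def forward(self, x: np.ndarray):
        B, T, D = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        # input-side affine for every timestep in one matmul
        xa = (x.reshape(B * T, D) @ Wx + b).reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((T, B, H), dtype=DTYPE)
        gates = np.empty((T, B, 4 * H), dtype=DTYPE)
        cs = np.empty((T + 1, B, H), dtype=DTYPE)      # cs[t] = c_{t-1}
        tcs = np.empty((T, B, H), dtype=DTYPE)         # tanh(c_t)
        cs[0] = c
        for t in range(T):
            a = xa[:, t, :] + h @ Wh
            # gate layout i | f | g | o; sigmoid gates evaluated in two calls
            a[:, :2 * H] = sigmoid(a[:, :2 * H])
            a[:, 3 * H:] = sigmoid(a[:, 3 * H:])
            np.tanh(a[:, 2 * H:3 * H], out=a[:, 2 * H:3 * H])
            c = a[:, H:2 * H] * cs[t] + a[:, :H] * a[:, 2 * H:3 * H]
            tc = np.tanh(c)
            h = a[:, 3 * H:] * tc
            hs[t] = h
            cs[t + 1] = c
            gates[t] = a
            tcs[t] = tc
        cache = (x, hs, gates, cs, tcs)
        return hs.transpose(1, 0, 2), cache  # (B, T, H)

    def backward(self, dout: np.ndarray, cache) -> np.ndarray:
        """dout: (B, T, H) gradient on every timestep's output."""
        x, hs, gates, cs, tcs = cache
        B, T, D = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        das = np.empty((T, B, 4 * H), dtype=DTYPE)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        da = np.empty((B, 4 * H), dtype=DTYPE)
        # the recurrence itself is sequential; weight/input gradients are
        # batched into single matmuls afterwards
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H:2 * H]
            g = gates[t, :, 2 * H:3 * H]
            o = gates[t, :, 3 * H:]
            tc = tcs[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            da[:, :H] = dc * g * i * (1.0 - i)
            da[:, H:2 * H] = dc * cs[t] * f * (1.0 - f)
            da[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
            da[:, 3 * H:] = do * o * (1.0 - o)
            das[t] = da
            dh_next = da @ Wh.T
            dc_next = dc * f
        da_flat = das.transpose(1, 0, 2).reshape(B * T, 4 * H)
        self.grads["Wx"] += x.reshape(B * T, D).T @ da_flat
        h_prev = np.concatenate([np.zeros((1, B, H), dtype=DTYPE), hs[:-1]])
        self.grads["Wh"] += h_prev.transpose(1, 0, 2).reshape(B * T, H).T @ da_flat
        self.grads["b"] += da_flat.sum(axis=0)
        return (da_flat @ Wx.T).reshape(B, T, D)


class BiLSTMStack(Layer):
    """Stacked bidirectional LSTM; returns a fixed-size summary vector.

    The summary is the last layer's final forward hidden state concatenated
    with its final backward hidden state: (B, 2 * hidden).
    """

    def __init__(self, d_in: int, hidden: int, num_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.num_layers = num_layers
        self.cells: list[tuple[LSTM, LSTM]] = []
        d = d_in
        for layer in range(num_layers):
            fwd = LSTM(d, hidden, rng)
            bwd = LSTM(d, hidden, rng)
            self.cells.append((fwd, bwd))
            for name, p in fwd.params.items():
                self.params[f"l{layer}_fwd_{name}"] = p
            for name, p in bwd.params.items():
                self.params[f"l{layer}_bwd_{name}"] = p
            d = 2 * hidden
        self.zero_grad()

    def zero_grad(self) -> None:
        super().zero_grad()
        for fwd, bwd in getattr(self, "cells", []):
            fwd.zero_grad()
            bwd.zero_grad()

    def _collect_grads(self) -> None:
        for layer, (fwd, bwd) in enumerate(self.cells):
            for name, g in fwd.grads.items():
                self.grads[f"l{layer}_fwd_{name}"] = g
            for name, g in bwd.grads.items():
                self.grads[f"l{layer}_bwd_{name}"] = g

    def forward(self, x: np.ndarray):
        caches = []
        out = x
        for fwd, bwd in self.cells:
            h_f, cache_f = fwd.forward(out)
            h_b_rev, cache_b = bwd.forward(out[:, ::-1, :])
            h_b = h_b_rev[:, ::-1, :]
            out = np.concatenate([h_f, h_b], axis=2)
            caches.append((cache_f, cache_b))
        # final fwd state = h_f at t=T-1; final bwd state = h_b at t=0
        summary = np.concatenate([out[:, -1, :self.hidden],
                                  out[:, 0, self.hidden:]], axis=1)
        return summary, (caches, x.shape)

    def backward(self, dsummary: np.ndarray, cache) -> np.ndarray:
        caches, x_shape = cache
        B, T, _ = x_shape
        H = self.hidden
        dout = np.zeros((B, T, 2 * H), dtype=DTYPE)
        dout[:, -1, :H] = dsummary[:, :H]
        dout[:, 0, H:] = dsummary[:, H:]
        for layer in range(self.num_layers - 1, -1, -1):
            fwd, bwd = self.cells[layer]
            cache_f, cache_b = caches[layer]
            dx_f = fwd.backward(np.ascontiguousarray(dout[..., :H]), cache_f)
            dx_b_rev = bwd.backward(
                np.ascontiguousarray(dout[:, ::-1, H:]), cache_b)
            dout = dx_f + dx_b_rev[:, ::-1, :]
        self._collect_grads()
        return dout


def relu(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class AdamW:
    """Adam with decoupled weight decay applied multiplicatively to weights."""

    def __init__(self, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             frozen: frozenset[str] = frozenset(),
             no_decay: frozenset[str] = frozenset()) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for key, p in params.items():
            if key in frozen:
                continue
            g = grads[key]
            if key not in self.m:
                self.m[key] = np.zeros_like(p)
                self.v[key] = np.zeros_like(p)
            self.m[key] = self.b1 * self.m[key] + (1.0 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1.0 - self.b2) * g * g
            m_hat = self.m[key] / bc1
            v_hat = self.v[key] / bc2
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if key not in no_decay:
                p -= self.lr * self.weight_decay * p
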