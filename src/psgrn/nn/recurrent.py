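"""Recurrent sequence encoders: GRU (default), vanilla RNN, LSTM.

The GRU follows the two-gate formulation with reset gate r_t and update
gate z_t, both sigmoid, a tanh candidate state, and the convex-combination
update

    r_t = sigmoid(W_r · [h_{t-1}, x_t])
    z_t = sigmoid(W_z · [h_{t-1}, x_t])
    h'_t = tanh(W_h · [r_t ⊙ h_{t-1}, x_t])
    h_t  = (1 - z_t) ⊙ h_{t-1} + z_t ⊙ h'_t

Encoders map a batch of feature matrices (B, T, D) to the full hidden
state sequence (B, T, H); the initial state is zero.  Input-to-hidden
weights use Kaiming initialization, hidden-to-hidden weights are
orthogonal, biases start at zero.
"""

from __future__ import annotations

import numpy as np

from .core import DTYPE, Module, Param, kaiming, orthogonal, sigmoid

__all__ = ["GRU", "RNN", "LSTM"]


class GRU(Module):
    """Gated recurrent unit over (B, T, D) -> (B, T, H).

    Gate order in the stacked weight matrices is [reset | update | candidate].
    """

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden_dim: int):
        H = hidden_dim
        self.in_dim, self.hidden_dim = in_dim, H
        self.Wx = Param(kaiming(rng, (in_dim, 3 * H), in_dim))
        self.Wh = Param(
            np.concatenate([orthogonal(rng, H, H) for _ in range(3)], axis=1)
        )
        self.b = Param(np.zeros(3 * H))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        B, T, _ = x.shape
        H = self.hidden_dim
        h = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        steps = []
        Wx, Wh, b = self.Wx.value, self.Wh.value, self.b.value
        # precompute all input projections in one big matmul
        ax = x.reshape(B * T, -1) @ Wx
        ax = ax.reshape(B, T, 3 * H) + b
        for t in range(T):
            h_prev = h
            g = h_prev @ Wh[:, : 2 * H]
            r = sigmoid(ax[:, t, :H] + g[:, :H])
            z = sigmoid(ax[:, t, H : 2 * H] + g[:, H:])
            rh = r * h_prev
            c = np.tanh(ax[:, t, 2 * H :] + rh @ Wh[:, 2 * H :])
            h = (1 - z) * h_prev + z * c
            hs[:, t] = h
            steps.append((h_prev, r, z, c, rh))
        self._cache = (x, steps)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, steps = self._cache
        B, T, D = x.shape
        H = self.hidden_dim
        Wx, Wh = self.Wx.value, self.Wh.value
        dWx, dWh, db = self.Wx.grad, self.Wh.grad, self.b.grad
        dx = np.empty_like(x)
        dh = np.zeros((B, H), dtype=DTYPE)
        dpre_all = np.empty((B, T, 3 * H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            h_prev, r, z, c, rh = steps[t]
            dht = dhs[:, t] + dh
            dz_pre = dht * (c - h_prev) * z * (1 - z)
            dc_pre = dht * z * (1 - c * c)
            dh_prev = dht * (1 - z)
            drh = dc_pre @ Wh[:, 2 * H :].T
            dr_pre = drh * h_prev * r * (1 - r)
            dh_prev += drh * r
            dWh[:, 2 * H :] += rh.T @ dc_pre
            drz = np.concatenate([dr_pre, dz_pre], axis=1)
            dWh[:, : 2 * H] += h_prev.T @ drz
            dh_prev += drz @ Wh[:, : 2 * H].T
            dpre_all[:, t, :H] = dr_pre
            dpre_all[:, t, H : 2 * H] = dz_pre
            dpre_all[:, t, 2 * H :] = dc_pre
            dh = dh_prev
        dpre_flat = dpre_all.reshape(B * T, 3 * H)
        dWx += x.reshape(B * T, D).T @ dpre_flat
        db += dpre_flat.sum(axis=0)
        dx[...] = (dpre_flat @ Wx.T).reshape(B, T, D)
        return dx


class RNN(Module):
    """Vanilla tanh recurrent encoder, h_t = tanh(W·[h_{t-1}, x_t] + b)."""

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden_dim: int):
        self.in_dim, self.hidden_dim = in_dim, hidden_dim
        self.Wx = Param(kaiming(rng, (in_dim, hidden_dim), in_dim))
        self.Wh = Param(orthogonal(rng, hidden_dim, hidden_dim))
        self.b = Param(np.zeros(hidden_dim))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        B, T, _ = x.shape
        H = self.hidden_dim
        h = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        ax = (x.reshape(B * T, -1) @ self.Wx.value).reshape(B, T, H) + self.b.value
        prevs = []
        for t in range(T):
            prevs.append(h)
            h = np.tanh(ax[:, t] + h @ self.Wh.value)
            hs[:, t] = h
        self._cache = (x, prevs, hs)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, prevs, hs = self._cache
        B, T, D = x.shape
        H = self.hidden_dim
        dh = np.zeros((B, H), dtype=DTYPE)
        dpre_all = np.empty((B, T, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            dht = dhs[:, t] + dh
            dpre = dht * (1 - hs[:, t] ** 2)
            self.Wh.grad += prevs[t].T @ dpre
            dh = dpre @ self.Wh.value.T
            dpre_all[:, t] = dpre
        dpre_flat = dpre_all.reshape(B * T, H)
        self.Wx.grad += x.reshape(B * T, D).T @ dpre_flat
        self.b.grad += dpre_flat.sum(axis=0)
        return (dpre_flat @ self.Wx.value.T).reshape(B, T, D)


class LSTM(Module):
    """Long short-term memory encoder with input/forget/output gates.

    Gate order in the stacked weights is [input | forget | candidate | output].
    """

    def __init__(self, rng: np.random.Generator, in_dim: int, hidden_dim: int):
        H = hidden_dim
        self.in_dim, self.hidden_dim = in_dim, H
        self.Wx = Param(kaiming(rng, (in_dim, 4 * H), in_dim))
        self.Wh = Param(
            np.concatenate([orthogonal(rng, H, H) for _ in range(4)], axis=1)
        )
        self.b = Param(np.zeros(4 * H))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        B, T, _ = x.shape
        H = self.hidden_dim
        h = np.zeros((B, H), dtype=DTYPE)
        cstate = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        ax = (x.reshape(B * T, -1) @ self.Wx.value).reshape(B, T, 4 * H) + self.b.value
        steps = []
        for t in range(T):
            pre = ax[:, t] + h @ self.Wh.value
            i = sigmoid(pre[:, :H])
            f = sigmoid(pre[:, H : 2 * H])
            g = np.tanh(pre[:, 2 * H : 3 * H])
            o = sigmoid(pre[:, 3 * H :])
            c_prev, h_prev = cstate, h
            cstate = f * c_prev + i * g
            tc = np.tanh(cstate)
            h = o * tc
            hs[:, t] = h
            steps.append((h_prev, c_prev, i, f, g, o, tc))
        self._cache = (x, steps)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, steps = self._cache
        B, T, D = x.shape
        H = self.hidden_dim
        dh = np.zeros((B, H), dtype=DTYPE)
        dc = np.zeros((B, H), dtype=DTYPE)
        dpre_all = np.empty((B, T, 4 * H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = steps[t]
            dht = dhs[:, t] + dh
            do_pre = dht * tc * o * (1 - o)
            dct = dht * o * (1 - tc * tc) + dc
            di_pre = dct * g * i * (1 - i)
            df_pre = dct * c_prev * f * (1 - f)
            dg_pre = dct * i * (1 - g * g)
            dc = dct * f
            dpre = np.concatenate([di_pre, df_pre, dg_pre, do_pre], axis=1)
            self.Wh.grad += h_prev.T @ dpre
            dh = dpre @ self.Wh.value.T
            dpre_all[:, t] = dpre
        dpre_flat = dpre_all.reshape(B * T, 4 * H)
        self.Wx.grad += x.reshape(B * T, D).T @ dpre_flat
        self.b.grad += dpre_flat.sum(axis=0)
        return (dpre_flat @ self.Wx.value.T).reshape(B, T, D)
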