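"""A small, fast NumPy implementation of a stacked LSTM regressor.

Everything here is float32 and single-threaded-BLAS friendly: the input
projection of a whole sequence batch is one GEMM, only the recurrent update
loops over time. Gates are laid out as one (4H) block ordered (i, f, o | z)
so the three sigmoids are a single contiguous vectorized call.

Gradients are exact backpropagation-through-time; they are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def init_lstm_params(input_size, hidden_size, n_layers, output_size, rng):
    """Uniform fan-in initialization, U(-1/sqrt(H), 1/sqrt(H)) for recurrent
    layers and U(-1/sqrt(H), 1/sqrt(H)) for the time-distributed output head."""
    params = []
    s = 1.0 / np.sqrt(hidden_size)
    nin = input_size
    for _ in range(n_layers):
        params.append({
            "Wx": rng.uniform(-s, s, (nin, 4 * hidden_size)).astype(F32),
            "Wh": rng.uniform(-s, s, (hidden_size, 4 * hidden_size)).astype(F32),
            "b": rng.uniform(-s, s, 4 * hidden_size).astype(F32),
        })
        nin = hidden_size
    params.append({
        "Wo": rng.uniform(-s, s, (hidden_size, output_size)).astype(F32),
        "bo": np.zeros(output_size, dtype=F32),
    })
    return params


def forward(params, X, want_cache=True):
    """Run the stacked LSTM + linear head on ``X`` (B, T, D) float32.

    Returns (Y, caches); caches is None when ``want_cache`` is False.
    """
    X = np.ascontiguousarray(X, dtype=F32)
    B, T, _ = X.shape
    H = params[0]["Wh"].shape[0]
    S = 3 * H  # sigmoid block (i, f, o); tanh block is [S:]
    caches = [] if want_cache else None
    inp = X
    for layer in params[:-1]:
        Wx, Wh, b = layer["Wx"], layer["Wh"], layer["b"]
        pre = inp.reshape(B * T, -1) @ Wx
        pre = pre.reshape(B, T, 4 * H)
        pre += b
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        Hs = np.empty((B, T, H), dtype=F32)
        Cs = np.empty((B, T, H), dtype=F32)
        Gs = np.empty((B, T, 4 * H), dtype=F32)
        TC = np.empty((B, T, H), dtype=F32)
        for t in range(T):
            g = pre[:, t]
            g += h @ Wh
            gs = Gs[:, t]
            # sigmoid on (i, f, o), tanh on z
            np.exp(np.negative(g[:, :S]), out=gs[:, :S])
            gs[:, :S] += F32(1.0)
            np.reciprocal(gs[:, :S], out=gs[:, :S])
            np.tanh(g[:, S:], out=gs[:, S:])
            i = gs[:, :H]
            f = gs[:, H:2 * H]
            o = gs[:, 2 * H:S]
            z = gs[:, S:]
            c = f * c
            c += i * z
            tc = np.tanh(c, out=TC[:, t])
            h = o * tc
            Hs[:, t] = h
            Cs[:, t] = c
        if want_cache:
            caches.append((inp, Hs, Cs, Gs, TC))
        inp = Hs
    head = params[-1]
    Y = inp.reshape(B * T, H) @ head["Wo"] + head["bo"]
    return Y.reshape(B, T, -1), caches


def backward(params, caches, dY):
    """BPTT; returns gradients in the same structure as ``params``."""
    dY = np.ascontiguousarray(dY, dtype=F32)
    B, T, _ = dY.shape
    H = params[0]["Wh"].shape[0]
    S = 3 * H
    head = params[-1]
    Hs_last = caches[-1][1]
    dWo = Hs_last.reshape(B * T, H).T @ dY.reshape(B * T, -1)
    dbo = dY.sum(axis=(0, 1))
    dinp = (dY.reshape(B * T, -1) @ head["Wo"].T).reshape(B, T, H)
    grads = [None] * len(params)
    grads[-1] = {"Wo": dWo, "bo": dbo}
    for li in range(len(params) - 2, -1, -1):
        Wx, Wh = params[li]["Wx"], params[li]["Wh"]
        inp, Hs, Cs, Gs, TC = caches[li]
        dh_next = np.zeros((B, H), dtype=F32)
        dc_next = np.zeros((B, H), dtype=F32)
        dG = np.empty((B, T, 4 * H), dtype=F32)
        for t in range(T - 1, -1, -1):
            dh = dinp[:, t] + dh_next
            gs = Gs[:, t]
            i = gs[:, :H]
            f = gs[:, H:2 * H]
            o = gs[:, 2 * H:S]
            z = gs[:, S:]
            tc = TC[:, t]
            dc = dh * o
            dc *= (F32(1.0) - tc * tc)
            dc += dc_next
            cprev = Cs[:, t - 1] if t > 0 else F32(0.0)
            dg = dG[:, t]
            dg[:, :H] = dc * z * i * (F32(1.0) - i)
            dg[:, H:2 * H] = dc * cprev * f * (F32(1.0) - f)
            dg[:, 2 * H:S] = dh * tc * o * (F32(1.0) - o)
            dg[:, S:] = dc * i * (F32(1.0) - z * z)
            dh_next = dg @ Wh.T
            dc_next = dc * f
        flat = dG.reshape(B * T, 4 * H)
        dWx = inp.reshape(B * T, -1).T @ flat
        Hprev = np.empty_like(Hs)
        Hprev[:, 0] = F32(0.0)
        Hprev[:, 1:] = Hs[:, :-1]
        dWh = Hprev.reshape(B * T, H).T @ flat
        db = flat.sum(axis=0)
        grads[li] = {"Wx": dWx, "Wh": dWh, "b": db}
        dinp = (flat @ Wx.T).reshape(B, T, -1)
    return grads


class Adam:
    """Standard Adam optimizer over the nested parameter structure."""

    def __init__(self, params, lr=0.006, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = F32(lr)
        self.beta1 = F32(beta1)
        self.beta2 = F32(beta2)
        self.eps = F32(eps)
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in params]
        self.v = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in params]

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - float(self.beta1) ** self.t
        b2t = 1.0 - float(self.beta2) ** self.t
        alpha = F32(float(self.lr) * np.sqrt(b2t) / b1t)
        for layer, glayer, mlayer, vlayer in zip(params, grads, self.m, self.v):
            for k in layer:
                g = glayer[k]
                m = mlayer[k]
                v = vlayer[k]
                m *= self.beta1
                m += (F32(1.0) - self.beta1) * g
                v *= self.beta2
                v += (F32(1.0) - self.beta2) * (g * g)
                layer[k] -= alpha * m / (np.sqrt(v) + self.eps)


def mse_loss_and_grad(Y, target):
    """Mean squared error over all elements and its gradient w.r.t. Y."""
    diff = Y - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    dY = (F32(2.0) / F32(diff.size)) * diff
    return loss, dY
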