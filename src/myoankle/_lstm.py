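"""Minimal single-layer LSTM sequence regressor in numpy.

One LSTM layer followed by a linear single-output head, trained with Adam on
mean-squared error via truncated backpropagation through time.  Gate order in
the stacked weight matrices is (input, forget, cell, output); the forget-gate
bias is initialized to +1, the classic trick that keeps early memory open.
All arithmetic is float64 and fully deterministic given the seeded generator
used at initialization and batching.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["LSTMCore"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMCore:
    """Single-layer LSTM + linear head with an in-object Adam optimizer."""

    PARAM_NAMES = ("Wx", "Wh", "b", "Wy", "by")

    def __init__(self, n_inputs: int, hidden_units: int, rng: np.random.Generator,
                 learning_rate: float = 1e-3, grad_clip: float = 1.0):
        self.n_inputs = n_inputs
        self.hidden = hidden_units
        self.lr = learning_rate
        self.grad_clip = grad_clip
        h = hidden_units
        k = 1.0 / np.sqrt(h)
        self.params = {
            "Wx": rng.uniform(-k, k, size=(n_inputs, 4 * h)),
            "Wh": rng.uniform(-k, k, size=(h, 4 * h)),
            "b": np.zeros(4 * h),
            "Wy": rng.uniform(-k, k, size=h),
            "by": np.zeros(1),
        }
        self.params["b"][h : 2 * h] = 1.0  # forget-gate bias
        self._adam_m = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_v = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------ forward

    def _forward(self, x: np.ndarray):
        """Full forward pass.  x: [B, T, D].  Returns y [B, T] and caches."""
        b_sz, t_len, _ = x.shape
        h_n = self.hidden
        p = self.params
        h = np.zeros((b_sz, h_n))
        c = np.zeros((b_sz, h_n))
        cache = []
        y = np.empty((b_sz, t_len))
        for t in range(t_len):
            a = x[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(a[:, :h_n])
            f = _sigmoid(a[:, h_n : 2 * h_n])
            g = np.tanh(a[:, 2 * h_n : 3 * h_n])
            o = _sigmoid(a[:, 3 * h_n :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            y[:, t] = h @ p["Wy"] + p["by"][0]
            cache.append((x[:, t], h_prev, c_prev, i, f, g, o, tc, h))
        return y, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Stateful pass over a full sequence.  x: [T, D] -> y: [T]."""
        y, _ = self._forward(x[None, :, :])
        return y[0]

    # ----------------------------------------------------------------- backward

    def train_batch(self, x: np.ndarray, target: np.ndarray) -> float:
        """One Adam step on a batch.  x: [B, T, D], target: [B, T].  Returns MSE."""
        y, cache = self._forward(x)
        b_sz, t_len, _ = x.shape
        h_n = self.hidden
        p = self.params
        resid = y - target
        loss = float(np.mean(resid**2))

        grads = {n: np.zeros_like(v) for n, v in p.items()}
        dh_next = np.zeros((b_sz, h_n))
        dc_next = np.zeros((b_sz, h_n))
        scale = 2.0 / (b_sz * t_len)
        for t in range(t_len - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc, h = cache[t]
            dy = scale * resid[:, t]
            grads["Wy"] += dy @ h
            grads["by"][0] += dy.sum()
            dh = dy[:, None] * p["Wy"][None, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += xt.T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh_next = da @ p["Wh"].T

        if self.grad_clip is not None and self.grad_clip > 0:
            norm = np.sqrt(sum(float(np.sum(g_**2)) for g_ in grads.values()))
            if norm > self.grad_clip:
                factor = self.grad_clip / norm
                for g_ in grads.values():
                    g_ *= factor

        self._adam_step(grads)
        return loss

    def _adam_step(self, grads, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        t = self._adam_t
        for n, g in grads.items():
            self._adam_m[n] = beta1 * self._adam_m[n] + (1 - beta1) * g
            self._adam_v[n] = beta2 * self._adam_v[n] + (1 - beta2) * g**2
            m_hat = self._adam_m[n] / (1 - beta1**t)
            v_hat = self._adam_v[n] / (1 - beta2**t)
            self.params[n] -= self.lr * m_hat / (np.sqrt(v_hat) + eps)

    # ------------------------------------------------------------ serialization

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {n: self.params[n].copy() for n in self.PARAM_NAMES}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for n in self.PARAM_NAMES:
            self.params[n] = np.asarray(arrays[n], dtype=float).copy()

    def checksum(self) -> str:
        """SHA-256 over the concatenated parameter bytes (canonical order)."""
        hasher = hashlib.sha256()
        for n in self.PARAM_NAMES:
            hasher.update(np.ascontiguousarray(self.params[n]).tobytes())
        return hasher.hexdigest()
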