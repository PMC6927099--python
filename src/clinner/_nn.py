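"""Minimal numpy neural-network primitives for the sequence tagger.

Contains a batched LSTM layer with explicit backpropagation through
time, masking for padded positions (state is carried through padding
unchanged so the last timestep holds the final real state), an Adam
optimiser, and global-norm gradient clipping.  Everything is float64;
the tagger is desk-scale and correctness (checkable by numerical
gradients) is worth more than throughput here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["LSTM", "Adam", "clip_global_norm", "xavier", "reverse_padded"]


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's first ``lengths[b]`` timesteps, keep padding.

    ``x`` has shape (B, T, ...); used to run the backward direction of a
    bidirectional recurrence with right-padded batches.
    """
    out = x.copy()
    for b, n in enumerate(lengths):
        out[b, :n] = x[b, :n][::-1]
    return out


@dataclass
class LSTM:
    """Single-direction LSTM over right-padded batches.

    Gate order in the fused weight matrices is (input, forget, cell,
    output).  The forget-gate bias is initialised to 1.
    """

    input_dim: int
    hidden_dim: int
    Wx: np.ndarray = field(repr=False, default=None)
    Wh: np.ndarray = field(repr=False, default=None)
    b: np.ndarray = field(repr=False, default=None)

    @classmethod
    def create(
        cls, rng: np.random.Generator, input_dim: int, hidden_dim: int
    ) -> "LSTM":
        Wx = xavier(rng, input_dim, 4 * hidden_dim)
        Wh = xavier(rng, hidden_dim, 4 * hidden_dim)
        b = np.zeros(4 * hidden_dim)
        b[hidden_dim : 2 * hidden_dim] = 1.0  # forget-gate bias
        return cls(input_dim, hidden_dim, Wx, Wh, b)

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.Wx": self.Wx, f"{prefix}.Wh": self.Wh, f"{prefix}.b": self.b}

    def forward(
        self, x: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, dict]:
        """Run the recurrence.

        x: (B, T, input_dim); mask: (B, T) in {0, 1}.  Returns hidden
        states (B, T, hidden_dim) and a cache for backward().  Masked
        positions carry the previous state through unchanged.
        """
        B, T, D = x.shape
        H = self.hidden_dim
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = {
            "x": x, "mask": mask,
            "i": np.zeros((B, T, H)), "f": np.zeros((B, T, H)),
            "g": np.zeros((B, T, H)), "o": np.zeros((B, T, H)),
            "tc": np.zeros((B, T, H)),  # tanh(c_t)
            "h_prev": np.zeros((B, T, H)), "c_prev": np.zeros((B, T, H)),
        }
        for t in range(T):
            m = mask[:, t][:, None]
            cache["h_prev"][:, t] = h
            cache["c_prev"][:, t] = c
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
            cache["i"][:, t], cache["f"][:, t] = i, f
            cache["g"][:, t], cache["o"][:, t] = g, o
            cache["tc"][:, t] = tc
            hs[:, t] = h
        return hs, cache

    def backward(
        self, dhs: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Backprop through time.

        dhs: gradient w.r.t. the returned hidden states (B, T, H).
        Returns (dx, grads) with dx of shape (B, T, input_dim).
        """
        x, mask = cache["x"], cache["mask"]
        B, T, D = x.shape
        H = self.hidden_dim
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_rec = np.zeros((B, H))
        dc_rec = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            m = mask[:, t][:, None]
            i, f = cache["i"][:, t], cache["f"][:, t]
            g, o = cache["g"][:, t], cache["o"][:, t]
            tc = cache["tc"][:, t]
            c_prev = cache["c_prev"][:, t]

            dh_total = dhs[:, t] + dh_rec
            dh_new = m * dh_total  # gradient into this step's candidate h
            dh_carry = (1 - m) * dh_total
            dc_new = m * dc_rec
            dc_carry = (1 - m) * dc_rec

            do = dh_new * tc
            dct = dh_new * o * (1 - tc ** 2) + dc_new
            df = dct * c_prev
            di = dct * g
            dg = dct * i
            dc_rec = dct * f + dc_carry

            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g ** 2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dx[:, t] = dz @ self.Wx.T
            dh_rec = dz @ self.Wh.T + dh_carry
            dWx += x[:, t].T @ dz
            dWh += cache["h_prev"][:, t].T @ dz
            db += dz.sum(axis=0)
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


def clip_global_norm(
    grads: Mapping[str, np.ndarray], max_norm: float
) -> float:
    """Scale all gradients in place so their global L2 norm <= max_norm."""
    total = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


class Adam:
    """Adam with bias correction, over a dict of named parameters."""

    def __init__(
        self,
        params: Mapping[str, np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = dict(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.t = 0

    def step(self, grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
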