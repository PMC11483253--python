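"""Neural building blocks: linear, embedding, transformer encoder layer, LSTM.

Parameters are plain :class:`~temporalmatch.nn.autodiff.Tensor` objects with
``requires_grad=True``; modules expose them through :meth:`Module.parameters`
in a deterministic order so optimizers and checksums are reproducible.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for name in sorted(vars(self)):
            value = getattr(self, name)
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def checksum(self) -> float:
        """Order-sensitive parameter digest, used to assert frozenness."""
        return float(sum(np.abs(a.astype(np.float64)).sum() + a.astype(np.float64).sum() * 0.5
                         for a in self.state_arrays()))


def _init(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = _init(rng, (d_in, d_out), 1.0 / np.sqrt(d_in))
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.weight, self.bias)


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, scale: float = 0.02):
        self.weight = _init(rng, (n, d), scale)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return ad.gather_rows(self.weight, indices)


class LayerNorm(Module):
    def __init__(self, d: int):
        self.weight = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.weight, self.bias)


class Attention(Module):
    """Multi-head self-attention with key padding mask."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads != 0:
            raise ValueError(f"hidden size {d} not divisible by {n_heads} heads")
        self.d = d
        self.n_heads = n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.proj = Linear(d, d, rng)

    def _split(self, x: Tensor, b: int, length: int) -> Tensor:
        dh = self.d // self.n_heads
        x = ad.reshape(x, (b, length, self.n_heads, dh))
        return ad.swapaxes(x, 1, 2)  # [B, H, L, dh]

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        b, length, d = x.shape
        q = self._split(self.wq(x), b, length)
        k = self._split(self.wk(x), b, length)
        v = self._split(self.wv(x), b, length)
        out = ad.scaled_dot_attention(q, k, v, key_mask)  # [B, H, L, dh]
        out = ad.reshape(ad.swapaxes(out, 1, 2), (b, length, d))
        return self.proj(out)


class TransformerLayer(Module):
    """Post-norm transformer encoder block (attention + position-wise FFN)."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = Attention(d, n_heads, rng)
        self.ln1 = LayerNorm(d)
        self.ff1 = Linear(d, d_ff, rng)
        self.ff2 = Linear(d_ff, d, rng)
        self.ln2 = LayerNorm(d)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.attn(x, key_mask))
        x = self.ln2(x + self.ff2(ad.gelu(self.ff1(x))))
        return x


class LSTM(Module):
    """Single-layer LSTM over padded sequences, returning the last real state.

    Gate order in the fused weight matrices is (input, forget, cell, output).
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.wx = Linear(d_in, 4 * d_hidden, rng)
        self.wh = Linear(d_hidden, 4 * d_hidden, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        # x: [B, T, d_in]; mask: [B, T] bool. Returns h at each item's last step.
        b, steps, _ = x.shape
        dh = self.d_hidden
        h = Tensor(np.zeros((b, dh), dtype=np.float32))
        c = Tensor(np.zeros((b, dh), dtype=np.float32))
        for t in range(steps):
            xt = _slice_t(x, t)
            gates = self.wx(xt) + self.wh(h)
            i = ad.sigmoid(_cols(gates, 0, dh))
            f = ad.sigmoid(_cols(gates, dh, 2 * dh))
            g = ad.tanh(_cols(gates, 2 * dh, 3 * dh))
            o = ad.sigmoid(_cols(gates, 3 * dh, 4 * dh))
            c_new = f * c + i * g
            h_new = o * ad.tanh(c_new)
            m = Tensor(mask[:, t:t + 1].astype(np.float32))
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
        return h


def _slice_t(x: Tensor, t: int) -> Tensor:
    """x[:, t, :] keeping gradient flow."""
    data = x.data[:, t, :]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, t, :] = g
            x._accumulate(full)

    return ad._make(data, (x,), backward)


def _cols(x: Tensor, lo: int, hi: int) -> Tensor:
    data = x.data[:, lo:hi]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, lo:hi] = g
            x._accumulate(full)

    return ad._make(data, (x,), backward)
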