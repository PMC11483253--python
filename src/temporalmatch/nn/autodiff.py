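"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the package's models need: broadcasting
arithmetic, (batched) matmul, gather/embedding lookup, reductions, fused
softmax-cross-entropy, fused layer norm, and the pointwise nonlinearities
used by transformer and LSTM layers. Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via a topological sort.

All computation is float32 unless the caller supplies float64 data; the
engine never changes dtype behind the caller's back.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _acc_unb(t: "Tensor", g: np.ndarray) -> None:
    """Accumulate ``g`` into ``t`` after unbroadcasting; adopts the buffer
    only when unbroadcasting actually allocated a new one."""
    gu = _unbroadcast(g, t.data.shape)
    if gu is g:
        t._accumulate(gu)
    else:
        t._accumulate_owned(gu)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            if isinstance(data, (np.floating, np.integer)):
                data = np.asarray(data)  # keep numpy scalar dtype
            else:
                data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad and grad_enabled()
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            if g.dtype == self.data.dtype:
                self.grad = g.copy()
            else:
                self.grad = g.astype(self.data.dtype)
        else:
            self.grad += g

    def _accumulate_owned(self, g: np.ndarray) -> None:
        """Adopt a freshly allocated gradient without copying.

        Only valid when the caller guarantees ``g`` is not aliased by any
        other node's gradient (i.e. it was newly computed in the backward
        closure, not passed through from the output gradient).
        """
        if self.grad is None:
            if g.dtype != self.data.dtype:
                g = g.astype(self.data.dtype)
            self.grad = g
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other, self))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other, self))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _as_tensor(-1.0, self))

    def __sub__(self, other):
        return add(self, -_as_tensor(other, self))

    def __rsub__(self, other):
        return add(_as_tensor(other, self), -self)

    def __truediv__(self, other):
        other = _as_tensor(other, self)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else np.float32
    return Tensor(np.asarray(x, dtype=dtype))


def _make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    req = grad_enabled() and any(p.requires_grad for p in parents)
    out = Tensor(data)
    out.requires_grad = req
    if req:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# -- primitive operations --------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            _acc_unb(a, g)
        if b.requires_grad:
            _acc_unb(b, g)

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate_owned(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate_owned(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    data = a.data**exponent

    def backward(g):
        if a.requires_grad:
            a._accumulate_owned(g * exponent * a.data ** (exponent - 1.0))

    return _make(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy batch semantics (leading dims broadcast)."""
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate_owned(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate_owned(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate_owned(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
        a._accumulate_owned(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), _as_tensor(1.0 / n, a))


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    data = np.swapaxes(a.data, ax1, ax2)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.swapaxes(g, ax1, ax2))

    return _make(data, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(data, tuple(tensors), backward)


def gather_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Embedding lookup: ``table[indices]`` with scatter-add backward."""
    indices = np.asarray(indices)
    data = table.data[indices]

    def backward(g):
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, indices.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accumulate_owned(acc)

    return _make(data, (table,), backward)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate_owned(g * data)

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate_owned(g / a.data)

    return _make(data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate_owned(g * (1.0 - data * data))

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate_owned(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate_owned(g * (a.data > 0.0))

    return _make(data, (a,), backward)


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))


def gelu(a: Tensor) -> Tensor:
    """Tanh approximation of the Gaussian error linear unit.

    Written with in-place updates: gelu is the widest activation in the
    transformer blocks and dominates pointwise cost otherwise.
    """
    x = a.data
    u = x * x
    inner = u * x
    inner *= np.float32(0.044715)
    inner += x
    inner *= _GELU_C
    t = np.tanh(inner)
    data = 1.0 + t
    data *= x
    data *= 0.5

    def backward(g):
        if a.requires_grad:
            # d/dx = 0.5 * [(1 + t) + x * (1 - t^2) * C * (1 + 3*0.044715*x^2)]
            v = u * np.float32(3 * 0.044715)
            v += 1.0
            v *= _GELU_C
            w = t * t
            np.subtract(1.0, w, out=w)
            w *= v
            w *= x
            w += t
            w += 1.0
            w *= 0.5
            w *= g
            a._accumulate_owned(w)

    return _make(data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            gs = (g * data).sum(axis=axis, keepdims=True)
            a._accumulate_owned(data * (g - gs))

    return _make(data, (a,), backward)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of ``logits`` [N, V] against integer ``targets`` [N]."""
    targets = np.asarray(targets)
    if logits.data.ndim != 2 or targets.shape[0] != logits.data.shape[0]:
        raise ValueError("logits must be [N, V] with one target per row")
    n = logits.data.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    loss = -logp[np.arange(n), targets].mean()

    def backward(g):
        if logits.requires_grad:
            grad = np.exp(logp)
            grad[np.arange(n), targets] -= 1.0
            logits._accumulate_owned(grad * (g / n))

    return _make(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Fused affine map ``x @ weight + bias`` (one graph node).

    ``weight`` must be 2-D; leading axes of ``x`` are flattened into a
    single GEMM rather than a batched matmul.
    """
    d_in, d_out = weight.data.shape
    lead = x.data.shape[:-1]
    x2 = x.data.reshape(-1, d_in)
    data = (x2 @ weight.data + bias.data).reshape(*lead, d_out)

    def backward(g):
        g2 = g.reshape(-1, d_out)
        if x.requires_grad:
            x._accumulate_owned((g2 @ weight.data.T).reshape(x.data.shape))
        if weight.requires_grad:
            weight._accumulate_owned(x2.T @ g2)
        if bias.requires_grad:
            bias._accumulate_owned(g2.sum(axis=0))

    return _make(data, (x, weight, bias), backward)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         key_mask: np.ndarray) -> Tensor:
    """Fused softmax attention for [B, H, L, dh] tensors.

    ``key_mask`` is [B, L] boolean; masked keys receive no attention.
    """
    dh = q.data.shape[-1]
    scale = np.float32(1.0 / np.sqrt(dh))
    scores = (q.data @ np.swapaxes(k.data, -1, -2)) * scale
    scores += np.where(key_mask[:, None, None, :], 0.0, -1e9).astype(scores.dtype)
    scores -= scores.max(axis=-1, keepdims=True)
    attn = np.exp(scores)
    attn /= attn.sum(axis=-1, keepdims=True)
    data = attn @ v.data

    def backward(g):
        if v.requires_grad:
            v._accumulate_owned(np.swapaxes(attn, -1, -2) @ g)
        if q.requires_grad or k.requires_grad:
            g_attn = g @ np.swapaxes(v.data, -1, -2)
            g_scores = attn * (g_attn - (g_attn * attn).sum(axis=-1, keepdims=True))
            if q.requires_grad:
                q._accumulate_owned((g_scores @ k.data) * scale)
            if k.requires_grad:
                k._accumulate_owned((np.swapaxes(g_scores, -1, -2) @ q.data) * scale)

    return _make(data, (q, k, v), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits.

    ``weights`` (optional, per-item) are normalized to mean 1 so the loss
    scale is comparable with the unweighted case.
    """
    z = logits.data.reshape(-1)
    y = np.asarray(targets, dtype=z.dtype).reshape(-1)
    if z.size == 0:
        raise ValueError("empty batch")
    if y.size != z.size:
        raise ValueError("logits and targets must have equal length")
    if weights is None:
        w = np.ones_like(z)
    else:
        w = np.asarray(weights, dtype=z.dtype).reshape(-1)
        w = w / w.mean()
    per_item = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = (w * per_item).mean()

    def backward(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            dz = w * (p - y) * (g / z.size)
            logits._accumulate_owned(dz.reshape(logits.data.shape))

    return _make(np.asarray(loss, dtype=z.dtype), (logits,), backward)


def layer_norm(a: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift (fused backward)."""
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    data = xhat * weight.data + bias.data

    def backward(g):
        if weight.requires_grad:
            weight._accumulate_owned(
                (g * xhat).reshape(-1, a.data.shape[-1]).sum(axis=0))
        if bias.requires_grad:
            bias._accumulate_owned(g.reshape(-1, a.data.shape[-1]).sum(axis=0))
        if a.requires_grad:
            gx = g * weight.data
            ga = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            a._accumulate_owned(ga)

    return _make(data, (a, weight, bias), backward)
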