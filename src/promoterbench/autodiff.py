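"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the promoter classifiers need: broadcasted
add/mul, matmul, elementwise nonlinearities, basic indexing, concatenation,
1-D convolution (im2col), non-overlapping max pooling, and numerically
stable fused classification losses.  Everything runs in float64 so
gradients can be validated against central finite differences.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            self._accum(g @ other.data.swapaxes(-1, -2))
            other._accum(self.data.swapaxes(-1, -2) @ g)

        out._backward = bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    # -- reductions & nonlinearities ---------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def pow(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: self._accum(g * (1 - t * t))
        return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid cross-correlation: x (B,C,L), w (F,C,k), b (F,) -> (B,F,L-k+1)."""
    B, C, L = x.data.shape
    F, C2, k = w.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, filters {C2}")
    if L < k:
        raise ValueError(f"input length {L} shorter than filter length {k}")
    cols = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=2)  # (B,C,Lo,k)
    out_data = np.einsum("bclk,fck->bfl", cols, w.data, optimize=True) + b.data[None, :, None]
    out = Tensor(out_data, parents=(x, w, b))
    Lo = L - k + 1

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("bfl,bclk->fck", g, cols, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.einsum("bfl,fck->bclk", g, w.data, optimize=True)
            dx = np.zeros_like(x.data)
            for o in range(k):
                dx[:, :, o : o + Lo] += dcols[:, :, :, o]
            x._accum(dx)

    out._backward = bw
    return out


def max_pool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pool along the last axis (remainder dropped)."""
    B, F, L = x.data.shape
    Lp = L // pool
    if Lp == 0:
        raise ValueError(f"pool width {pool} exceeds length {L}")
    trimmed = x.data[:, :, : Lp * pool].reshape(B, F, Lp, pool)
    idx = trimmed.argmax(axis=3)
    out = Tensor(trimmed.max(axis=3), parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dtr = np.zeros_like(trimmed)
        np.put_along_axis(dtr, idx[..., None], g[..., None], axis=3)
        dx = np.zeros_like(x.data)
        dx[:, :, : Lp * pool] = dtr.reshape(B, F, Lp * pool)
        x._accum(dx)

    out._backward = bw
    return out


def global_max_pool1d(x: Tensor) -> Tensor:
    """Max over the whole position axis: (B,F,L) -> (B,F)."""
    idx = x.data.argmax(axis=2)
    out = Tensor(x.data.max(axis=2), parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, idx[..., None], g[..., None], axis=2)
        x._accum(dx)

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores, computed stably."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    loss_val = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    out = Tensor(loss_val, parents=(logits,))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    out._backward = lambda g: logits._accum(g * (p - y) / z.size)
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy for (B, K) raw scores and integer class targets."""
    z = logits.data
    y = np.asarray(targets, dtype=np.intp)
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    out = Tensor(-logp[np.arange(len(y)), y].mean(), parents=(logits,))
    probs = np.exp(logp)

    def bw(g):
        d = probs.copy()
        d[np.arange(len(y)), y] -= 1.0
        logits._accum(g * d / len(y))

    out._backward = bw
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    zmax = z.max(axis=-1, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over a dict of named parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


class SGD:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.vel = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.vel[k] = self.momentum * self.vel[k] - self.lr * p.grad
            p.data += self.vel[k]

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
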