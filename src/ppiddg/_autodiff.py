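"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the geometric encoder and the pre-training
heads need: broadcast arithmetic, 2-D matrix products, per-channel mixing of
3-vector stacks, elementwise nonlinearities, reductions, concatenation, row
gathering and segment means for message aggregation. Gradients accumulate in
float64 numpy arrays; the graph is built eagerly and freed after backward().
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "segment_mean",
           "split_matmul", "split_vecmix"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            # copy: g may be a view into another tensor's gradient
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            # free graph references eagerly
            t._parents = ()
            t._backward = None

    # ---- arithmetic -----------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    __matmul__ = matmul

    def vecmix(self, w: "Tensor") -> "Tensor":
        """Mix vector channels: x[N, v_in, 3], w[v_out, v_in] -> [N, v_out, 3].

        Implemented as a BLAS matmul on the (N*3, v) unfolding.
        """
        w = Tensor._lift(w)
        y, xt = _vecmix_fwd(self.data, w.data)
        out = Tensor(y, (self, w))

        def bw(g):
            gt = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(-1, g.shape[1])
            if self.requires_grad:
                n = self.data.shape[0]
                self._accum((gt @ w.data).reshape(n, 3, -1).transpose(0, 2, 1))
            if w.requires_grad:
                w._accum(gt.T @ xt)

        out._backward = bw
        return out

    # ---- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y * (1 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / (2 * y))
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    # ---- reductions & shaping ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def norm(self, axis=-1, keepdims=False, eps=1e-8):
        """Euclidean norm along `axis` (fused); eps keeps the gradient finite
        at zero vectors."""
        n = np.sqrt((self.data * self.data).sum(axis=axis, keepdims=True) + eps)
        out_data = n if keepdims else n.squeeze(axis)
        out = Tensor(out_data, (self,))

        def bw(g):
            if self.requires_grad:
                gk = g if keepdims else np.expand_dims(g, axis)
                self._accum(gk * self.data / n)

        out._backward = bw
        return out

    def detach(self):
        return Tensor(self.data.copy())


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def _vecmix_fwd(x: np.ndarray, w: np.ndarray):
    """(y, x_unfolded) for y[n,w,c] = sum_v w[w,v] x[n,v,c] via BLAS."""
    n = x.shape[0]
    xt = np.ascontiguousarray(x.transpose(0, 2, 1)).reshape(n * 3, -1)
    y = (xt @ w.T).reshape(n, 3, -1).transpose(0, 2, 1)
    return np.ascontiguousarray(y), xt


def split_matmul(parts, W: Tensor, b: Tensor | None = None) -> Tensor:
    """sum_k parts[k] @ W[rows_k] (+ b) without materializing the
    concatenation of `parts`; W's row blocks correspond to the parts."""
    parts = [Tensor._lift(p) for p in parts]
    offs = np.cumsum([0] + [p.data.shape[1] for p in parts])
    if offs[-1] != W.data.shape[0]:
        raise ValueError("part widths do not sum to W rows")
    y = parts[0].data @ W.data[offs[0]:offs[1]]
    for k in range(1, len(parts)):
        y += parts[k].data @ W.data[offs[k]:offs[k + 1]]
    if b is not None:
        y = y + b.data
    out = Tensor(y, tuple(parts) + ((W, b) if b is not None else (W,)))

    def bw(g):
        for k, p in enumerate(parts):
            if p.requires_grad:
                p._accum(g @ W.data[offs[k]:offs[k + 1]].T)
        if W.requires_grad:
            W._accum(np.concatenate([p.data.T @ g for p in parts], axis=0))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=0))

    out._backward = bw
    return out


def split_vecmix(parts, W: Tensor) -> Tensor:
    """sum_k einsum('nvc,wv->nwc', parts[k], W[:, cols_k]): vector-channel
    mixing over an implicit channel concatenation of `parts`."""
    parts = [Tensor._lift(p) for p in parts]
    offs = np.cumsum([0] + [p.data.shape[1] for p in parts])
    if offs[-1] != W.data.shape[1]:
        raise ValueError("part channel counts do not sum to W columns")
    n = parts[0].data.shape[0]
    xts = [np.ascontiguousarray(p.data.transpose(0, 2, 1)).reshape(n * 3, -1)
           for p in parts]
    acc = xts[0] @ W.data[:, offs[0]:offs[1]].T
    for k in range(1, len(parts)):
        acc += xts[k] @ W.data[:, offs[k]:offs[k + 1]].T
    y = np.ascontiguousarray(acc.reshape(n, 3, -1).transpose(0, 2, 1))
    out = Tensor(y, tuple(parts) + (W,))

    def bw(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(n * 3, -1)
        for k, p in enumerate(parts):
            if p.requires_grad:
                p._accum((gt @ W.data[:, offs[k]:offs[k + 1]])
                         .reshape(n, 3, -1).transpose(0, 2, 1))
        if W.requires_grad:
            W._accum(np.concatenate([(gt.T @ xt) for xt in xts], axis=1))

    out._backward = bw
    return out


def segment_mean(src: Tensor, index: np.ndarray, n_segments: int) -> Tensor:
    """Mean of `src` rows grouped by `index`; empty segments yield zeros.

    This is the per-relation message aggregation: src has one row per edge,
    index[e] is the destination node of edge e.
    """
    index = np.asarray(index, dtype=np.intp)
    counts = np.bincount(index, minlength=n_segments).astype(np.float64)
    safe = np.maximum(counts, 1.0)
    acc = np.zeros((n_segments,) + src.data.shape[1:])
    np.add.at(acc, index, src.data)
    acc /= safe.reshape((-1,) + (1,) * (src.data.ndim - 1))
    out = Tensor(acc, (src,))

    def bw(g):
        if src.requires_grad:
            scaled = g / safe.reshape((-1,) + (1,) * (g.ndim - 1))
            src._accum(scaled[index])

    out._backward = bw
    return out


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
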