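"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the attention network, the feed-forward
baseline and the integrated-gradients explainer need: broadcasting
arithmetic, matmul (2-D, and batched 3-D against a 2-D weight), row
gather/scatter, segment reductions over a sorted index (the softmax
normalisation over each target node's incoming edges), and the usual
activations.  Everything is float64 and single-threaded numpy, which makes
runs bit-reproducible under a fixed seed.

Segment reductions use ``np.add.reduceat`` over pre-sorted edge indices
rather than ``np.add.at``; a :class:`SegmentIndex` carries the sort order so
backward passes stay O(E log E)-free after construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "SegmentIndex",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "t_sum",
    "t_exp",
    "t_log",
    "reshape",
    "gather",
    "segment_sum",
    "segment_max_detached",
    "leaky_relu",
    "elu",
    "log_softmax",
    "Adam",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # Operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if seed is None else np.asarray(seed, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(node: Tensor, grad: np.ndarray) -> None:
    if not (node.requires_grad or node._parents):
        return
    if node.grad is None:
        node.grad = grad.copy()
    else:
        node.grad += grad


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data - b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(-g, b.data.shape))

    return _make(data, (a, b), backward)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, -g)

    return _make(-a.data, (a,), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data / b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    """``a @ b`` with ``a`` 2-D or 3-D (batched) and ``b`` 2-D."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        if a.data.ndim == 2:
            _accumulate(b, a.data.T @ g)
        else:  # batched: sum weight gradient over leading axis
            _accumulate(b, np.einsum("bnf,bnk->fk", a.data, g))

    return _make(data, (a, b), backward)


def t_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accumulate(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def t_exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        _accumulate(a, g * data)

    return _make(data, (a,), backward)


def t_log(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.data.shape

    def backward(g):
        _accumulate(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


class SegmentIndex:
    """Index structure for gather/scatter along an edge list.

    ``idx`` maps each of E edges to a node id in [0, n_nodes).  ``order``
    sorts the edges by node id so both the forward segment reduction and the
    scatter in gather's backward pass can use ``reduceat``.
    """

    def __init__(self, idx: np.ndarray, n_nodes: int):
        self.idx = np.asarray(idx, dtype=np.int64)
        self.n_nodes = int(n_nodes)
        self.order = np.argsort(self.idx, kind="stable")
        sorted_idx = self.idx[self.order]
        self.uniq, self.starts = np.unique(sorted_idx, return_index=True)

    def scatter_sum(self, values: np.ndarray, axis: int = 0) -> np.ndarray:
        """Sum ``values`` (per-edge, along ``axis``) into per-node slots."""
        v = np.take(values, self.order, axis=axis)
        reduced = np.add.reduceat(v, self.starts, axis=axis)
        shape = list(values.shape)
        shape[axis] = self.n_nodes
        out = np.zeros(shape, dtype=values.dtype)
        sl = [slice(None)] * values.ndim
        sl[axis] = self.uniq
        out[tuple(sl)] = reduced
        return out

    def scatter_max(self, values: np.ndarray, axis: int = 0, fill=-np.inf) -> np.ndarray:
        v = np.take(values, self.order, axis=axis)
        reduced = np.maximum.reduceat(v, self.starts, axis=axis)
        shape = list(values.shape)
        shape[axis] = self.n_nodes
        out = np.full(shape, fill, dtype=values.dtype)
        sl = [slice(None)] * values.ndim
        sl[axis] = self.uniq
        out[tuple(sl)] = reduced
        return out


def gather(a, seg: SegmentIndex, axis: int = 0) -> Tensor:
    """Per-edge view ``a[idx]`` along ``axis``; scatter-adds on backward."""
    a = _as_tensor(a)
    data = np.take(a.data, seg.idx, axis=axis)

    def backward(g):
        _accumulate(a, seg.scatter_sum(g, axis=axis))

    return _make(data, (a,), backward)


def segment_sum(a, seg: SegmentIndex, axis: int = 0) -> Tensor:
    """Sum per-edge values into per-node slots (missing nodes get zero)."""
    a = _as_tensor(a)
    data = seg.scatter_sum(a.data, axis=axis)

    def backward(g):
        _accumulate(a, np.take(g, seg.idx, axis=axis))

    return _make(data, (a,), backward)


def segment_max_detached(a: Tensor, seg: SegmentIndex, axis: int = 0) -> np.ndarray:
    """Per-node max of per-edge values; constant w.r.t. the graph (used only
    to stabilise the segment softmax)."""
    return seg.scatter_max(a.data, axis=axis)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    data = np.where(a.data > 0, a.data, slope * a.data)

    def backward(g):
        _accumulate(a, g * np.where(a.data > 0, 1.0, slope))

    return _make(data, (a,), backward)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _as_tensor(a)
    expm1 = alpha * np.expm1(np.minimum(a.data, 0.0))
    data = np.where(a.data > 0, a.data, expm1)

    def backward(g):
        _accumulate(a, g * np.where(a.data > 0, 1.0, expm1 + alpha))

    return _make(data, (a,), backward)


def log_softmax(logits: Tensor) -> Tensor:
    """Row-wise log-softmax of a 2-D logits tensor, numerically stabilised."""
    m = logits.data.max(axis=1, keepdims=True)  # constant shift
    shifted = sub(logits, Tensor(m))
    lse = t_log(t_sum(t_exp(shifted), axis=1, keepdims=True))
    return sub(shifted, lse)


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
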