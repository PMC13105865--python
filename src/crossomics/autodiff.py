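"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The cross-omics model is small (a few hundred graph nodes, hidden widths in the
tens), so a dependency-free tape-based engine is sufficient: every operation
records its inputs and a closure that accumulates gradients into them.  The op
set is exactly what the relational message-passing network, the attention
readouts and the attribution methods need — dense linear algebra, pointwise
nonlinearities, reductions, and gather/scatter along the node axis.

Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager that disables tape recording (pure inference)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    __array_priority__ = 100  # win against raw ndarrays in mixed expressions

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray, own: bool = False):
        """Accumulate a gradient contribution.

        ``own=True`` promises `grad` is a fresh temporary this tensor may keep
        without copying — the common case in the backward closures below, and
        the difference between one and two passes over every large array.
        """
        if self.grad is None:
            g = _unbroadcast(grad, self.data.shape)
            if g is grad and not own:
                g = grad.copy()
            self.grad = g
        else:
            self.grad += _unbroadcast(grad, self.data.shape)

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (defaults to d(out)/d(out) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be deep at many layers/steps
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data, own=True)
            if other.requires_grad:
                other._accum(g * self.data, own=True)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data, own=True)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2), own=True)

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2), own=True)
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g, own=True)

        return self._make(self.data @ other.data, (self, other), backward)

    def square(self):
        return self * self

    # ---------------------------------------------------------- nonlinearities
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask, own=True)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2), own=True)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data, own=True)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data, own=True)

        return self._make(np.log(self.data), (self,), backward)

    # --------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig), own=True)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.add.at(self.grad, key, g)

        return self._make(self.data[key], (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy(), own=True)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_detached(self, axis=None, keepdims=False) -> np.ndarray:
        """Max as a constant (used for numerically stable softmax shifts)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # ---------------------------------------------------- node-axis operations
    def take_nodes(self, index: np.ndarray):
        """Gather along axis 1 (the node axis of a (batch, nodes, dim) state)."""
        index = np.asarray(index)

        def backward(g):
            if self.requires_grad:
                scattered = _segment_sum(g, index, self.data.shape[1])
                if self.grad is None:
                    self.grad = scattered
                else:
                    self.grad += scattered

        return self._make(self.data[:, index], (self,), backward)

    def take_block(self, lo: int, hi: int):
        """Contiguous slice along axis 1 (cheaper backward than a fancy gather)."""

        def backward(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                self.grad[:, lo:hi] += g

        return self._make(self.data[:, lo:hi], (self,), backward)

    def scatter_add_nodes(self, index: np.ndarray, n_out: int):
        """Scatter-sum rows along axis 1 into `n_out` slots (message aggregation)."""
        index = np.asarray(index)

        def backward(g):
            if self.requires_grad:
                self._accum(g[:, index], own=True)

        return self._make(_segment_sum(self.data, index, n_out), (self,), backward)


#: memoized sort plans for the edge-index arrays reused on every layer/step;
#: the stored reference keeps the keyed array alive so ids stay valid
_SEGMENT_PLANS: dict[int, tuple] = {}


def _segment_plan(index: np.ndarray) -> tuple:
    key = id(index)
    hit = _SEGMENT_PLANS.get(key)
    if hit is not None and hit[0] is index:
        return hit[1]
    order = np.argsort(index, kind="stable")
    sorted_ix = index[order]
    boundaries = np.flatnonzero(np.diff(sorted_ix)) + 1
    starts = np.concatenate(([0], boundaries))
    plan = (order, starts, sorted_ix[starts])
    _SEGMENT_PLANS[key] = (index, plan)
    return plan


def _segment_sum(values: np.ndarray, index: np.ndarray, n_out: int) -> np.ndarray:
    """Sum rows of (B, E, ...) `values` into `n_out` node slots along axis 1.

    Sorting plus ``np.add.reduceat`` is dramatically faster than ``np.add.at``
    for the duplicate-heavy index vectors that edge lists produce.
    """
    out_shape = (values.shape[0], n_out) + values.shape[2:]
    out = np.zeros(out_shape, dtype=values.dtype)
    if len(index) == 0:
        return out
    order, starts, segment_ids = _segment_plan(index)
    out[:, segment_ids] = np.add.reduceat(values[:, order], starts, axis=1)
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis, differentiable per block."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if _grad_enabled and any(t.requires_grad for t in tensors):
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Stack equal-shaped tensors along a new axis."""
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if _grad_enabled and any(t.requires_grad for t in tensors):
        def backward(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))

        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
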