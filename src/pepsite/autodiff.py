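"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to express and train the attention network: broadcasted
arithmetic, (batched) matrix products, row gathering for graph neighborhoods,
reductions, and the usual nonlinearities. Tensors hold float64 data; backward
walks a topologically sorted tape. An Adam optimizer lives alongside since
every training path in the package uses it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over broadcasted axes back to the original shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        o = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if o.requires_grad:
                o.grad += _unbroadcast(g, o.shape)

        return self._make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __mul__(self, other):
        o = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * o.data, self.shape)
            if o.requires_grad:
                o.grad += _unbroadcast(g * self.data, o.shape)

        return self._make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        o = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / o.data, self.shape)
            if o.requires_grad:
                o.grad += _unbroadcast(-g * self.data / o.data**2, o.shape)

        return self._make(self.data / o.data, (self, o), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        o = self._lift(other)
        out_data = self.data @ o.data

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g @ np.swapaxes(o.data, -1, -2), self.shape)
            if o.requires_grad:
                o.grad += _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, o.shape)

        return self._make(out_data, (self, o), bw)

    # -- shape ops ---------------------------------------------------------

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        return self._make(self.data.transpose(axes), (self,), bw)

    @property
    def T(self):
        return self.transpose()

    def reshape(self, *shape):
        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(self.shape)

        return self._make(self.data.reshape(shape), (self,), bw)

    def gather_rows(self, idx: np.ndarray):
        """out[...] = self[idx, :] with scatter-add on the way back."""
        idx = np.asarray(idx, dtype=int)

        def bw(g):
            if self.requires_grad:
                np.add.at(self.grad, idx.reshape(-1), g.reshape(-1, g.shape[-1]))

        return self._make(self.data[idx], (self,), bw)

    def take_column(self, idx: np.ndarray):
        """Per-row element selection: out[i] = self[i, idx[i]]."""
        idx = np.asarray(idx, dtype=int)
        rows = np.arange(self.shape[0])

        def bw(g):
            if self.requires_grad:
                np.add.at(self.grad, (rows, idx), g)

        return self._make(self.data[rows, idx], (self,), bw)

    # -- elementwise -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self.grad += g * out_data

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self.grad += g / self.data

        return self._make(np.log(self.data), (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self.grad += g * mask

        return self._make(self.data * mask, (self,), bw)

    def power(self, p: float):
        def bw(g):
            if self.requires_grad:
                self.grad += g * p * self.data ** (p - 1)

        return self._make(self.data**p, (self,), bw)

    def sqrt(self):
        return self.power(0.5)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self.grad += np.broadcast_to(gg, self.shape)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- composed layers ---------------------------------------------------

    def softmax(self, axis: int = -1):
        shift = self - np.max(self.data, axis=axis, keepdims=True)
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + eps).sqrt() * gamma + beta

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        if not training or p <= 0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)
        return self * mask


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t.grad += piece

        out._backward = bw
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a matrix (used for per-head outputs)."""
    out = Tensor(np.stack([t.data for t in tensors]))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t.grad += g[i]

        out._backward = bw
    return out


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
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
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
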