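"""Minimal reverse-mode autodiff over numpy arrays.

The segmentation network needs exactly one batch layout — a single volume
of shape (C, D, H, W) in float32 — so this engine stays deliberately
small: a :class:`Tensor` wraps an ndarray, records its parents and a
backward closure, and :meth:`Tensor.backward` runs the tape in reverse
topological order.  All heavy ops (convolutions, resampling) live in
:mod:`vesseg.nn.functional` and register their own gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "add", "mul_scalar", "concat_channels", "pad_kernel", "make_op"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        # iterative DFS topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.accumulate(grad)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate gradients/graph as we go
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def make_op(data: np.ndarray, parents: tuple, backward) -> Tensor:
    """Wrap an op result; ``backward(grad)`` must call parent.accumulate."""
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")

    def backward(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return make_op(a.data + b.data, (a, b), backward)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a.accumulate(g * s)

    return make_op(a.data * s, (a,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel (first) axis."""
    ca = a.data.shape[0]

    def backward(g):
        if a.requires_grad:
            a.accumulate(g[:ca])
        if b.requires_grad:
            b.accumulate(g[ca:])

    return make_op(np.concatenate([a.data, b.data], axis=0), (a, b), backward)


def pad_kernel(w: Tensor, target_k: int) -> Tensor:
    """Zero-pad a (Co, Ci, k, k, k) kernel symmetrically to target_k per axis."""
    k = w.data.shape[-1]
    if (target_k - k) % 2:
        raise ValueError("kernel padding must be symmetric (same parity)")
    p = (target_k - k) // 2
    if p == 0:
        return w
    pads = ((0, 0), (0, 0), (p, p), (p, p), (p, p))
    sl = (slice(None), slice(None)) + (slice(p, p + k),) * 3

    def backward(g):
        if w.requires_grad:
            w.accumulate(g[sl])

    return make_op(np.pad(w.data, pads), (w,), backward)
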