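"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small (~10k parameters, 1-D signals), so a
compact tape-based engine is sufficient: each :class:`Tensor` records the
operation that produced it and a closure that propagates the upstream
gradient to its parents.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the original shape.

Only float64 is used during training; there is no device abstraction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._from_op(self.data**e, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g
                if not keepdims:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    ax = tuple(i % a.ndim for i in ax)
                    gg = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._from_op(self.data[idx], (self,), backward)

    def pad_last(self, before: int, after: int):
        """Zero-pad along the final axis."""
        width = [(0, 0)] * (self.ndim - 1) + [(before, after)]
        L = self.shape[-1]

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g[..., before:before + L])

        return Tensor._from_op(np.pad(self.data, width), (self,), backward)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------------
    def elu(self, alpha: float = 1.0):
        x = self.data
        neg = alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
        out_data = np.where(x > 0, x, neg)

        def backward(g, a=self, neg=neg):
            if a.requires_grad:
                a._accum(g * np.where(a.data > 0, 1.0, neg + alpha))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._from_op(s, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- convolution ----------------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               padding: int = 0):
        """Cross-correlate a batch of 1-D feature maps.

        self: [B, C, L]; weight: [O, C, K]; bias: [O]; stride 1.
        """
        w = self._wrap(weight)
        B, C, L = self.shape
        O, Cw, K = w.shape
        if Cw != C:
            raise ValueError(f"conv1d channel mismatch: input {C}, weight {Cw}")
        xp = np.pad(self.data, ((0, 0), (0, 0), (padding, padding)))
        Lout = L + 2 * padding - K + 1
        if Lout < 1:
            raise ValueError("conv1d: kernel longer than padded input")
        # cols: [B, C, K, Lout] via sliding windows
        win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # [B,C,Lout,K]
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, C * K, Lout)
        out_data = np.einsum("ok,bkl->bol", w.data.reshape(O, C * K), cols,
                             optimize=True)
        parents = [self, w]
        if bias is not None:
            out_data = out_data + bias.data[None, :, None]
            parents.append(bias)

        def backward(g, a=self, w=w, bias=bias, cols=cols):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.einsum("bol,bkl->ok", g, cols, optimize=True)
                w._accum(gw.reshape(O, C, K))
            if a.requires_grad:
                gcols = np.einsum("ok,bol->bkl", w.data.reshape(O, C * K), g,
                                  optimize=True).reshape(B, C, K, Lout)
                gx = np.zeros((B, C, L + 2 * padding))
                for k in range(K):
                    gx[:, :, k:k + Lout] += gcols[:, :, k, :]
                a._accum(gx[:, :, padding:padding + L] if padding else gx)

        return Tensor._from_op(out_data, parents, backward)

    def dilate_last(self, stride: int):
        """Insert stride-1 zeros between samples along the final axis."""
        if stride == 1:
            return self
        L = self.shape[-1]
        out_shape = self.shape[:-1] + ((L - 1) * stride + 1,)
        out_data = np.zeros(out_shape)
        out_data[..., ::stride] = self.data

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g[..., ::stride])

        return Tensor._from_op(out_data, (self,), backward)

    def flip_last(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g[..., ::-1])

        return Tensor._from_op(self.data[..., ::-1].copy(), (self,), backward)

    # -- backprop -------------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis` (differentiable)."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._from_op(data, tensors, backward)
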