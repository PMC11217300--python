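"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operator set needed by the detection,
labelling and grading networks in this package: broadcasting arithmetic,
matmul, pointwise nonlinearities, reductions, indexing, 2-D convolution
(via im2col), nearest-neighbour upsampling and row gathers for embedding
tables.  Gradients are accumulated by a topological backward sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
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

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1.0),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            if b.data.ndim == 1:
                ga = np.outer(g, b.data) if a.data.ndim == 2 else g[..., None] * b.data
                gb = a.data.T @ g if a.data.ndim == 2 else (a.data * g[..., None]).sum(
                    axis=tuple(range(a.data.ndim - 1))
                )
            elif a.data.ndim == 1:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.outer(a.data, g)
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return Tensor._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data ** 2),)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            return (g * sign,)

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            expanded = out_data
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                expanded = np.expand_dims(out_data, axis)
            mask = self.data == expanded
            # split gradient among ties (ties are measure-zero in practice)
            mask = mask / mask.sum(axis=axis, keepdims=True)
            return (mask * g,)

        return Tensor._make(out_data, (self,), backward)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            return (g.reshape(old),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    def take_rows(self, indices: np.ndarray):
        """Gather rows of a 2-D table (embedding lookup)."""
        indices = np.asarray(indices, dtype=np.intp)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, indices, g)
            return (full,)

        return Tensor._make(self.data[indices], (self,), backward)

    # -- composed helpers -----------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    # -- convolution / resampling primitives ----------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution; self (N,C,H,W), weight (Cout,Cin,k,k)."""
        x, w = self, weight
        n, c, h, wd = x.data.shape
        cout, cin, kh, kw = w.data.shape
        assert cin == c, "channel mismatch"
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        ho = (h + 2 * padding - kh) // stride + 1
        wo = (wd + 2 * padding - kw) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]            # (N,C,Ho,Wo,kh,kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
        wmat = w.data.reshape(cout, c * kh * kw)
        out_data = cols @ wmat.T                        # (N,L,Cout)
        if bias is not None:
            out_data = out_data + bias.data
        out_data = out_data.transpose(0, 2, 1).reshape(n, cout, ho, wo)

        def backward(g):
            gl = g.reshape(n, cout, ho * wo).transpose(0, 2, 1)   # (N,L,Cout)
            gw = np.einsum("nlo,nlc->oc", gl, cols).reshape(w.data.shape)
            gcols = gl @ wmat
            gcols = gcols.reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    gxp[:, :, di:di + ho * stride:stride, dj:dj + wo * stride:stride] += \
                        gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
            gx = gxp[:, :, padding:padding + h, padding:padding + wd] if padding else gxp
            grads = [gx, gw]
            if bias is not None:
                grads.append(gl.sum(axis=(0, 1)))
            return tuple(grads)

        parents = (x, w) if bias is None else (x, w, bias)
        return Tensor._make(out_data, parents, backward)

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling of (N,C,H,W)."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            n, c, h2, w2 = g.shape
            return (g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)),)

        return Tensor._make(out_data, (self,), backward)

    # -- backward sweep -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order with children before parents
        order: list[Tensor] = []
        perm_seen: set[int] = set()

        def visit(node: Tensor):
            st = [(node, False)]
            while st:
                cur, done = st.pop()
                if done:
                    order.append(cur)
                    continue
                if id(cur) in perm_seen or not cur.requires_grad:
                    continue
                perm_seen.add(id(cur))
                st.append((cur, True))
                for p in cur._parents:
                    st.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += pgrad


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    out_data = np.concatenate(datas, axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        moved = np.moveaxis(g, axis, 0)
        return tuple(moved[i] for i in range(len(tensors)))

    return Tensor._make(out_data, tuple(tensors), backward)
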