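"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's encoder/decoder networks
need: broadcast arithmetic, matmul, strided 1-D convolution (via im2col),
nearest-neighbour upsampling, pointwise nonlinearities, reductions, and
two fused classification losses. All tensors are float32.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

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

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.reciprocal()
        return self * (1.0 / float(other))

    def reciprocal(self):
        inv = 1.0 / self.data
        return Tensor._make(inv, (self,), lambda g: (-g * inv * inv,))

    def __pow__(self, p: float):
        d = self.data

        def backward(g):
            return (g * p * np.power(d, p - 1),)

        return Tensor._make(np.power(d, p), (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._make(t, (self,), lambda g: (g * (1 - t * t),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * s * (1 - s),))

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(*axes), (self,), lambda g: (g.transpose(*inv),)
        )

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    def amax(self, axis: int):
        """Maximum along one axis; gradient flows to the argmax element."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis)

        def backward(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(
                full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
            )
            return (full,)

        return Tensor._make(out, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).astype(_DTYPE),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).astype(_DTYPE),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(node: Tensor):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            # leaves with _backward do not exist; interior grads are transient
        # any remaining entries are leaves reached directly
        for node in topo:
            g = grads.pop(id(node), None)
            if g is not None and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g


# -- structured ops -----------------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """1-D convolution. x: (B, C, L), w: (O, C, K), b: (O,) -> (B, O, Lout)."""
    B, C, L = x.shape
    O, Cw, K = w.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    Lp = xp.shape[2]
    Lout = (Lp - K) // stride + 1
    idx = np.arange(K)[:, None] + stride * np.arange(Lout)[None, :]
    cols = xp[:, :, idx]                      # (B, C, K, Lout)
    cols2 = cols.reshape(B, C * K, Lout)
    out = np.einsum("of,bfl->bol", w.data.reshape(O, C * K), cols2, optimize=True)
    out = out + b.data[None, :, None]

    def backward(g):                          # g: (B, O, Lout)
        gw = np.einsum("bol,bfl->of", g, cols2, optimize=True).reshape(O, C, K)
        gb = g.sum(axis=(0, 2))
        gcols = np.einsum("of,bol->bfl", w.data.reshape(O, C * K), g, optimize=True)
        gcols = gcols.reshape(B, C, K, Lout)
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, :, k : k + stride * Lout : stride] += gcols[:, :, k, :]
        gx = gxp[:, :, padding : Lp - padding] if padding else gxp
        return gx, gw, gb

    return Tensor._make(out, (x, w, b), backward)


def upsample1d(x: Tensor, factor: int) -> Tensor:
    """Centred nearest-neighbour upsampling along the last axis.

    The repeated signal is advanced by (factor-1)//2 samples (edge
    replicated) so that upsampling is phase-centred with respect to
    strided downsampling, avoiding a cumulative temporal shift across
    encoder/decoder stages.
    """
    B, C, L = x.shape
    shift = (factor - 1) // 2
    rep = np.repeat(x.data, factor, axis=2)
    if shift:
        out = np.concatenate(
            [rep[:, :, shift:], np.repeat(rep[:, :, -1:], shift, axis=2)], axis=2
        )
    else:
        out = rep

    def backward(g):
        grep = np.zeros_like(rep)
        if shift:
            grep[:, :, shift:] = g[:, :, : rep.shape[2] - shift]
            grep[:, :, -1] += g[:, :, rep.shape[2] - shift :].sum(axis=2)
        else:
            grep = g
        return (grep.reshape(B, C, L, factor).sum(axis=3),)

    return Tensor._make(out, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._make(out, tuple(tensors), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean multinomial cross-entropy. logits: (B, K), labels: int (B,)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    B = z.shape[0]
    nll = -(np.log(p[np.arange(B), labels] + 1e-12)).mean()

    def backward(g):
        grad = p.copy()
        grad[np.arange(B), labels] -= 1.0
        return (g * grad / B,)

    return Tensor._make(nll, (logits,), backward)


def sigmoid_bce(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean multi-label binary cross-entropy with logits. Shapes (B, K)."""
    z = logits.data
    t = np.asarray(targets, dtype=_DTYPE)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-z))
        return (g * (s - t) / z.size,)

    return Tensor._make(loss.mean(), (logits,), backward)
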