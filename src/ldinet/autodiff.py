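"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network in this package is small (tens of thousands of parameters at the
tiny profile), so a tape-based engine over float64 ndarrays is both fast
enough and easy to verify with finite differences.  Only the operations the
model needs are implemented: broadcast arithmetic, (batched) matmul, reshapes,
softmax, layer norm, GELU, sigmoid, binary cross-entropy with logits, a
same-padded 2-D convolution over token grids, and dropout.

Gradients for broadcast operations are reduced back to the parent shape with
:func:`_unbroadcast`; batched matmul sums gradients over broadcast batch axes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "AdamW"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor.as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))
        a, b = self.data, other.data

        def backward(g):
            if b.ndim == 1:
                ga = g[..., None] * b if a.ndim > 1 else g * b
                gb = np.einsum("...mk,...m->k", a, g) if a.ndim > 1 else a * g
                return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
            ga = g @ np.swapaxes(b, -1, -2)
            if a.ndim == 1:
                gb = np.einsum("k,...n->...kn", a, g)
            else:
                gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._backward = lambda g: (g.reshape(src),)
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), (self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def broadcast_to(self, shape) -> "Tensor":
        src = self.shape
        out = Tensor(np.broadcast_to(self.data, shape).copy(), (self,))
        out._backward = lambda g: (_unbroadcast(g, src),)
        return out

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        src = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, src).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, src).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ------------------------------------------------------- nonlinearities
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def gelu(self) -> "Tensor":
        """Exact (erf-based) GELU."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        out = Tensor(x * phi, (self,))
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        out._backward = lambda g: (g * (phi + x * pdf),)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, (self,))

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        out._backward = backward
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-6) -> "Tensor":
        """Normalize over the last axis, then scale/shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = Tensor(xhat * gamma.data + beta.data, (self, gamma, beta))

        def backward(g):
            ggamma = _unbroadcast(g * xhat, gamma.shape)
            gbeta = _unbroadcast(g, beta.shape)
            gx_hat = g * gamma.data
            gx = inv * (
                gx_hat
                - gx_hat.mean(axis=-1, keepdims=True)
                - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
            )
            return (gx, ggamma, gbeta)

        out._backward = backward
        return out

    def dropout(self, rate: float, rng: np.random.Generator, training: bool) -> "Tensor":
        if not training or rate <= 0.0:
            return self
        keep = 1.0 - rate
        mask = (rng.random(self.shape) < keep) / keep
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    def conv2d_same(self, weight: "Tensor", bias: "Tensor", kernel: int) -> "Tensor":
        """Same-padded kernel×kernel conv on a (B, h, w, C) grid.

        `weight` has shape (kernel*kernel*C, C_out); implemented as im2col
        followed by a single matmul so the backward pass is a scatter-add.
        """
        x = self.data
        b_, h, w, c = x.shape
        p = kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((b_, h, w, kernel * kernel, c))
        for i in range(kernel):
            for j in range(kernel):
                cols[:, :, :, i * kernel + j, :] = xp[:, i : i + h, j : j + w, :]
        cols2 = cols.reshape(b_, h, w, kernel * kernel * c)
        y = cols2 @ weight.data + bias.data
        out = Tensor(y, (self, weight, bias))

        def backward(g):
            gw = np.einsum("bhwk,bhwo->ko", cols2, g)
            gb = g.sum(axis=(0, 1, 2))
            gcols = (g @ weight.data.T).reshape(b_, h, w, kernel * kernel, c)
            gxp = np.zeros_like(xp)
            for i in range(kernel):
                for j in range(kernel):
                    gxp[:, i : i + h, j : j + w, :] += gcols[:, :, :, i * kernel + j, :]
            gx = gxp[:, p : p + h, p : p + w, :]
            return (gx, gw, gb)

        out._backward = backward
        return out

    def bce_with_logits(self, target: np.ndarray) -> "Tensor":
        """Mean binary cross-entropy between sigmoid(self) and binary targets.

        Uses the softplus form log(1+exp(-|z|)) + max(z,0) - z*t, which is
        numerically stable for large |z|.
        """
        t = np.asarray(target, dtype=np.float64)
        z = self.data
        loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
        out = Tensor(loss.mean(), (self,))
        n = z.size
        s = 1.0 / (1.0 + np.exp(-z))
        out._backward = lambda g: (g * (s - t) / n,)
        return out

    # --------------------------------------------------------------- engine
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep; accumulates into `.grad` of every ancestor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))

        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad = parent.grad + g


class Parameter(Tensor):
    """A leaf tensor that the optimizer updates."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class AdamW:
    """AdamW with decoupled weight decay over a dict of named Parameters."""

    def __init__(self, params: dict[str, Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
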