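"""Minimal reverse-mode automatic differentiation on numpy arrays.

The neural GRN models in this package are small (hundreds to a few thousand
parameters) and bias-free, so a compact tape-based engine is sufficient: it
supports the handful of operations the models use (matmul, elementwise
arithmetic, ReLU, tanh, Softplus, reductions) with numpy broadcasting, and an
Adam optimizer with L2 weight decay applied to the gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "mse"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entry needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "retain_grad",
                 "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.retain_grad = False
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._from_op(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return self._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return self._from_op(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        return self._from_op(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    # -- activations ----------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        t = np.tanh(self.data)
        return self._from_op(t, (self,), lambda g: (g * (1.0 - t * t),))

    def softplus(self):
        # log(1 + e^x); linear for large x to avoid overflow
        x = self.data
        out = np.where(x > 30.0, x, np.log1p(np.exp(np.minimum(x, 30.0))))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))
        return self._from_op(out, (self,), lambda g: (g * sig,))

    # -- reductions -----------------------------------------------------------
    def sum(self):
        return self._from_op(
            self.data.sum(), (self,), lambda g: (np.full(self.shape, g),)
        )

    def mean(self):
        n = self.data.size
        return self._from_op(
            self.data.mean(), (self,), lambda g: (np.full(self.shape, g / n),)
        )

    # -- backward -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor"):
            stack = [(node, iter(node._parents))]
            if id(node) in seen:
                return
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for parent in it:
                    if parent.requires_grad and id(parent) not in seen:
                        seen.add(id(parent))
                        stack.append((parent, iter(parent._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node.retain_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def mse(pred: Tensor, target) -> Tensor:
    """Mean squared error, averaged over every entry."""
    diff = pred - Tensor._lift(target)
    return (diff * diff).mean()


class Adam:
    """Adam with L2 weight decay added to the gradient (torch semantics)."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1 ** self._t)
            v_hat = self._v[i] / (1 - b2 ** self._t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
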