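"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports the handful of operations needed by the adversarial sequence
models in this package: dense layers, elementwise nonlinearities,
reductions and broadcasting. Every vector-Jacobian product is itself
expressed in terms of traced tensor operations, so gradients are
differentiable again — second-order gradients (as required by a critic
gradient penalty) come for free by calling :func:`grad` on the output of
a previous :func:`grad`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Vjp = Callable[["Tensor"], "Tensor"]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "parents", "requires_grad")
    __array_priority__ = 100  # our operators win over numpy's

    def __init__(
        self,
        data,
        parents: Sequence[tuple["Tensor", Vjp]] = (),
        requires_grad: bool = False,
    ) -> None:
        self.data = np.asarray(data, dtype=float)
        self.parents = tuple(
            (p, fn) for p, fn in parents if p.requires_grad
        )
        self.requires_grad = requires_grad or bool(self.parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        return Tensor(
            self.data + other.data,
            [
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        return Tensor(
            self.data * other.data,
            [
                (self, lambda g: _unbroadcast(g * other, self.shape)),
                (other, lambda g: _unbroadcast(g * self, other.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return _wrap(other) * self**-1.0

    def __pow__(self, p: float):
        out = Tensor(
            self.data**p,
            [(self, lambda g: g * (p * self ** (p - 1.0)))],
        )
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        return Tensor(
            self.data @ other.data,
            [
                (self, lambda g: g @ other.T),
                (other, lambda g: self.T @ g),
            ],
        )

    @property
    def T(self) -> "Tensor":
        return Tensor(self.data.T, [(self, lambda g: g.T)])

    # -- reductions / shape -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.shape

        def vjp(g: "Tensor") -> "Tensor":
            gd = g
            if axis is not None and not keepdims:
                gd = gd.reshape(_keepdims_shape(shape, axis))
            return gd.broadcast_to(shape)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), [(self, vjp)])

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in _normalize_axes(axis, self.data.ndim)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def reshape(self, shape) -> "Tensor":
        old = self.shape
        return Tensor(self.data.reshape(shape), [(self, lambda g: g.reshape(old))])

    def broadcast_to(self, shape) -> "Tensor":
        old = self.shape
        return Tensor(
            np.broadcast_to(self.data, shape),
            [(self, lambda g: _unbroadcast(g, old))],
        )

    # -- nonlinearities -----------------------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), [(self, lambda g: g * out)])
        return out

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data), [(self, lambda g: g / self)])

    def sqrt(self) -> "Tensor":
        return self**0.5

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), [(self, lambda g: g * (1.0 - out * out))])
        return out

    def sigmoid(self) -> "Tensor":
        out = Tensor(
            _sigmoid(self.data), [(self, lambda g: g * out * (1.0 - out))]
        )
        return out

    def softplus(self) -> "Tensor":
        # numerically stable forward; d/dx softplus = sigmoid
        data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        return Tensor(data, [(self, lambda g: g * self.sigmoid())])

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = Tensor(np.where(self.data > 0, 1.0, slope))
        return self * mask

    def softmax(self, axis: int = -1) -> "Tensor":
        # composed from primitives so all higher-order derivatives are exact;
        # the max shift is a constant and drops out of the gradient
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _normalize_axes(axis, ndim: int) -> tuple[int, ...]:
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def _keepdims_shape(shape: tuple[int, ...], axis) -> tuple[int, ...]:
    axes = _normalize_axes(axis, len(shape))
    return tuple(1 if i in axes else s for i, s in enumerate(shape))


def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = len(g.shape) - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(
        i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1
    )
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    grad_output: Tensor | None = None,
) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    The returned tensors carry their own computation graphs, so calling
    :func:`grad` on (functions of) them yields higher-order derivatives.
    """
    inputs = list(inputs)
    if grad_output is None:
        if output.data.size != 1:
            raise ValueError("output must be scalar unless grad_output is given")
        grad_output = Tensor(np.ones_like(output.data))

    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))

    grads: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None:
            continue
        for parent, vjp in node.parents:
            contrib = vjp(g)
            prev = grads.get(id(parent))
            grads[id(parent)] = contrib if prev is None else prev + contrib
    return [
        grads.get(id(x), Tensor(np.zeros_like(x.data))) for x in inputs
    ]


class Adam:
    """Adam optimizer updating parameter tensors in place."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.5, 0.9),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: Sequence[Tensor]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * gd
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * gd**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
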