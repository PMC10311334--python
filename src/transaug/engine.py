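"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports double backpropagation: the backward pass of every operation is
itself expressed with :class:`Tensor` operations, so gradients carry a
computation graph and can be differentiated again.  This is what the
WGAN-GP gradient penalty needs (a loss built from the gradient of the
critic with respect to its input).

Only the small set of operations used by the generative models lives
here; the arrays are float64 and sized for desk-scale experiments.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "grad",
    "concat_cols",
    "gather_cols",
    "scatter_add_cols",
    "take",
    "scatter_add_1d",
    "Linear",
    "MLP",
    "Adam",
]


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "requires_grad", "grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in _parents
        )
        self._parents = tuple(_parents) if self.requires_grad else ()
        self.grad: Tensor | None = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # tapes hold closures; checkpoints keep values only
    def __getstate__(self):
        return {"data": self.data, "requires_grad": self.requires_grad}

    def __setstate__(self, state):
        self.data = state["data"]
        self.requires_grad = state["requires_grad"]
        self._parents = ()
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data + other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data * other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g * other, self.shape)),
                (other, lambda g: _unbroadcast(g * self, other.shape)),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        e = float(exponent)
        out = Tensor(
            self.data ** e,
            _parents=((self, lambda g: g * (e * self ** (e - 1.0))),),
        )
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            _parents=(
                (self, lambda g: g @ other.T),
                (other, lambda g: self.T @ g),
            ),
        )
        return out

    @property
    def T(self) -> "Tensor":
        return Tensor(self.data.T, _parents=((self, lambda g: g.T),))

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        in_shape = self.shape

        def _bw(g: "Tensor") -> "Tensor":
            gd = g
            if axis is not None and not keepdims:
                gd = gd.reshape(_keepdims_shape(in_shape, axis))
            return gd.broadcast_to(in_shape)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=((self, _bw),))

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in _normalize_axes(axis, self.ndim)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def reshape(self, shape) -> "Tensor":
        in_shape = self.shape
        return Tensor(
            self.data.reshape(shape), _parents=((self, lambda g: g.reshape(in_shape)),)
        )

    def broadcast_to(self, shape) -> "Tensor":
        in_shape = self.shape
        return Tensor(
            np.broadcast_to(self.data, shape),
            _parents=((self, lambda g: _unbroadcast(g, in_shape)),),
        )

    # -- nonlinearities -------------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=((self, lambda g: g * out),))
        return out

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data), _parents=((self, lambda g: g * self ** -1.0),))

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def abs(self) -> "Tensor":
        sign = Tensor(np.sign(self.data))
        return Tensor(np.abs(self.data), _parents=((self, lambda g: g * sign),))

    def relu(self) -> "Tensor":
        mask = Tensor((self.data > 0).astype(np.float64))
        return Tensor(self.data * mask.data, _parents=((self, lambda g: g * mask),))

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = Tensor(np.where(self.data > 0, 1.0, slope))
        return Tensor(self.data * factor.data, _parents=((self, lambda g: g * factor),))

    def sigmoid(self) -> "Tensor":
        out = Tensor(
            0.5 * (np.tanh(0.5 * self.data) + 1.0),
            _parents=((self, lambda g: g * out * (1.0 - out)),),
        )
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(
            np.tanh(self.data), _parents=((self, lambda g: g * (1.0 - out * out)),)
        )
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = Tensor(((self.data >= lo) & (self.data <= hi)).astype(np.float64))
        return Tensor(
            np.clip(self.data, lo, hi), _parents=((self, lambda g: g * mask),)
        )

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        n_cols = self.shape[1]
        idx = np.arange(start, stop)
        return Tensor(
            self.data[:, start:stop],
            _parents=((self, lambda g: scatter_add_cols(g, idx, n_cols)),),
        )

    # ------------------------------------------------------------------
    def backward(self, seed=None) -> None:
        """Populate ``.grad`` on every tensor reachable from ``self``."""
        seed_t = Tensor(np.ones_like(self.data)) if seed is None else _as_tensor(seed)
        grads = _backward_pass(self, seed_t)
        for t, g in grads.items():
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g

    def zero_grad(self) -> None:
        self.grad = None


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _normalize_axes(axis, ndim):
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def _keepdims_shape(shape, axis):
    axes = _normalize_axes(axis, len(shape))
    return tuple(1 if i in axes else s for i, s in enumerate(shape))


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ts) in enumerate(zip(g.shape, shape)):
        if ts == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    if g.shape != tuple(shape):
        g = g.reshape(shape)
    return g


# ----------------------------------------------------------------------
# column gather/scatter — the adjoint pair behind sparse attention
# ----------------------------------------------------------------------


def gather_cols(t: Tensor, idx: np.ndarray) -> Tensor:
    """``t[:, idx]`` for a 2-D tensor; backward scatter-adds duplicates."""
    idx = np.asarray(idx, dtype=np.intp)
    n_cols = t.shape[1]
    return Tensor(
        t.data[:, idx], _parents=((t, lambda g: scatter_add_cols(g, idx, n_cols)),)
    )


def scatter_add_cols(t: Tensor, idx: np.ndarray, n_cols: int) -> Tensor:
    """Column scatter-add: ``out[:, idx[p]] += t[:, p]``."""
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros((t.shape[0], n_cols), dtype=np.float64)
    np.add.at(out, (slice(None), idx), t.data)
    return Tensor(out, _parents=((t, lambda g: gather_cols(g, idx)),))


def take(t: Tensor, idx: np.ndarray) -> Tensor:
    """1-D gather ``t[idx]``; backward scatter-adds into the source."""
    idx = np.asarray(idx, dtype=np.intp)
    n = t.shape[0]
    return Tensor(t.data[idx], _parents=((t, lambda g: scatter_add_1d(g, idx, n)),))


def scatter_add_1d(t: Tensor, idx: np.ndarray, n: int) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros(n, dtype=np.float64)
    np.add.at(out, idx, t.data)
    return Tensor(out, _parents=((t, lambda g: take(g, idx)),))


def concat_cols(tensors: Sequence[Tensor]) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    widths = [t.shape[1] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(widths)])
    parents = []
    for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
        parents.append((t, (lambda a=a, b=b: (lambda g: g.slice_cols(int(a), int(b))))()))
    return Tensor(np.concatenate([t.data for t in tensors], axis=1), _parents=parents)


# ----------------------------------------------------------------------
# backward engine
# ----------------------------------------------------------------------


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order


def _backward_pass(root: Tensor, seed: Tensor) -> dict[Tensor, Tensor]:
    grads: dict[int, Tensor] = {id(root): seed}
    by_id: dict[int, Tensor] = {id(root): root}
    out: dict[Tensor, Tensor] = {}
    for node in reversed(_toposort(root)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        out[node] = g
        for parent, fn in node._parents:
            contrib = fn(g)
            pid = id(parent)
            if pid in grads:
                grads[pid] = grads[pid] + contrib
            else:
                grads[pid] = contrib
                by_id[pid] = parent
    return out


def grad(output: Tensor, inputs: Iterable[Tensor]) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    The returned tensors keep their own tape, so expressions built from
    them can be backpropagated again (double backprop).
    """
    grads = _backward_pass(output, Tensor(np.ones_like(output.data)))
    result = []
    for t in inputs:
        g = grads.get(t)
        result.append(g if g is not None else Tensor(np.zeros_like(t.data)))
    return result


# ----------------------------------------------------------------------
# layers and optimizer
# ----------------------------------------------------------------------


class Linear:
    """Affine layer with He-scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Fully connected stack with a configurable output activation."""

    def __init__(
        self,
        n_in: int,
        hidden: Sequence[int],
        n_out: int,
        rng: np.random.Generator,
        activation: str = "relu",
        out_activation: str | None = None,
    ):
        dims = [n_in, *hidden, n_out]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activation = activation
        self.out_activation = out_activation

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers[:-1]:
            h = layer(h)
            h = h.relu() if self.activation == "relu" else h.leaky_relu()
        h = self.layers[-1](h)
        if self.out_activation == "sigmoid":
            h = h.sigmoid()
        elif self.out_activation == "tanh":
            h = h.tanh()
        return h

    @property
    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters]


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
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
            g = p.grad.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
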