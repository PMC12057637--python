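"""Minimal reverse-mode automatic differentiation over numpy arrays.

The energy model needs exact gradients twice over: forces are gradients of
the energy with respect to coordinates, and force-matching training needs
gradients of those forces with respect to the model parameters.  Every
primitive therefore defines its vector-Jacobian product *in terms of other
primitives*, so the backward pass builds a differentiable graph and
``grad`` can be nested to arbitrary order.

Only the operations the potential actually uses are provided.  All math is
float64.  Constants (plain numbers / ndarrays) are wrapped on the fly and
receive no gradient.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "tensor", "grad", "concatenate", "einsum", "matmul",
           "where_mask", "gather", "scatter_add", "erfc", "softplus",
           "sigmoid", "logsumexp_stable"]


class Tensor:
    """Node in the computation graph: an ndarray plus parent edges."""

    __slots__ = ("data", "_parents", "requires_grad")
    __array_priority__ = 100  # beat ndarray in mixed binary ops

    def __init__(self, data, parents=(), requires_grad=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self._parents = tuple(parents)  # ((Tensor, vjp_fn), ...)
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p, _ in parents)
        self.requires_grad = bool(requires_grad)

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


def tensor(x, requires_grad=False, dtype=None) -> Tensor:
    x = np.asarray(x)
    if dtype is not None:
        x = x.astype(dtype)
    return Tensor(x, requires_grad=requires_grad)


# ---------------------------------------------------------------------------
# broadcasting helper
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if g.shape == shape:
        return g
    # sum leading added axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    # sum axes that were 1 in the original
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _pair(a, b):
    """Wrap operands, keeping python-scalar constants at the array dtype."""
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(a, (int, float)) and isinstance(b, Tensor):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    return astensor(a), astensor(b)


def add(a, b) -> Tensor:
    a, b = _pair(a, b)
    return Tensor(a.data + b.data,
                  parents=((a, lambda g: _unbroadcast(g, a.shape)),
                           (b, lambda g: _unbroadcast(g, b.shape))))


def mul(a, b) -> Tensor:
    a, b = _pair(a, b)
    return Tensor(a.data * b.data,
                  parents=((a, lambda g: _unbroadcast(mul(g, b), a.shape)),
                           (b, lambda g: _unbroadcast(mul(g, a), b.shape))))


def power(a, p: float) -> Tensor:
    a = astensor(a)
    p = float(p)
    out = Tensor(a.data ** p,
                 parents=((a, lambda g: mul(g, mul(p, power(a, p - 1.0)))),))
    return out


def exp(a) -> Tensor:
    a = astensor(a)
    out = Tensor(np.exp(a.data))
    out._parents = ((a, lambda g: mul(g, out)),)
    out.requires_grad = a.requires_grad
    return out


def log(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.log(a.data), parents=((a, lambda g: mul(g, power(a, -1.0))),))


def sqrt(a) -> Tensor:
    a = astensor(a)
    out = Tensor(np.sqrt(a.data))
    out._parents = ((a, lambda g: mul(g, mul(0.5, power(out, -1.0)))),)
    out.requires_grad = a.requires_grad
    return out


def cos(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.cos(a.data), parents=((a, lambda g: mul(g, mul(-1.0, sin(a)))),))


def sin(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.sin(a.data), parents=((a, lambda g: mul(g, cos(a))),))


def tanh(a) -> Tensor:
    a = astensor(a)
    out = Tensor(np.tanh(a.data))
    out._parents = ((a, lambda g: mul(g, add(1.0, mul(-1.0, mul(out, out))))),)
    out.requires_grad = a.requires_grad
    return out


_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


def erfc(a) -> Tensor:
    a = astensor(a)
    return Tensor(_sp.erfc(a.data),
                  parents=((a, lambda g: mul(g, mul(-_TWO_OVER_SQRT_PI,
                                                    exp(mul(-1.0, mul(a, a)))))),))


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out = Tensor(_sp.expit(a.data))
    out._parents = ((a, lambda g: mul(g, mul(out, add(1.0, mul(-1.0, out))))),)
    out.requires_grad = a.requires_grad
    return out


def softplus(a) -> Tensor:
    """log(1 + e^x), overflow-safe; derivative is the logistic function."""
    a = astensor(a)
    return Tensor(np.logaddexp(0.0, a.data),
                  parents=((a, lambda g: mul(g, sigmoid(a))),))


def logsumexp_stable(a) -> Tensor:  # pragma: no cover - convenience
    m = np.max(a.data)
    return add(log(sum_(exp(add(a, -m)))), m)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    data = np.sum(a.data, axis=axis, keepdims=keepdims)

    def vjp(g):
        gg = g
        if not keepdims and axis is not None:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % a.ndim for i in ax)
            shp = tuple(1 if i in ax else n for i, n in enumerate(a.shape))
            gg = reshape(gg, shp)
        elif not keepdims and axis is None:
            gg = reshape(gg, (1,) * a.ndim)
        return broadcast_to(gg, a.shape)

    return Tensor(data, parents=((a, vjp),))


def broadcast_to(a, shape) -> Tensor:
    a = astensor(a)
    return Tensor(np.broadcast_to(a.data, shape),
                  parents=((a, lambda g: _unbroadcast(g, a.shape)),))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return Tensor(a.data.reshape(shape),
                  parents=((a, lambda g: reshape(g, a.shape)),))


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    inv = tuple(np.argsort(axes))
    return Tensor(np.transpose(a.data, axes),
                  parents=((a, lambda g: transpose(g, inv)),))


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul primitive is 2-D only; use einsum for batches")
    return Tensor(a.data @ b.data,
                  parents=((a, lambda g: matmul(g, transpose(b, (1, 0)))),
                           (b, lambda g: matmul(transpose(a, (1, 0)), g))))


_EINSUM_PATHS: dict = {}


def _einsum_path(subscripts, sa, sb):
    key = (subscripts, sa, sb)
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(subscripts, np.empty(sa), np.empty(sb),
                              optimize="optimal")[0]
        _EINSUM_PATHS[key] = path
    return path


def einsum(subscripts: str, a, b) -> Tensor:
    """Two-operand einsum.

    Restriction (checked): no index repeats within one operand and every
    index of each operand appears in the output or in the other operand.
    Under that restriction the adjoint is itself an einsum.
    """
    a, b = astensor(a), astensor(b)
    lhs, out_sub = subscripts.split("->")
    a_sub, b_sub = lhs.split(",")
    for s in (a_sub, b_sub):
        if len(set(s)) != len(s):
            raise ValueError(f"repeated index within operand: {subscripts}")
    if not (set(a_sub) <= set(out_sub) | set(b_sub)
            and set(b_sub) <= set(out_sub) | set(a_sub)):
        raise ValueError(f"unsupported einsum for autodiff: {subscripts}")
    data = np.einsum(subscripts, a.data, b.data,
                     optimize=_einsum_path(subscripts, a.shape, b.shape))

    def vjp_a(g):
        return einsum(f"{out_sub},{b_sub}->{a_sub}", g, b)

    def vjp_b(g):
        return einsum(f"{out_sub},{a_sub}->{b_sub}", g, a)

    return Tensor(data, parents=((a, vjp_a), (b, vjp_b)))


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        n = t.shape[axis]
        idx = [slice(None)] * data.ndim
        idx[axis] = slice(start, start + n)
        idx = tuple(idx)
        parents.append((t, (lambda ix: lambda g: getitem(g, ix))(idx)))
        start += n
    return Tensor(data, parents=parents)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    return Tensor(a.data[idx],
                  parents=((a, lambda g: scatter_add(a.shape, idx, g)),))


def scatter_add(shape, idx, values) -> Tensor:
    """Zeros of ``shape`` with ``values`` added at ``idx`` (adjoint of getitem)."""
    values = astensor(values)
    data = np.zeros(shape, dtype=values.data.dtype)
    np.add.at(data, idx, values.data)
    return Tensor(data, parents=((values, lambda g: getitem(g, idx)),))


def where_mask(mask: np.ndarray, a, b=0.0) -> Tensor:
    """Select by a *constant* boolean mask (no gradient through the mask)."""
    a, b = astensor(a), astensor(b)
    m = np.asarray(mask, dtype=np.float64)
    return add(mul(a, m), mul(b, 1.0 - m))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p, _ in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # children before parents


def grad(output: Tensor, wrt, seed=None):
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``wrt``.

    Returns Tensors, so the result can be differentiated again.  ``seed``
    optionally replaces the initial adjoint (defaults to ones).
    """
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    if not output.requires_grad:
        zeros = [Tensor(np.zeros(w.shape, dtype=w.data.dtype))
                 for w in wrt_list]
        return zeros[0] if single else zeros

    wrt_ids = {id(w) for w in wrt_list}
    adjoint = {id(output): astensor(seed) if seed is not None
               else Tensor(np.ones(output.shape, dtype=output.data.dtype))}
    for node in reversed(_toposort(output)):
        g = adjoint.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in node._parents:
            if not parent.requires_grad:
                continue
            pg = vjp(g)
            acc = adjoint.get(id(parent))
            adjoint[id(parent)] = pg if acc is None else add(acc, pg)
        if id(node) in wrt_ids:
            adjoint[id(node)] = g  # keep for readout
    out = []
    for w in wrt_list:
        g = adjoint.get(id(w))
        out.append(g if g is not None else Tensor(np.zeros(w.shape)))
    return out[0] if single else out
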