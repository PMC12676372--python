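"""Minimal reverse-mode automatic differentiation over numpy arrays.

The whole-volume gradient solver needs gradients of a scalar loss with
respect to every voxel's parameters at once.  This module provides a small
tape-based reverse-mode engine ("micro autograd") covering exactly the
operations the built-in forward models, loss functions and regularisers
use: elementwise arithmetic, exp/log/sigmoid, absolute value, reductions,
shape manipulation, fancy indexing, and unitary FFTs on complex arrays.

Complex support follows the packed-gradient convention used by mainstream
AD frameworks: for a real-valued loss ``L`` and a complex leaf
``z = x + iy``, ``z.grad`` holds ``dL/dx + i dL/dy`` (equivalently
``2 * conj(Wirtinger dL/dz)``), so that ``z - lr * z.grad`` is a steepest
descent step and real leaves reduce to ordinary gradients.  For a
complex-linear operator ``A`` the backward rule is the adjoint ``A^H``;
for a holomorphic elementwise ``f`` it is ``conj(f'(z)) * g``.

Functions here accept plain ndarrays as well as Tensors and fall back to
numpy when no Tensor is involved, so model code can be written once and
evaluated with or without gradient tracking.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "absolute",
    "concatenate",
    "conj",
    "exp",
    "expand_dims",
    "fftn",
    "grad",
    "ifftn",
    "imag",
    "log",
    "mean",
    "moveaxis",
    "real",
    "reshape",
    "sigmoid",
    "sqrt",
    "square",
    "sum",
]

_np_sum = np.sum


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


class Tensor:
    """An ndarray with a gradient tape node."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjps")

    # make ndarray <op> Tensor defer to our reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjps=()):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = _parents
        self._vjps = _vjps

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def detach(self) -> np.ndarray:
        return self.data

    # -- autograd -------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if np.iscomplexobj(self.data):
            g = np.asarray(g, dtype=complex)
        else:
            g = np.asarray(g).real
        g = _unbroadcast(np.broadcast_to(g, np.broadcast_shapes(g.shape, self.data.shape)), self.data.shape)
        if self.grad is None:
            self.grad = np.zeros(self.data.shape, dtype=g.dtype)
        self.grad = self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (real scalar) node to all leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss node")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data, dtype=float)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                parent._accumulate(vjp(node.grad))

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(other))

    def __rsub__(self, other):
        return add(neg(self), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __abs__(self):
        return absolute(self)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _node(value, parents_and_vjps):
    parents = tuple(p for p, _ in parents_and_vjps if isinstance(p, Tensor))
    vjps = tuple(v for p, v in parents_and_vjps if isinstance(p, Tensor))
    return Tensor(value, requires_grad=True, _parents=parents, _vjps=vjps)


# -- arithmetic ----------------------------------------------------------------

def add(a, b):
    if not _is_tensor(a, b):
        return np.add(a, b)
    av, bv = _data(a), _data(b)
    return _node(av + bv, [(a, lambda g: g), (b, lambda g: g)])


def neg(a):
    if not _is_tensor(a):
        return np.negative(a)
    return _node(-_data(a), [(a, lambda g: -g)])


def mul(a, b):
    if not _is_tensor(a, b):
        return np.multiply(a, b)
    av, bv = _data(a), _data(b)
    return _node(av * bv, [(a, lambda g: g * np.conj(bv)), (b, lambda g: g * np.conj(av))])


def div(a, b):
    if not _is_tensor(a, b):
        return np.divide(a, b)
    av, bv = _data(a), _data(b)
    return _node(
        av / bv,
        [
            (a, lambda g: g * np.conj(1.0 / bv)),
            (b, lambda g: g * np.conj(-av / (bv * bv))),
        ],
    )


def power(a, p):
    """Elementwise power with a constant real exponent."""
    if not _is_tensor(a):
        return np.power(a, p)
    av = _data(a)
    val = av**p
    return _node(val, [(a, lambda g: g * np.conj(p * av ** (p - 1)))])


def square(a):
    return mul(a, a)


def exp(a):
    if not _is_tensor(a):
        return np.exp(a)
    val = np.exp(_data(a))
    return _node(val, [(a, lambda g: g * np.conj(val))])


def log(a):
    if not _is_tensor(a):
        return np.log(a)
    av = _data(a)
    return _node(np.log(av), [(a, lambda g: g * np.conj(1.0 / av))])


def sqrt(a):
    return power(a, 0.5)


def sigmoid(a):
    """Logistic function; real inputs only (used by the bound transform)."""
    if not _is_tensor(a):
        return 1.0 / (1.0 + np.exp(-np.asarray(a, dtype=float)))
    s = 1.0 / (1.0 + np.exp(-_data(a)))
    return _node(s, [(a, lambda g: g * s * (1.0 - s))])


def absolute(a):
    """|a| with subgradient 0 at a = 0; complex modulus for complex input."""
    if not _is_tensor(a):
        return np.abs(a)
    av = _data(a)
    mag = np.abs(av)

    def vjp(g):
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(mag > 0, av / np.where(mag > 0, mag, 1.0), 0.0)
        return g * d

    return _node(mag, [(a, vjp)])


def real(a):
    if not _is_tensor(a):
        return np.real(a)
    return _node(np.real(_data(a)), [(a, lambda g: np.asarray(g).real + 0j)])


def imag(a):
    if not _is_tensor(a):
        return np.imag(a)
    return _node(np.imag(_data(a)), [(a, lambda g: 1j * np.asarray(g).real)])


def conj(a):
    if not _is_tensor(a):
        return np.conj(a)
    return _node(np.conj(_data(a)), [(a, lambda g: np.conj(g))])


# -- reductions & shape --------------------------------------------------------

def sum(a, axis=None):
    if not _is_tensor(a):
        return _np_sum(a, axis=axis)
    av = _data(a)
    val = _np_sum(av, axis=axis)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, av.shape)
        g = np.expand_dims(g, axis)
        return np.broadcast_to(g, av.shape)

    return _node(val, [(a, vjp)])


def mean(a, axis=None):
    av = _data(a)
    if axis is None:
        n = av.size
    else:
        axes = (axis,) if np.isscalar(axis) else tuple(axis)
        n = int(np.prod([av.shape[i] for i in axes]))
    return div(sum(a, axis=axis), float(n))


def reshape(a, shape):
    if not _is_tensor(a):
        return np.reshape(a, shape)
    av = _data(a)
    return _node(np.reshape(av, shape), [(a, lambda g: np.reshape(g, av.shape))])


def expand_dims(a, axis):
    if not _is_tensor(a):
        return np.expand_dims(a, axis)
    av = _data(a)
    return reshape(a, np.expand_dims(av, axis).shape)


def moveaxis(a, source, destination):
    if not _is_tensor(a):
        return np.moveaxis(a, source, destination)
    return _node(
        np.moveaxis(_data(a), source, destination),
        [(a, lambda g: np.moveaxis(g, destination, source))],
    )


def concatenate(arrays, axis=0):
    if not _is_tensor(*arrays):
        return np.concatenate(arrays, axis=axis)
    datas = [_data(x) for x in arrays]
    val = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(sl)]

        return vjp

    return _node(val, [(x, make_vjp(i)) for i, x in enumerate(arrays)])


def getitem(a, idx):
    if not _is_tensor(a):
        return np.asarray(a)[idx]
    av = _data(a)
    val = av[idx]

    def vjp(g):
        out = np.zeros(av.shape, dtype=np.result_type(g.dtype, float))
        np.add.at(out, idx, g)
        return out

    return _node(val, [(a, vjp)])


# -- FFT (unitary) -------------------------------------------------------------

def fftn(a, axes):
    """Unitary (norm='ortho') n-D FFT over ``axes``; adjoint is :func:`ifftn`."""
    if not _is_tensor(a):
        return np.fft.fftn(a, axes=axes, norm="ortho")
    return _node(
        np.fft.fftn(_data(a), axes=axes, norm="ortho"),
        [(a, lambda g: np.fft.ifftn(g, axes=axes, norm="ortho"))],
    )


def ifftn(a, axes):
    if not _is_tensor(a):
        return np.fft.ifftn(a, axes=axes, norm="ortho")
    return _node(
        np.fft.ifftn(_data(a), axes=axes, norm="ortho"),
        [(a, lambda g: np.fft.fftn(g, axes=axes, norm="ortho"))],
    )


# -- convenience ---------------------------------------------------------------

def grad(fn, args, wrt=None):
    """Evaluate ``fn(*leaves)`` and return (value, gradients).

    ``args`` are ndarrays promoted to leaf Tensors; ``wrt`` selects which
    positions to differentiate (default: all).
    """
    leaves = [Tensor(np.asarray(a), requires_grad=True) for a in args]
    out = fn(*leaves)
    if not isinstance(out, Tensor):
        raise TypeError("fn must return a Tensor")
    out.backward()
    sel = range(len(leaves)) if wrt is None else wrt
    grads = [leaves[i].grad if leaves[i].grad is not None else np.zeros_like(leaves[i].data) for i in sel]
    return out.data.item(), grads
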