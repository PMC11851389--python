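"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports higher-order differentiation: every vector-Jacobian
product is itself expressed with :class:`Tensor` operations, so a gradient
computed with ``create_graph=True`` is a differentiable node.  This is what
the R1 gradient penalty needs — the penalty is a function of the
discriminator's input gradient, and its parameter gradient is a second
derivative.

Only the operations required by the networks in this package are provided.
Tensors wrap numpy arrays of any floating dtype; dtype is preserved through
the graph (float32 for training speed, float64 where tests need precision).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "is_grad_enabled",
    "backward",
    "grad",
]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference / updates)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad=False, _parents=(), _vjps=()):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None  # numpy array, filled by backward()
        self._parents = _parents
        self._vjps = _vjps

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def backward(self, create_graph=False):
        backward(self, create_graph=create_graph)


def tensor(data, requires_grad=False, dtype=None) -> Tensor:
    arr = np.asarray(data, dtype=dtype if dtype is not None else None)
    if arr.dtype.kind != "f":
        arr = arr.astype(np.float64)
    return Tensor(arr, requires_grad=requires_grad)


def _as_tensor(x, like=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.dtype if like is not None else np.float64
    return Tensor(np.asarray(x, dtype=dtype))


def _make(data, parents, vjps) -> Tensor:
    """Create an op output; record the graph only when grad is enabled."""
    if is_grad_enabled() and any(p.requires_grad for p in parents):
        out = Tensor(data, requires_grad=True, _parents=tuple(parents), _vjps=tuple(vjps))
    else:
        out = Tensor(data, requires_grad=False)
    return out


# ---------------------------------------------------------------------------
# broadcasting helper: reduce g to `shape` (adjoint of numpy broadcasting)
# ---------------------------------------------------------------------------

def _sum_to(g: Tensor, shape) -> Tensor:
    if g.shape == tuple(shape):
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = tsum(g, axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a = _as_tensor(a, b if isinstance(b, Tensor) else None)
    b = _as_tensor(b, a)
    return _make(
        a.data + b.data,
        (a, b),
        (lambda g: _sum_to(g, a.shape), lambda g: _sum_to(g, b.shape)),
    )


def sub(a, b) -> Tensor:
    a = _as_tensor(a, b if isinstance(b, Tensor) else None)
    b = _as_tensor(b, a)
    return _make(
        a.data - b.data,
        (a, b),
        (lambda g: _sum_to(g, a.shape), lambda g: _sum_to(neg(g), b.shape)),
    )


def mul(a, b) -> Tensor:
    a = _as_tensor(a, b if isinstance(b, Tensor) else None)
    b = _as_tensor(b, a)
    return _make(
        a.data * b.data,
        (a, b),
        (lambda g: _sum_to(mul(g, b), a.shape), lambda g: _sum_to(mul(g, a), b.shape)),
    )


def div(a, b) -> Tensor:
    a = _as_tensor(a, b if isinstance(b, Tensor) else None)
    b = _as_tensor(b, a)
    return _make(
        a.data / b.data,
        (a, b),
        (
            lambda g: _sum_to(div(g, b), a.shape),
            lambda g: _sum_to(neg(mul(g, div(a, mul(b, b)))), b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = _as_tensor(a)
    return _make(-a.data, (a,), (lambda g: neg(g),))


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)
    return _make(
        a.data**p,
        (a,),
        (lambda g: mul(g, mul(p, power(a, p - 1.0))),),
    )


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)
    out = _make(out_data, (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, out),)
    return out


def log(a) -> Tensor:
    a = _as_tensor(a)
    return _make(np.log(a.data), (a,), (lambda g: div(g, a),))


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out = _make(np.tanh(a.data), (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, sub(1.0, mul(out, out))),)
    return out


def sigmoid(a) -> Tensor:
    from scipy.special import expit

    a = _as_tensor(a)
    out = _make(expit(a.data), (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, mul(out, sub(1.0, out))),)
    return out


def absval(a) -> Tensor:
    # sign treated as locally constant (a.e. derivative)
    a = _as_tensor(a)
    s = np.sign(a.data)
    return _make(np.abs(a.data), (a,), (lambda g: mul(g, Tensor(s)),))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    m = np.where(a.data > 0, 1.0, slope).astype(a.dtype)
    return _make(a.data * m, (a,), (lambda g: mul(g, Tensor(m)),))


def silu(a) -> Tensor:
    return mul(a, sigmoid(a))


def clip(a, lo: float, hi: float) -> Tensor:
    # straight-through inside the range; zero gradient where clipped
    a = _as_tensor(a)
    m = ((a.data > lo) & (a.data < hi)).astype(a.dtype)
    return _make(np.clip(a.data, lo, hi), (a,), (lambda g: mul(g, Tensor(m)),))


def where_mask(mask: np.ndarray, a, b) -> Tensor:
    """mask is a constant boolean array; gradient routes accordingly."""
    a = _as_tensor(a)
    b = _as_tensor(b, a)
    m = mask.astype(a.dtype)
    return _make(
        np.where(mask, a.data, b.data),
        (a, b),
        (
            lambda g: _sum_to(mul(g, Tensor(m)), a.shape),
            lambda g: _sum_to(mul(g, Tensor(1.0 - m)), b.shape),
        ),
    )


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % a.ndim for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(a.shape))
            g = reshape(g, kshape)
        return broadcast_to(g, a.shape)

    return _make(data, (a,), (vjp,))


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= a.shape[ax % a.ndim]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    return _make(a.data.reshape(shape), (a,), (lambda g: reshape(g, a.shape),))


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), (a,), (lambda g: transpose(g, inv),))


def swap_last2(a) -> Tensor:
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def broadcast_to(a, shape) -> Tensor:
    a = _as_tensor(a)
    return _make(
        np.broadcast_to(a.data, shape).copy(),
        (a,),
        (lambda g: _sum_to(g, a.shape),),
    )


def concat(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + [t.shape[axis] for t in tensors])

    def make_vjp(i):
        def vjp(g):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return getitem(g, tuple(key))

        return vjp

    return _make(data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def getitem(a, key) -> Tensor:
    a = _as_tensor(a)
    return _make(a.data[key], (a,), (lambda g: _scatter(g, a.shape, key),))


def _scatter(g, shape, key) -> Tensor:
    """Adjoint of basic slicing: place g into zeros of `shape` at `key`."""
    g = _as_tensor(g)
    data = np.zeros(shape, dtype=g.dtype)
    data[key] = g.data
    return _make(data, (g,), (lambda gg: getitem(gg, key),))


def pad2d(a, padding: int) -> Tensor:
    """Zero-pad the last two axes symmetrically."""
    a = _as_tensor(a)
    if padding == 0:
        return a
    p = padding
    pads = [(0, 0)] * (a.ndim - 2) + [(p, p), (p, p)]
    data = np.pad(a.data, pads)
    key = tuple([slice(None)] * (a.ndim - 2) + [slice(p, -p), slice(p, -p)])
    return _make(data, (a,), (lambda g: getitem(g, key),))


# ---------------------------------------------------------------------------
# matmul
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a = _as_tensor(a)
    b = _as_tensor(b)
    return _make(
        a.data @ b.data,
        (a, b),
        (
            lambda g: _sum_to(matmul(g, swap_last2(b)), a.shape),
            lambda g: _sum_to(matmul(swap_last2(a), g), b.shape),
        ),
    )


# ---------------------------------------------------------------------------
# im2col / col2im — the linear adjoint pair behind convolution
# ---------------------------------------------------------------------------

def im2col(x, kh: int, kw: int, stride: int = 1) -> Tensor:
    """(B, C, H, W) -> (B, C*kh*kw, oh*ow) sliding-window unfold."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (B, C, oh, ow, kh, kw)
    data = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
    data = data.reshape(B, C * kh * kw, oh * ow)
    meta = (C, H, W, kh, kw, stride)
    return _make(data, (x,), (lambda g: col2im(g, meta),))


def col2im(cols, meta) -> Tensor:
    """Adjoint of :func:`im2col`: overlap-add of window columns."""
    cols = _as_tensor(cols)
    C, H, W, kh, kw, stride = meta
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    B = cols.shape[0]
    blocks = cols.data.reshape(B, C, kh, kw, oh, ow)
    data = np.zeros((B, C, H, W), dtype=cols.dtype)
    for ii in range(kh):
        hi = ii + stride * oh
        for jj in range(kw):
            wj = jj + stride * ow
            data[:, :, ii:hi:stride, jj:wj:stride] += blocks[:, :, ii, jj]
    return _make(data, (cols,), (lambda g: im2col(g, kh, kw, stride),))


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) via unfold + matmul.

    x: (B, Cin, H, W); w: (Cout, Cin // groups, kh, kw); b: (Cout,) or None.
    Built entirely from differentiable primitives, so second derivatives
    (needed by the gradient penalty) come for free.
    """
    x = _as_tensor(x)
    w = _as_tensor(w)
    B, Cin, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    if Cin % groups or Cout % groups or Cg != Cin // groups:
        raise ValueError("channel counts incompatible with groups")
    xp = pad2d(x, padding)
    oh = (H + 2 * padding - kh) // stride + 1
    ow = (W + 2 * padding - kw) // stride + 1
    if groups == 1:
        cols = im2col(xp, kh, kw, stride)  # (B, Cin*kh*kw, oh*ow)
        wf = reshape(w, (Cout, Cg * kh * kw))
        out = matmul(wf, cols)  # (B, Cout, oh*ow)
    else:
        outs = []
        gc_in = Cin // groups
        gc_out = Cout // groups
        for gi in range(groups):
            xg = getitem(xp, (slice(None), slice(gi * gc_in, (gi + 1) * gc_in)))
            wg = getitem(w, (slice(gi * gc_out, (gi + 1) * gc_out),))
            cols = im2col(xg, kh, kw, stride)
            wf = reshape(wg, (gc_out, gc_in * kh * kw))
            outs.append(matmul(wf, cols))
        out = concat(outs, axis=1)
    out = reshape(out, (B, Cout, oh, ow))
    if b is not None:
        out = add(out, reshape(b, (1, Cout, 1, 1)))
    return out


def upsample_nearest2x(x) -> Tensor:
    x = _as_tensor(x)
    B, C, H, W = x.shape
    y = reshape(x, (B, C, H, 1, W, 1))
    y = broadcast_to(y, (B, C, H, 2, W, 2))
    return reshape(y, (B, C, 2 * H, 2 * W))


# ---------------------------------------------------------------------------
# backward / grad
# ---------------------------------------------------------------------------

def _topo(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # children after parents; iterate reversed for backprop


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


def backward(out: Tensor, create_graph: bool = False) -> None:
    """Accumulate gradients of scalar `out` into `.grad` of all leaf tensors."""
    if out.data.size != 1:
        raise ValueError("backward() requires a scalar output")
    seed = Tensor(np.ones_like(out.data))
    grads = {id(out): seed}
    for node in reversed(_topo(out)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if not node._parents:
            if node.requires_grad:
                acc = g.data if g.data.shape == node.shape else np.broadcast_to(g.data, node.shape)
                node.grad = acc.copy() if node.grad is None else node.grad + acc
            continue
        ctx = no_grad() if not create_graph else _nullcontext()
        with ctx:
            for p, vjp in zip(node._parents, node._vjps):
                if not p.requires_grad:
                    continue
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg


def grad(out: Tensor, inputs, create_graph: bool = False):
    """Return d out / d inputs as Tensors, without touching `.grad` fields."""
    single = isinstance(inputs, Tensor)
    if single:
        inputs = [inputs]
    if out.data.size != 1:
        raise ValueError("grad() requires a scalar output")
    seed = Tensor(np.ones_like(out.data))
    grads = {id(out): seed}
    order = _topo(out)
    for node in reversed(order):
        g = grads.get(id(node))
        if g is None or not node._parents:
            continue
        ctx = no_grad() if not create_graph else _nullcontext()
        with ctx:
            for p, vjp in zip(node._parents, node._vjps):
                if not p.requires_grad:
                    continue
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
    results = []
    for inp in inputs:
        g = grads.get(id(inp))
        if g is None:
            g = Tensor(np.zeros_like(inp.data))
        results.append(g)
    return results[0] if single else results
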