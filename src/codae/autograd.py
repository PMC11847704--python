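"""A minimal reverse-mode automatic-differentiation engine on numpy.

This is the numerical substrate for the autoencoder: dense float32
tensors, a dynamically built tape, and exactly the operations the model
needs (elementwise arithmetic, matmul, 2D convolution via im2col,
pooling, bilinear grid sampling, trig).  Gradients are checked against
finite differences in the test suite.

Not a general framework: no views-with-aliasing, no higher-order
gradients, no dtype promotion beyond float32/float64.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32) if not isinstance(
            data, np.ndarray) else data
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None
        self._grad_borrowed = False

    # -- tape helpers -----------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._grad_borrowed = False
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    def _accum(self, g: np.ndarray) -> None:
        # First accumulation borrows the array (no copy); a second
        # accumulation copies before adding in place, so a gradient array
        # shared between two parents is never mutated.
        if self.grad is None:
            self.grad = g if g.dtype == self.data.dtype else g.astype(self.data.dtype)
            self._grad_borrowed = True
        else:
            if self._grad_borrowed:
                self.grad = self.grad + g
                self._grad_borrowed = False
            else:
                self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_borrowed = False

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

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

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


# ---------------------------------------------------------------------------
# elementwise and linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** exponent

    def backward(g):
        a._accum(_unbroadcast(g * exponent * a.data ** (exponent - 1), a.data.shape))

    return Tensor._result(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return Tensor._result(out_data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(old))

    return Tensor._result(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accum(np.transpose(g, inv))

    return Tensor._result(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    return Tensor._result(out_data, (a,), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(out_data, tuple(tensors), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy()
                     if np.ndim(g) else np.full_like(a.data, g))
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.data.shape).copy())

    return Tensor._result(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def tmax(a, axis: int) -> Tensor:
    """Maximum along one axis; gradient routed to the (first) argmax."""
    a = as_tensor(a)
    idx = np.argmax(a.data, axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis
                                  ).squeeze(axis)

    def backward(g):
        full = np.zeros_like(a.data)
        np.put_along_axis(full, np.expand_dims(idx, axis),
                          np.expand_dims(g, axis), axis=axis)
        a._accum(full)

    return Tensor._result(out_data, (a,), backward)


def _unary(a, fval, fgrad):
    a = as_tensor(a)
    out_data = fval(a.data)

    def backward(g):
        a._accum(g * fgrad(a.data, out_data))

    return Tensor._result(out_data, (a,), backward)


def relu(a):
    return _unary(a, lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(x.dtype))


def sigmoid(a):
    return _unary(a, lambda x: 1.0 / (1.0 + np.exp(-x)), lambda x, y: y * (1.0 - y))


def tanh(a):
    return _unary(a, np.tanh, lambda x, y: 1.0 - y * y)


def exp(a):
    return _unary(a, np.exp, lambda x, y: y)


def log(a):
    return _unary(a, np.log, lambda x, y: 1.0 / x)


def sin(a):
    return _unary(a, np.sin, lambda x, y: np.cos(x))


def cos(a):
    return _unary(a, np.cos, lambda x, y: -np.sin(x))


def atan2(y, x) -> Tensor:
    y, x = as_tensor(y), as_tensor(x)
    out_data = np.arctan2(y.data, x.data)
    denom = y.data ** 2 + x.data ** 2

    def backward(g):
        if y.requires_grad:
            y._accum(_unbroadcast(g * x.data / denom, y.data.shape))
        if x.requires_grad:
            x._accum(_unbroadcast(-g * y.data / denom, x.data.shape))

    return Tensor._result(out_data, (y, x), backward)


# ---------------------------------------------------------------------------
# convolution and spatial ops
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None) -> Tensor:
    """'same' correlation: x (B, C, H, W) with w (F, C, k, k), odd k.

    Implemented by im2col + one BLAS matmul; the backward pass uses the
    transposed matmul and a k*k-step col2im scatter.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.data.shape
    F, C2, k, k2 = w.data.shape
    if C != C2 or k != k2:
        raise ValueError("kernel shape mismatch")
    if k % 2 == 0:
        raise ValueError("kernel size must be odd (no well-defined centre)")
    p = k // 2
    # layout (C, k, k, B, H, W) so both GEMMs are single large 2D products;
    # pad and transpose in one contiguous assignment
    xpt = np.zeros((C, B, H + 2 * p, W + 2 * p), dtype=x.data.dtype)
    xpt[:, :, p:p + H, p:p + W] = x.data.transpose(1, 0, 2, 3)
    cols = np.empty((C, k, k, B, H, W), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xpt[:, :, i:i + H, j:j + W]
    cols2 = cols.reshape(C * k * k, B * H * W)
    wmat = w.data.reshape(F, C * k * k)
    out_data = np.ascontiguousarray(
        (wmat @ cols2).reshape(F, B, H, W).transpose(1, 0, 2, 3))
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.reshape(1, F, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(
            F, B * H * W)
        if w.requires_grad:
            w._accum((gmat @ cols2.T).reshape(F, C, k, k))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = (wmat.T @ gmat).reshape(C, k, k, B, H, W)
            gxpt = np.zeros_like(xpt)
            for i in range(k):
                for j in range(k):
                    gxpt[:, :, i:i + H, j:j + W] += gcols[:, i, j]
            x._accum(np.ascontiguousarray(
                gxpt[:, :, p:p + H, p:p + W].transpose(1, 0, 2, 3)))

    return Tensor._result(out_data, parents, backward)


def avg_pool2(x) -> Tensor:
    """2x2 average pooling (even spatial dims required)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    out_data = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accum(gx)

    return Tensor._result(out_data, (x,), backward)


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    x = as_tensor(x)
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        B, C, H2, W2 = g.shape
        gx = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        x._accum(gx)

    return Tensor._result(out_data, (x,), backward)


def sample_bilinear(img, gx, gy) -> Tensor:
    """Sample img (B, C, H, W) at coords gx, gy (B, Ho, Wo), zeros outside.

    ``gx`` is the column coordinate, ``gy`` the row coordinate, in pixel
    units.  Differentiable with respect to the image and both coordinate
    grids (the spatial-transformer sampler).
    """
    img, gx, gy = as_tensor(img), as_tensor(gx), as_tensor(gy)
    B, C, H, W = img.data.shape
    x = gx.data
    y = gy.data
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    fx = (x - x0).astype(img.data.dtype)
    fy = (y - y0).astype(img.data.dtype)

    corners = []
    for dy_, dx_ in ((0, 0), (0, 1), (1, 0), (1, 1)):
        xi = x0 + dx_
        yi = y0 + dy_
        valid = ((xi >= 0) & (xi < W) & (yi >= 0) & (yi < H))
        xi_c = np.clip(xi, 0, W - 1)
        yi_c = np.clip(yi, 0, H - 1)
        wgt = ((fx if dx_ else (1.0 - fx)) * (fy if dy_ else (1.0 - fy))
               * valid.astype(img.data.dtype))
        corners.append((xi_c, yi_c, wgt, valid))

    bidx = np.arange(B)[:, None, None]
    imgt = np.moveaxis(img.data, 1, -1)            # (B, H, W, C)
    out_data = np.zeros((B, C, *x.shape[1:]), dtype=img.data.dtype)
    vals = []
    for xi_c, yi_c, wgt, _ in corners:
        v = imgt[bidx, yi_c, xi_c]                 # (B, Ho, Wo, C)
        v = np.moveaxis(v, -1, 1)                  # (B, C, Ho, Wo)
        vals.append(v)
        out_data += v * wgt[:, None]

    def backward(g):
        if img.requires_grad:
            gimgt = np.zeros_like(imgt)
            for xi_c, yi_c, wgt, _ in corners:
                contrib = np.moveaxis(g * wgt[:, None], 1, -1)  # (B,Ho,Wo,C)
                np.add.at(gimgt, (bidx, yi_c, xi_c), contrib)
            img._accum(np.moveaxis(gimgt, -1, 1))
        if gx.requires_grad or gy.requires_grad:
            (v00, v01, v10, v11) = vals
            m = [c[3].astype(img.data.dtype)[:, None] for c in corners]
            # d out / d fx and d fy (zero-outside handled by corner masks)
            dfx = ((v01 * m[1] - v00 * m[0]) * (1.0 - fy[:, None])
                   + (v11 * m[3] - v10 * m[2]) * fy[:, None])
            dfy = ((v10 * m[2] - v00 * m[0]) * (1.0 - fx[:, None])
                   + (v11 * m[3] - v01 * m[1]) * fx[:, None])
            if gx.requires_grad:
                gx._accum((g * dfx).sum(axis=1))
            if gy.requires_grad:
                gy._accum((g * dfy).sum(axis=1))

    return Tensor._result(out_data, (img, gx, gy), backward)


# ---------------------------------------------------------------------------
# parameters and optimizer
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Adam:
    """Adam optimizer with optional global gradient-norm clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = float(np.sqrt(sum(float((g ** 2).sum()) for g in grads)))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
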