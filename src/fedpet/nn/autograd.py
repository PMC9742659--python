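"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the handful of operations needed for 2D convolutional encoder-decoder
networks are provided: same-padding (dilated) convolution, ReLU, 2x2 max
pooling, bilinear resizing, channel concatenation, elementwise add, and mean
squared error.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward` in reverse topological order.

The engine is intentionally define-by-run and dtype-agnostic: float32 for
speed during image training, float64 where tests demand tight numerical
identities.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "relu",
    "maxpool2",
    "resize_bilinear",
    "concat",
    "add",
    "mse",
    "add_losses",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node (default seed gradient: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Same-padding 2D cross-correlation.

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin, k, k) with odd ``k``;
    ``b``: (Cout,) or None.  Effective padding is ``dilation * (k // 2)``
    so the spatial size is preserved for any odd kernel.
    """
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, C2, k, k2 = wd.shape
    if C != C2 or k != k2 or k % 2 != 1:
        raise ValueError(f"conv2d shape mismatch: x {xd.shape}, w {wd.shape}")
    pad = dilation * (k // 2)
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((B, O, H, W), dtype=xd.dtype)
    out_flat = out.reshape(B, O, H * W)
    for i in range(k):
        for j in range(k):
            xs = xp[:, :, i * dilation : i * dilation + H, j * dilation : j * dilation + W]
            # (O,C) @ (B,C,HW) -> (B,O,HW), BLAS-backed
            out_flat += np.matmul(wd[:, :, i, j], xs.reshape(B, C, H * W))
    if b is not None:
        out += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)
    t = Tensor(out, parents=parents)

    def backward(g):
        gf = g.reshape(B, O, H * W)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.empty_like(wd)
            for i in range(k):
                for j in range(k):
                    xs = xp[
                        :, :, i * dilation : i * dilation + H, j * dilation : j * dilation + W
                    ].reshape(B, C, H * W)
                    # sum_B (B,O,HW) @ (B,HW,C) -> (O,C)
                    gw[:, :, i, j] = np.matmul(gf, xs.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            wt = wd.transpose(1, 0, 2, 3)  # (C,O,k,k)
            for i in range(k):
                for j in range(k):
                    gxp[
                        :, :, i * dilation : i * dilation + H, j * dilation : j * dilation + W
                    ] += np.matmul(wt[:, :, i, j], gf).reshape(B, C, H, W)
            x._accumulate(gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp)

    t._backward = backward
    return t


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    t = Tensor(np.where(mask, x.data, 0), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.where(mask, g, 0))

    t._backward = backward
    return t


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties resolve to the first maximum."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 requires even spatial size, got {H}x{W}")
    Ho, Wo = H // 2, W // 2
    windows = (
        x.data.reshape(B, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, 4)
    )
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    t = Tensor(out, parents=(x,))

    def backward(g):
        if x.requires_grad:
            gw = np.zeros((B, C, Ho, Wo, 4), dtype=g.dtype)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = (
                gw.reshape(B, C, Ho, Wo, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(B, C, H, W)
            )
            x._accumulate(gx)

    t._backward = backward
    return t


_resize_cache: dict[tuple, np.ndarray] = {}


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1D linear-interpolation matrix (n_out, n_in), half-pixel centers."""
    key = (n_in, n_out, np.dtype(dtype).str)
    m = _resize_cache.get(key)
    if m is None:
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        f = src - i0
        m = np.zeros((n_out, n_in), dtype=dtype)
        rows = np.arange(n_out)
        np.add.at(m, (rows, i0), 1 - f)
        np.add.at(m, (rows, i1), f)
        _resize_cache[key] = m
    return m


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of (B, C, H, W) to spatial size ``out_hw``."""
    B, C, H, W = x.data.shape
    Ho, Wo = out_hw
    if (Ho, Wo) == (H, W):
        t = Tensor(x.data, parents=(x,))
        t._backward = lambda g: x._accumulate(g) if x.requires_grad else None
        return t
    Rh = _resize_matrix(H, Ho, x.data.dtype)
    Rw = _resize_matrix(W, Wo, x.data.dtype)
    out = np.matmul(np.matmul(Rh, x.data), Rw.T)
    t = Tensor(out, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.matmul(np.matmul(Rh.T, g), Rw))

    t._backward = backward
    return t


def concat(xs: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([x.data for x in xs], axis=axis)
    t = Tensor(out, parents=tuple(xs))
    sizes = [x.data.shape[axis] for x in xs]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for x, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            if x.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                x._accumulate(g[tuple(sl)])

    t._backward = backward
    return t


def add(x: Tensor, y: Tensor) -> Tensor:
    if x.data.shape != y.data.shape:
        raise ValueError("add requires identical shapes")
    t = Tensor(x.data + y.data, parents=(x, y))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g)
        if y.requires_grad:
            y._accumulate(g)

    t._backward = backward
    return t


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target; returns a scalar tensor."""
    target = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - target
    n = diff.size
    t = Tensor(np.asarray((diff * diff).sum() / n, dtype=pred.data.dtype), parents=(pred,))

    def backward(g):
        if pred.requires_grad:
            pred._accumulate((2.0 / n) * diff * g)

    t._backward = backward
    return t


def add_losses(losses: list[Tensor]) -> Tensor:
    """Sum of scalar loss tensors."""
    t = Tensor(np.asarray(sum(l.data for l in losses)), parents=tuple(losses))

    def backward(g):
        for l in losses:
            if l.requires_grad:
                l._accumulate(g)

    t._backward = backward
    return t
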