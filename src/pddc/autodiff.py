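"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the computational core of the reconstruction network: dense enough
for small 2D convolutional cascades (conv2d via im2col, ReLU, channel
concatenation, centered orthonormal FFT pairs with exact adjoints, masked
data-consistency composition, mean-squared-error loss) and nothing more.
Gradients are accumulated by topological traversal of the recorded graph.

Complex data is carried as two real channels (real, imaginary); the FFT ops
convert to complex internally and their backward pass applies the adjoint
(= inverse, by unitarity) transform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "relu", "concat", "fft2c", "ifft2c", "mse_loss", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- elementwise arithmetic ------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return self._node(self.data - other.data, (self, other), backward)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    # -- autodiff driver --------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        return (g * mask,)

    return Tensor._node(np.where(mask, x.data, 0.0), (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)


def _col2im(gcol: np.ndarray, shape: tuple, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = shape
    ph, pw = kh // 2, kw // 2
    gpad = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
    g6 = gcol.reshape(n, h, w, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            gpad[:, :, i : i + h, j : j + w] += g6[:, :, :, :, i, j]
    return gpad[:, :, ph : ph + h, pw : pw + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded 2D convolution (cross-correlation) on (N, C, H, W) input.

    ``weight`` has shape (O, C, kh, kw) with odd kernel sizes; ``bias`` (O,).
    """
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"weight expects {ci} input channels, got {c}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel sizes must be odd")
    col = _im2col(x.data, kh, kw)  # (N*H*W, C*kh*kw)
    wmat = weight.data.reshape(o, -1)
    out = col @ wmat.T  # (N*H*W, O)
    if bias is not None:
        out = out + bias.data
    out = out.reshape(n, h, w, o).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gcol_out = g.transpose(0, 2, 3, 1).reshape(n * h * w, o)
        gw = (gcol_out.T @ col).reshape(weight.shape)
        gx = _col2im(gcol_out @ wmat, x.shape, kh, kw)
        if bias is None:
            return (gx, gw)
        return (gx, gw, gcol_out.sum(axis=0))

    return Tensor._node(out, parents, backward)


def _c2ch(z: np.ndarray) -> np.ndarray:
    return np.stack([z.real, z.imag], axis=1)


def _ch2c(x: np.ndarray) -> np.ndarray:
    return x[:, 0] + 1j * x[:, 1]


def _fft2c(z: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(z, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
    )


def _ifft2c(z: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(z, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
    )


def fft2c(x: Tensor) -> Tensor:
    """Centered orthonormal 2D FFT of a 2-channel (re, im) tensor (N, 2, H, W)."""

    def backward(g):
        # adjoint of a unitary C-linear map in the 2-real-channel representation
        return (_c2ch(_ifft2c(_ch2c(g))),)

    return Tensor._node(_c2ch(_fft2c(_ch2c(x.data))), (x,), backward)


def ifft2c(x: Tensor) -> Tensor:
    def backward(g):
        return (_c2ch(_fft2c(_ch2c(g))),)

    return Tensor._node(_c2ch(_ifft2c(_ch2c(x.data))), (x,), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target
    n = diff.size

    def backward(g):
        return (g * 2.0 * diff / n,)

    return Tensor._node(np.mean(diff**2), (pred,), backward)


# --------------------------------------------------------------------------
# Optimizer
# --------------------------------------------------------------------------


class Adam:
    """Adam with the standard bias correction; operates on a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
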