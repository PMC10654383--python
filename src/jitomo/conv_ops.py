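"""Low-level convolution primitives with hand-derived gradients.

All tensors are ``float32`` numpy arrays in channel-first layout:
``(batch, channels, [depth,] height, width)``.  Only the three shapes of
convolution needed by the small U-Net family are implemented:

* ``ConvSame`` — odd kernel (3 or 3x3x3), stride 1, zero "same" padding;
* ``Down2`` / ``Up2`` — non-overlapping 2x2 strided / transposed
  convolutions acting on the last two (in-plane) axes, which makes their
  adjoints simple block reshapes;
* ``Project`` — the final linear projection (1x1 in-plane, collapsing the
  full depth axis for volumetric / temporal networks).

Gradients are exact (verified by finite differences in the test suite);
there is no autograd graph — each layer caches what its backward needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "ConvSame", "Down2", "Up2", "Project", "ReLU"]


class Layer:
    """Base class: parameters and their gradients as parallel lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class ConvSame(Layer):
    """Odd-kernel stride-1 convolution with zero 'same' padding.

    ``nd`` is the number of spatial dimensions (2 or 3); the kernel is
    3 along every spatial axis.
    """

    def __init__(self, cin: int, cout: int, nd: int, rng: np.random.Generator, ksize: int = 3):
        if ksize % 2 != 1:
            raise ValueError("ConvSame requires an odd kernel size")
        self.nd = nd
        self.ksize = ksize
        kshape = (ksize,) * nd
        fan_in = cin * ksize**nd
        self.w = _he_init(rng, (cout, cin) + kshape, fan_in)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._win: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.ksize // 2
        pads = [(0, 0), (0, 0)] + [(p, p)] * self.nd
        return np.pad(x, pads)

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = self.nd
        xp = self._pad(x)
        axes = tuple(range(2, 2 + nd))
        win = sliding_window_view(xp, (self.ksize,) * nd, axis=axes)
        # win: (B, C, *S, *k); contract channel + kernel dims against w.
        self._win = win
        out = np.tensordot(win, self.w, axes=([1] + list(range(2 + nd, 2 + 2 * nd)), [1] + list(range(2, 2 + nd))))
        # out: (B, *S, F) -> (B, F, *S)
        out = np.moveaxis(out, -1, 1)
        out += self.b.reshape((1, -1) + (1,) * nd)
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = self.nd
        win = self._win
        assert win is not None, "forward must run before backward"
        spatial = list(range(2, 2 + nd))
        # dW[f, c, *k] = sum_{b, s} dy[b, f, *s] * win[b, c, *s, *k]
        self.dw[...] = np.tensordot(dy, win, axes=([0] + spatial, [0] + spatial))
        self.db[...] = dy.sum(axis=tuple([0] + spatial))
        # dX = "full" correlation of dy with the flipped kernel.
        dyp = self._pad(dy)
        win2 = sliding_window_view(dyp, (self.ksize,) * nd, axis=tuple(spatial))
        wf = np.flip(self.w, axis=tuple(range(2, 2 + nd)))
        dx = np.tensordot(win2, wf, axes=([1] + list(range(2 + nd, 2 + 2 * nd)), [0] + list(range(2, 2 + nd))))
        dx = np.moveaxis(dx, -1, 1)
        self._win = None
        return np.ascontiguousarray(dx, dtype=np.float32)


class Down2(Layer):
    """2x2 stride-2 convolution on the two in-plane axes (no overlap)."""

    def __init__(self, cin: int, cout: int, nd: int, rng: np.random.Generator):
        self.nd = nd
        self.w = _he_init(rng, (cout, cin, 2, 2), cin * 4)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xb: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    @staticmethod
    def _blocks(x: np.ndarray) -> np.ndarray:
        *lead, h, w = x.shape
        return x.reshape(*lead, h // 2, 2, w // 2, 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] % 2 or x.shape[-2] % 2:
            raise ValueError("Down2 requires even in-plane dimensions")
        xb = self._blocks(x)
        self._xb = xb
        if self.nd == 2:
            out = np.einsum("bcxpyq,fcpq->bfxy", xb, self.w, optimize=True)
        else:
            out = np.einsum("bcdxpyq,fcpq->bfdxy", xb, self.w, optimize=True)
        out += self.b.reshape((1, -1) + (1,) * self.nd)
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xb = self._xb
        assert xb is not None
        if self.nd == 2:
            self.dw[...] = np.einsum("bfxy,bcxpyq->fcpq", dy, xb, optimize=True)
            dxb = np.einsum("bfxy,fcpq->bcxpyq", dy, self.w, optimize=True)
        else:
            self.dw[...] = np.einsum("bfdxy,bcdxpyq->fcpq", dy, xb, optimize=True)
            dxb = np.einsum("bfdxy,fcpq->bcdxpyq", dy, self.w, optimize=True)
        self.db[...] = dy.sum(axis=tuple([0] + list(range(2, 2 + self.nd))))
        *lead, h2, _, w2, _ = dxb.shape
        self._xb = None
        return np.ascontiguousarray(dxb.reshape(*lead, h2 * 2, w2 * 2), dtype=np.float32)


class Up2(Layer):
    """2x2 stride-2 transposed convolution on the two in-plane axes."""

    def __init__(self, cin: int, cout: int, nd: int, rng: np.random.Generator):
        self.nd = nd
        self.w = _he_init(rng, (cin, cout, 2, 2), cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        if self.nd == 2:
            out = np.einsum("bcxy,cfpq->bfxpyq", x, self.w, optimize=True)
        else:
            out = np.einsum("bcdxy,cfpq->bfdxpyq", x, self.w, optimize=True)
        *lead, h, _, w, _ = out.shape
        out = out.reshape(*lead, h * 2, w * 2)
        out = out + self.b.reshape((1, -1) + (1,) * self.nd)
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        dyb = Down2._blocks(dy)
        if self.nd == 2:
            self.dw[...] = np.einsum("bcxy,bfxpyq->cfpq", x, dyb, optimize=True)
            dx = np.einsum("bfxpyq,cfpq->bcxy", dyb, self.w, optimize=True)
        else:
            self.dw[...] = np.einsum("bcdxy,bfdxpyq->cfpq", x, dyb, optimize=True)
            dx = np.einsum("bfdxpyq,cfpq->bcdxy", dyb, self.w, optimize=True)
        self.db[...] = dy.sum(axis=tuple([0] + list(range(2, 2 + self.nd))))
        self._x = None
        return np.ascontiguousarray(dx, dtype=np.float32)


class Project(Layer):
    """Final linear projection.

    2-D nets: a 1x1 convolution.  3-D nets: a (depth, 1, 1) kernel that is
    *valid* along depth, collapsing the slice/frame axis to the single
    middle-frame output while projecting channels.  Initialised to zero so
    an untrained network outputs a constant (the normalisation offset).
    """

    def __init__(self, cin: int, cout: int, nd: int, depth: int = 1):
        self.nd = nd
        self.depth = depth
        if nd == 2:
            self.w = np.zeros((cout, cin), dtype=np.float32)
        else:
            self.w = np.zeros((cout, cin, depth), dtype=np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        if self.nd == 2:
            out = np.einsum("bcxy,fc->bfxy", x, self.w, optimize=True)
            out += self.b.reshape(1, -1, 1, 1)
        else:
            out = np.einsum("bcdxy,fcd->bfxy", x, self.w, optimize=True)[:, :, None]
            out += self.b.reshape(1, -1, 1, 1, 1)
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        if self.nd == 2:
            self.dw[...] = np.einsum("bfxy,bcxy->fc", dy, x, optimize=True)
            self.db[...] = dy.sum(axis=(0, 2, 3))
            dx = np.einsum("bfxy,fc->bcxy", dy, self.w, optimize=True)
        else:
            dy2 = dy[:, :, 0]
            self.dw[...] = np.einsum("bfxy,bcdxy->fcd", dy2, x, optimize=True)
            self.db[...] = dy2.sum(axis=(0, 2, 3))
            dx = np.einsum("bfxy,fcd->bcdxy", dy2, self.w, optimize=True)
        self._x = None
        return np.ascontiguousarray(dx, dtype=np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._mask
        assert mask is not None
        self._mask = None
        return np.where(mask, dy, np.float32(0.0))
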