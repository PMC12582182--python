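"""Minimal reverse-mode automatic differentiation for 3D registration networks.

This is a deliberately small tape-based engine over numpy arrays (float64
throughout, fully deterministic on one platform).  It implements exactly the
operations the cascaded deformation-prediction network needs:

* ``conv3d`` — 3x3x3 same-padded convolution via im2col,
* ``leaky_relu``, channel ``stack``, scalar combination of losses,
* ``upsample3`` — separable trilinear upsampling of a low-resolution
  displacement grid to the full grid,
* ``warp`` — differentiable trilinear resampling through a displacement
  field (gradients with respect to both the field and, when required, the
  image being resampled),
* ``ncc_loss`` / ``mse_loss`` — global similarity losses (lower is better),
* ``diffusion_reg`` — mean squared forward-difference gradient of a field.

Tensors are channel-first: images ``(C, nx, ny, nz)``, displacement fields
``(3, nx, ny, nz)`` with component ``c`` the displacement along axis ``c``.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "parents", "bw", "requires_grad")

    def __init__(self, data, parents: Tuple["Tensor", ...] = (),
                 bw: Optional[Callable[[np.ndarray], None]] = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.parents = parents
        self.bw = bw
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    def accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) node."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t.parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p.parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.bw is not None and node.grad is not None:
                node.bw(node.grad)

    def item(self) -> float:
        return float(self.data)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accum(g)
        if b.requires_grad:
            b.accum(g)

    out.bw = bw
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, (a,))
    out.bw = lambda g: a.accum(g * s)
    return out


def add_const(a: Tensor, c: np.ndarray | float) -> Tensor:
    out = Tensor(a.data + c, (a,))
    out.bw = lambda g: a.accum(g)
    return out


def mul_const(a: Tensor, c: np.ndarray | float) -> Tensor:
    out = Tensor(a.data * c, (a,))
    out.bw = lambda g: a.accum(g * c)
    return out


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    mask = np.where(x.data > 0, 1.0, alpha)
    out = Tensor(x.data * mask, (x,))
    out.bw = lambda g: x.accum(g * mask)
    return out


def stack_channels(parts: Sequence[Tensor | np.ndarray]) -> Tensor:
    """Concatenate single- or multi-channel blocks along the channel axis."""
    tensors = [p if isinstance(p, Tensor) else Tensor(p) for p in parts]
    arrays = []
    spans = []
    start = 0
    for t in tensors:
        block = t.data if t.data.ndim == 4 else t.data[None]
        arrays.append(block)
        spans.append((start, start + block.shape[0], t, t.data.ndim == 3))
        start += block.shape[0]
    out = Tensor(np.concatenate(arrays, axis=0), tuple(tensors))

    def bw(g):
        for lo, hi, t, squeeze in spans:
            if t.requires_grad:
                t.accum(g[lo] if squeeze else g[lo:hi])

    out.bw = bw
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3x3 convolution with zero 'same' padding.

    ``x``: (Cin, nx, ny, nz); ``w``: (Cout, Cin, 3, 3, 3); ``b``: (Cout,).
    """
    cin, nx, ny, nz = x.data.shape
    cout = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (Cin,nx,ny,nz,3,3,3)
    cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(-1, cin * 27)
    wr = w.data.reshape(cout, -1)
    y = cols @ wr.T + b.data  # (N, Cout)
    out = Tensor(np.ascontiguousarray(y.T).reshape(cout, nx, ny, nz), (x, w, b))

    def bw(g):
        gn = g.reshape(cout, -1).T  # (N, Cout)
        w.accum((gn.T @ cols).reshape(w.data.shape))
        b.accum(gn.sum(axis=0))
        if x.requires_grad:
            # full correlation of the output gradient with the flipped kernel
            gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (1, 1)))
            gwin = sliding_window_view(gp, (3, 3, 3), axis=(1, 2, 3))
            gcols = np.ascontiguousarray(gwin.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(-1, cout * 27)
            wf = w.data[:, :, ::-1, ::-1, ::-1].transpose(0, 2, 3, 4, 1).reshape(cout * 27, cin)
            gx = (gcols @ wf).T.reshape(cin, nx, ny, nz)
            x.accum(gx)

    out.bw = bw
    return out


def global_mean(x: Tensor) -> Tensor:
    """Spatial global average pooling: (C, nx, ny, nz) -> (C,)."""
    out = Tensor(x.data.mean(axis=(1, 2, 3)), (x,))
    nvox = x.data[0].size
    out.bw = lambda g: x.accum(np.broadcast_to(g[:, None, None, None] / nvox,
                                               x.data.shape))
    return out


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fully connected layer on a vector: y = w @ x + b."""
    out = Tensor(w.data @ x.data + b.data, (x, w, b))

    def bw(g):
        w.accum(np.outer(g, x.data))
        b.accum(g)
        if x.requires_grad:
            x.accum(w.data.T @ g)

    out.bw = bw
    return out


def affine_field(p: Tensor, centered_coords: np.ndarray) -> Tensor:
    """Displacement field of a global affine map from 12 parameters.

    ``p`` holds the 3x3 linear part row-major followed by the translation;
    ``disp[c] = sum_j p[3c+j] * x_j + p[9+c]`` with ``x`` the voxel
    coordinates centered on the volume (so zero parameters give the zero
    field and the translation is decoupled from the linear part).
    """
    cc = centered_coords  # (3, nx, ny, nz)
    lin = p.data[:9].reshape(3, 3)
    disp = np.einsum("cj,jxyz->cxyz", lin, cc) + p.data[9:, None, None, None]
    out = Tensor(disp, (p,))

    def bw(g):
        gl = np.einsum("cxyz,jxyz->cj", g, cc).reshape(9)
        gt = g.sum(axis=(1, 2, 3))
        p.accum(np.concatenate([gl, gt]))

    out.bw = bw
    return out


def smooth3(x: Tensor, sigma: float) -> Tensor:
    """Gaussian smoothing of each channel (zero padding; self-adjoint)."""
    from scipy import ndimage

    def blur(a):
        return np.stack([ndimage.gaussian_filter(a[c], sigma, mode="constant")
                         for c in range(a.shape[0])], axis=0)

    out = Tensor(blur(x.data), (x,))
    out.bw = lambda g: x.accum(blur(g))
    return out


def _lerp_axis(x: np.ndarray, axis: int, out_len: int, factor: float):
    """Linear interpolation along one axis at block-center-aligned positions
    ``(i - (factor-1)/2) / factor`` (edge clamp), matching average pooling."""
    d = x.shape[axis]
    s = (np.arange(out_len, dtype=np.float64) - (factor - 1) / 2.0) / factor
    i0 = np.floor(s).astype(np.int64)
    i0 = np.clip(i0, 0, d - 1)
    i1 = np.minimum(i0 + 1, d - 1)
    wgt = np.clip(s - i0, 0.0, 1.0)
    xa = np.moveaxis(x, axis, 0)
    shape = (out_len,) + (1,) * (xa.ndim - 1)
    wv = wgt.reshape(shape)
    ya = xa[i0] * (1.0 - wv) + xa[i1] * wv
    return np.moveaxis(ya, 0, axis), (i0, i1, wgt, d)


def upsample3(x: Tensor, factor: int, out_shape: Tuple[int, int, int]) -> Tensor:
    """Separable trilinear upsampling of ``(C, dx, dy, dz)`` to ``(C, *out_shape)``."""
    y = x.data
    meta = []
    for ax in range(3):
        y, m = _lerp_axis(y, ax + 1, out_shape[ax], float(factor))
        meta.append(m)
    out = Tensor(y, (x,))

    def bw(g):
        for ax in (2, 1, 0):
            i0, i1, wgt, d = meta[ax]
            ga = np.moveaxis(g, ax + 1, 0)
            buf = np.zeros((d,) + ga.shape[1:])
            shape = (len(wgt),) + (1,) * (ga.ndim - 1)
            wv = wgt.reshape(shape)
            np.add.at(buf, i0, ga * (1.0 - wv))
            np.add.at(buf, i1, ga * wv)
            g = np.moveaxis(buf, 0, ax + 1)
        x.accum(g)

    out.bw = bw
    return out


def warp(img: Tensor | np.ndarray, disp: Tensor) -> Tensor:
    """Differentiable pull-resampling: ``out[v] = img(v + disp[:, v])``.

    Out-of-bounds samples are zero (the image is conceptually zero-padded).
    Gradients flow into ``disp`` via the analytic trilinear derivative and
    into ``img`` (trilinear scatter) when it requires them.
    """
    img_t = img if isinstance(img, Tensor) else Tensor(img)
    shape = img_t.data.shape
    base = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                                indexing="ij"), axis=0)
    coords = base + disp.data  # (3, nx, ny, nz)
    padded = np.pad(img_t.data, 1)
    cp = coords + 1.0
    i0 = np.floor(cp).astype(np.int64)
    np.clip(i0, 0, np.array(shape).reshape(3, 1, 1, 1), out=i0)
    frac = np.clip(cp - i0, 0.0, 1.0)
    ix0, iy0, iz0 = i0
    ix1, iy1, iz1 = ix0 + 1, iy0 + 1, iz0 + 1
    fx, fy, fz = frac
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz

    c000 = padded[ix0, iy0, iz0]
    c001 = padded[ix0, iy0, iz1]
    c010 = padded[ix0, iy1, iz0]
    c011 = padded[ix0, iy1, iz1]
    c100 = padded[ix1, iy0, iz0]
    c101 = padded[ix1, iy0, iz1]
    c110 = padded[ix1, iy1, iz0]
    c111 = padded[ix1, iy1, iz1]

    w000 = gx * gy * gz
    w001 = gx * gy * fz
    w010 = gx * fy * gz
    w011 = gx * fy * fz
    w100 = fx * gy * gz
    w101 = fx * gy * fz
    w110 = fx * fy * gz
    w111 = fx * fy * fz

    val = (c000 * w000 + c001 * w001 + c010 * w010 + c011 * w011
           + c100 * w100 + c101 * w101 + c110 * w110 + c111 * w111)
    out = Tensor(val, (img_t, disp))

    def bw(g):
        if disp.requires_grad:
            dx = ((c100 - c000) * gy * gz + (c101 - c001) * gy * fz
                  + (c110 - c010) * fy * gz + (c111 - c011) * fy * fz)
            dy = ((c010 - c000) * gx * gz + (c011 - c001) * gx * fz
                  + (c110 - c100) * fx * gz + (c111 - c101) * fx * fz)
            dz = ((c001 - c000) * gx * gy + (c011 - c010) * gx * fy
                  + (c101 - c100) * fx * gy + (c111 - c110) * fx * fy)
            disp.accum(np.stack([dx * g, dy * g, dz * g], axis=0))
        if img_t.requires_grad:
            buf = np.zeros_like(padded)
            np.add.at(buf, (ix0, iy0, iz0), g * w000)
            np.add.at(buf, (ix0, iy0, iz1), g * w001)
            np.add.at(buf, (ix0, iy1, iz0), g * w010)
            np.add.at(buf, (ix0, iy1, iz1), g * w011)
            np.add.at(buf, (ix1, iy0, iz0), g * w100)
            np.add.at(buf, (ix1, iy0, iz1), g * w101)
            np.add.at(buf, (ix1, iy1, iz0), g * w110)
            np.add.at(buf, (ix1, iy1, iz1), g * w111)
            img_t.accum(buf[1:-1, 1:-1, 1:-1])

    out.bw = bw
    return out


def ncc_loss(a: Tensor, b: np.ndarray) -> Tensor:
    """``1 - global normalized cross-correlation`` (0 for a perfect match).

    A zero-variance image on either side yields the guard value 1 with zero
    gradient (correlation is undefined there).
    """
    av = a.data.ravel()
    bv = np.asarray(b, dtype=np.float64).ravel()
    ac = av - av.mean()
    bc = bv - bv.mean()
    a2 = float(ac @ ac)
    b2 = float(bc @ bc)
    if a2 <= 0.0 or b2 <= 0.0:
        return Tensor(1.0, (a,), bw=lambda g: None)
    den = np.sqrt(a2 * b2)
    num = float(ac @ bc)
    out = Tensor(1.0 - num / den, (a,))

    def bw(g):
        ga = -(bc / den - (num / (a2 * den)) * ac)
        ga -= ga.mean()
        a.accum((float(g) * ga).reshape(a.data.shape))

    out.bw = bw
    return out


def mse_loss(a: Tensor, b: np.ndarray) -> Tensor:
    diff = a.data - np.asarray(b, dtype=np.float64)
    out = Tensor(float((diff**2).mean()), (a,))
    out.bw = lambda g: a.accum(float(g) * 2.0 * diff / diff.size)
    return out


def diffusion_reg(disp: Tensor) -> Tensor:
    """Mean squared forward difference over all components and axes."""
    diffs = []
    total = 0
    for ax in (1, 2, 3):
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        d = disp.data[tuple(sl_hi)] - disp.data[tuple(sl_lo)]
        diffs.append((ax, d))
        total += d.size
    value = sum(float((d**2).sum()) for _, d in diffs) / total
    out = Tensor(value, (disp,))

    def bw(g):
        gd = np.zeros_like(disp.data)
        for ax, d in diffs:
            sl_hi = [slice(None)] * 4
            sl_lo = [slice(None)] * 4
            sl_hi[ax] = slice(1, None)
            sl_lo[ax] = slice(None, -1)
            gd[tuple(sl_hi)] += 2.0 * d / total
            gd[tuple(sl_lo)] -= 2.0 * d / total
        disp.accum(float(g) * gd)

    out.bw = bw
    return out


class Adam:
    """Standard Adam with bias correction; state is part of the checkpoint."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
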