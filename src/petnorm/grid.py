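"""Resampling and deformation-field numerics shared across modules.

All resampling uses pull semantics on the output grid: the value at output
voxel ``v`` is the input image interpolated at ``v + disp[v]`` (or at a
transformed coordinate).  Out-of-bounds samples are zero for images and
edge-clamped for fields.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage


def grid_coords(shape: Tuple[int, int, int]) -> np.ndarray:
    """Voxel-index coordinate array of shape ``(nx, ny, nz, 3)``."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def sample_trilinear(image: np.ndarray, coords: np.ndarray, *, oob_zero: bool = True) -> np.ndarray:
    """Trilinear interpolation of ``image`` at fractional voxel ``coords``.

    ``coords`` has shape ``(..., 3)``.  With ``oob_zero`` the image is
    treated as zero-padded: samples near the border interpolate against
    zeros and fade out continuously (the same convention as the training
    warp); otherwise coordinates are clamped to the edge.
    """
    if not oob_zero:
        pts = np.moveaxis(coords, -1, 0).reshape(3, -1)
        out = ndimage.map_coordinates(image, pts, order=1, mode="nearest")
        return out.reshape(coords.shape[:-1])
    shape = np.asarray(image.shape)
    padded = np.pad(image, 1)
    cp = coords + 1.0
    i0 = np.floor(cp).astype(np.int64)
    i0 = np.clip(i0, 0, shape)  # padded grid has extent shape+2
    frac = np.clip(cp - i0, 0.0, 1.0)
    ix0, iy0, iz0 = i0[..., 0], i0[..., 1], i0[..., 2]
    fx, fy, fz = frac[..., 0], frac[..., 1], frac[..., 2]
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz
    out = (padded[ix0, iy0, iz0] * gx * gy * gz
           + padded[ix0, iy0, iz0 + 1] * gx * gy * fz
           + padded[ix0, iy0 + 1, iz0] * gx * fy * gz
           + padded[ix0, iy0 + 1, iz0 + 1] * gx * fy * fz
           + padded[ix0 + 1, iy0, iz0] * fx * gy * gz
           + padded[ix0 + 1, iy0, iz0 + 1] * fx * gy * fz
           + padded[ix0 + 1, iy0 + 1, iz0] * fx * fy * gz
           + padded[ix0 + 1, iy0 + 1, iz0 + 1] * fx * fy * fz)
    return out


def sample_nearest(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Nearest-neighbour interpolation (for label maps)."""
    pts = np.moveaxis(coords, -1, 0).reshape(3, -1)
    out = ndimage.map_coordinates(image, pts, order=0, mode="constant", cval=0.0)
    return out.reshape(coords.shape[:-1]).astype(image.dtype)


def warp_array(image: np.ndarray, disp: np.ndarray, *, interpolation: str = "trilinear") -> np.ndarray:
    """Resample ``image`` through displacement ``disp`` (shape ``(*grid, 3)``)."""
    coords = grid_coords(disp.shape[:3]) + disp
    if interpolation == "trilinear":
        return sample_trilinear(image, coords)
    if interpolation == "nearest":
        return sample_nearest(image, coords)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def jacobian_determinant(disp: np.ndarray) -> np.ndarray:
    """Determinant of ``I + grad(disp)`` at interior voxels.

    Central differences on the interior grid; returned array has shape
    ``(nx-2, ny-2, nz-2)``.  Positive values everywhere mean the map
    ``v -> v + disp(v)`` is locally orientation-preserving.
    """
    core = (slice(1, -1),) * 3
    J = np.empty((*np.asarray(disp.shape[:3]) - 2, 3, 3))
    for c in range(3):
        gx, gy, gz = np.gradient(disp[..., c])
        J[..., c, 0] = gx[core]
        J[..., c, 1] = gy[core]
        J[..., c, 2] = gz[core]
    J[..., 0, 0] += 1.0
    J[..., 1, 1] += 1.0
    J[..., 2, 2] += 1.0
    return np.linalg.det(J)


def invert_displacement(disp: np.ndarray, iterations: int = 20) -> np.ndarray:
    """Fixed-point inverse of a displacement field.

    Finds ``h`` with ``h(v) = -disp(v + h(v))`` so that ``(id+h)`` is the
    inverse of ``(id+disp)``.  Converges for the smooth, Jacobian-positive
    fields produced by the phantom generator.
    """
    base = grid_coords(disp.shape[:3])
    h = np.zeros_like(disp)
    for _ in range(iterations):
        pts = base + h
        for c in range(3):
            h[..., c] = -sample_trilinear(disp[..., c], pts, oob_zero=False)
    return h


def compose_displacements(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Displacement of ``v -> v + inner(v) + outer(v + inner(v))``.

    Resampling an image through the returned field is (up to interpolation of
    ``outer``) identical to warping first by ``outer`` and then by ``inner``.
    """
    pts = grid_coords(inner.shape[:3]) + inner
    out = np.empty_like(inner)
    for c in range(3):
        out[..., c] = inner[..., c] + sample_trilinear(outer[..., c], pts, oob_zero=False)
    return out


def endpoint_error(pred: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean Euclidean distance between two displacement fields.

    When ``mask`` is given the mean is restricted to those voxels (typically a
    brain mask); otherwise interior voxels (one-voxel border excluded) are
    used, since border displacements are poorly constrained by any similarity.
    """
    err = np.sqrt(((pred - truth) ** 2).sum(axis=-1))
    if mask is None:
        mask = np.zeros(err.shape, dtype=bool)
        mask[1:-1, 1:-1, 1:-1] = True
    return float(err[mask].mean())
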