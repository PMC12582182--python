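"""Classic MR-based normalization pipeline (comparator for the MR-free path).

This is a functional stand-in for the conventional pipeline — rigid PET->MR
coregistration followed by iterative nonlinear MR->template normalization,
with the composed transform applied to the PET in a single resampling.  It
does not reimplement any particular neuroimaging suite's numerics; it plays
the same role (a conventional, MR-dependent comparator) with textbook
components:
multi-start derivative-free rigid registration and a multi-resolution
demons-style field optimization under the same similarity-plus-diffusion
objective the network trains against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize

from . import grid
from .registration import _rotation_matrix, similarity_loss
from .volumes import DeformationField, ShapeError, Volume3D, require_congruent


class MissingMRError(ValueError):
    """The classic pipeline needs an MR; point users to the MR-free path."""


@dataclass
class RigidTransform:
    """Rotation (degrees, about the volume center) plus translation (voxels).

    Pull convention: ``apply(points)`` maps coordinates on the *fixed* grid to
    coordinates in the *moving* volume, so resampling the moving volume at
    ``apply(grid)`` expresses it on the fixed grid.
    """

    angles_deg: Tuple[float, float, float]
    translation: Tuple[float, float, float]
    center: Tuple[float, float, float]

    def matrix(self) -> np.ndarray:
        return _rotation_matrix(np.asarray(self.angles_deg))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(..., 3)`` coordinate array."""
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (points - c) @ self.matrix().T + c + t

    @classmethod
    def from_matrix(cls, rot: np.ndarray, translation: Sequence[float],
                    center: Sequence[float]) -> "RigidTransform":
        """Recover Rx@Ry@Rz Euler angles (degrees) from a rotation matrix."""
        ay = np.degrees(np.arcsin(np.clip(rot[0, 2], -1.0, 1.0)))
        az = np.degrees(np.arctan2(-rot[0, 1], rot[0, 0]))
        ax = np.degrees(np.arctan2(-rot[1, 2], rot[2, 2]))
        return cls((float(ax), float(ay), float(az)),
                   tuple(float(t) for t in translation),
                   tuple(float(c) for c in center))

    def inverse(self) -> "RigidTransform":
        """Exact analytic inverse: x -> R(x-c)+c+t inverts to rotation R^T
        with translation -R^T t about the same center."""
        rinv = self.matrix().T
        t = np.asarray(self.translation)
        return RigidTransform.from_matrix(rinv, (-rinv @ t), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``.

        Both must share the same center.
        """
        if tuple(self.center) != tuple(other.center):
            raise ValueError("can only compose transforms about the same center")
        r = self.matrix() @ other.matrix()
        t = self.matrix() @ np.asarray(other.translation) + np.asarray(self.translation)
        return RigidTransform.from_matrix(r, t, self.center)

    def resample(self, moving: np.ndarray) -> np.ndarray:
        pts = self.apply(grid.grid_coords(moving.shape))
        return grid.sample_trilinear(moving, pts)


def _arr(v) -> np.ndarray:
    return v.data if isinstance(v, Volume3D) else np.asarray(v, dtype=np.float64)


def rigid_coregister(moving: Volume3D | np.ndarray, fixed: Volume3D | np.ndarray,
                     n_starts: int = 4, seed: int = 0) -> RigidTransform:
    """Six-parameter rigid registration maximizing global NCC.

    Powell minimization from the identity plus ``n_starts`` seeded random
    starting points; the best converged optimum wins.  Deterministic given
    the seed.
    """
    mov, fix = _arr(moving), _arr(fixed)
    require_congruent(mov.shape, fix.shape)
    center = tuple((np.asarray(mov.shape, dtype=np.float64) - 1) / 2)

    def cost(p: np.ndarray) -> float:
        rt = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
        return similarity_loss(rt.resample(mov), fix, kind="ncc")

    rng = np.random.default_rng(seed)
    starts = [np.zeros(6)]
    for _ in range(n_starts):
        starts.append(np.concatenate([rng.uniform(-10, 10, 3), rng.uniform(-4, 4, 3)]))
    best = None
    for s in starts:
        res = optimize.minimize(cost, s, method="Powell",
                                options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    p = best.x
    return RigidTransform(tuple(p[:3]), tuple(p[3:]), center)


def iterative_normalize(mr: Volume3D | np.ndarray, template: Volume3D | np.ndarray,
                        levels: int = 2, iterations: int = 40,
                        step: float = 1.5, field_sigma: float = 1.5
                        ) -> DeformationField:
    """Multi-resolution demons-style nonlinear registration of MR to template.

    Coarse-to-fine direct optimization of the displacement field: at each
    level the classic demons update
    ``u = (moving_warped - fixed) * grad / (|grad|^2 + diff^2)`` is applied
    and the field Gaussian-smoothed (the diffusion-regularized fixed point).
    Intensities are RMS-normalized first so the SSD force behaves across
    modalities with proportional contrast.  Returns the template->native pull
    field on the template grid.
    """
    mov, fix = _arr(mr), _arr(template)
    require_congruent(mov.shape, fix.shape)
    mov = mov / (np.sqrt((mov**2).mean()) + 1e-12)
    fix = fix / (np.sqrt((fix**2).mean()) + 1e-12)

    disp: Optional[np.ndarray] = None
    for level in range(levels - 1, -1, -1):
        factor = 2**level
        if factor > 1:
            mov_l = ndimage.zoom(mov, 1 / factor, order=1)
            fix_l = ndimage.zoom(fix, 1 / factor, order=1)
        else:
            mov_l, fix_l = mov, fix
        if disp is None:
            disp = np.zeros((*mov_l.shape, 3))
        else:
            scale = np.asarray(mov_l.shape) / np.asarray(disp.shape[:3])
            up = np.stack([ndimage.zoom(disp[..., c], scale, order=1) * scale[c]
                           for c in range(3)], axis=-1)
            disp = up
        for _ in range(iterations):
            warped = grid.warp_array(mov_l, disp)
            diff = warped - fix_l
            grads = np.stack(np.gradient(warped), axis=-1)
            g2 = (grads**2).sum(axis=-1)
            denom = g2 + diff**2 + 1e-9
            update = -step * (diff[..., None] * grads) / denom[..., None]
            disp = disp + update
            for c in range(3):
                disp[..., c] = ndimage.gaussian_filter(disp[..., c], field_sigma)
    return DeformationField(disp)


def run_classic(pet: Volume3D | np.ndarray, mr: Optional[Volume3D | np.ndarray],
                template: Volume3D | np.ndarray, *,
                levels: int = 2, iterations: int = 40, seed: int = 0
                ) -> Tuple[Volume3D | np.ndarray, DeformationField]:
    """Classic pipeline: coregister PET to MR, normalize MR, warp the PET.

    The rigid and nonlinear maps are concatenated in voxel space and the PET
    resampled exactly once through the composed map.  Returns the
    template-space PET and the nonlinear MR->template field.  A missing MR
    raises :class:`MissingMRError` (use :func:`petnorm.registration.normalize`
    for the MR-free path instead).
    """
    if mr is None:
        raise MissingMRError(
            "the classic pipeline requires a structural MR; for PET-only "
            "processing use the MR-free pipeline (registration.normalize)")
    pet_a, mr_a, tpl_a = _arr(pet), _arr(mr), _arr(template)
    require_congruent(pet_a.shape, mr_a.shape, tpl_a.shape)
    rigid = rigid_coregister(pet_a, mr_a, seed=seed)
    field = iterative_normalize(mr_a, tpl_a, levels=levels, iterations=iterations)
    # composed pull map: template voxel v -> MR coord v + disp(v) -> PET coord
    pts = grid.grid_coords(tpl_a.shape) + field.disp
    pet_pts = rigid.apply(pts)
    warped = grid.sample_trilinear(pet_a, pet_pts)
    if isinstance(pet, Volume3D):
        return pet.like(warped), field
    return warped, field
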