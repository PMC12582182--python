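"""Core in-memory containers: volumes, deformation fields, ROI atlases.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based ``(i, j, k)`` along the array axes.
* Deformation fields live on the template grid and use *pull* semantics:
  ``warped[v] = image(v + disp[v])``, i.e. the displacement at a template
  voxel points into the space of the image being resampled (for spatial
  normalization, the native-space image).  Displacements are in voxel units.
* NIfTI-1 is the on-disk format for all volumes and fields (via nibabel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np

#: Canonical ROI roles.  ``Braak12/34/56`` are the composite Braak-stage ROIs,
#: ``metatemporal`` the temporal composite, ``EC`` entorhinal cortex, ``ITG``
#: inferior temporal gyrus, ``cerebellar_gray`` the SUVR reference region.
ROLES = (
    "Braak12",
    "Braak34",
    "Braak56",
    "metatemporal",
    "EC",
    "ITG",
    "cerebellar_gray",
    "background",
)

#: ROI roles quantified by default (everything except the reference/background).
QUANT_ROLES = ("Braak12", "Braak34", "Braak56", "metatemporal", "EC", "ITG")


class ShapeError(ValueError):
    """Grids that were required to be congruent are not."""


@dataclass
class Volume3D:
    """A scalar 3D image on a regular grid.

    Parameters
    ----------
    data:
        3D array of intensities (activity for PET, arbitrary units for MR).
    spacing:
        Physical size of a voxel along each axis, in mm.
    affine:
        4x4 grid-to-world map.  Defaults to a diagonal map built from
        ``spacing``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 8:
            raise ShapeError(f"all dimensions must be >= 8, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.affine is None:
            aff = np.eye(4)
            aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
            self.affine = aff
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)
            if self.affine.shape != (4, 4):
                raise ShapeError("affine must be 4x4")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "Volume3D":
        """A new volume with the same grid metadata but different data."""
        return Volume3D(np.asarray(data), self.spacing, self.affine.copy())

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume3D":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, zooms, np.asarray(img.affine))


@dataclass
class DeformationField:
    """Per-voxel displacement vectors on the template grid (voxel units).

    ``disp`` has shape ``(nx, ny, nz, 3)``; component ``c`` is the displacement
    along array axis ``c``.  Pull semantics: the field maps template voxels to
    native-space coordinates.
    """

    disp: np.ndarray

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ShapeError(f"disp must have shape (nx,ny,nz,3), got {self.disp.shape}")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("deformation field contains non-finite values")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.disp.shape[:3]  # type: ignore[return-value]

    @classmethod
    def zero(cls, shape: Sequence[int]) -> "DeformationField":
        return cls(np.zeros((*shape, 3)))

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean displacement length."""
        return np.sqrt((self.disp**2).sum(axis=-1))

    def save(self, path: str | Path, affine: Optional[np.ndarray] = None) -> None:
        aff = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(self.disp.astype(np.float32), aff), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "DeformationField":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj, dtype=np.float64))


class AtlasSchemaError(ValueError):
    """Malformed atlas label map or role table."""


@dataclass
class ROIAtlas:
    """Integer label map congruent with the template plus label->roles mapping.

    One label per voxel; a label may carry several roles (e.g. the entorhinal
    blob belongs to ``EC``, ``Braak12`` and ``metatemporal``), and composite
    ROIs are voxel-pooled unions of all labels carrying the role.
    """

    labels: np.ndarray
    role_map: Dict[int, Tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int32)
        if self.labels.ndim != 3:
            raise AtlasSchemaError("labels must be a 3D integer grid")
        clean: Dict[int, Tuple[str, ...]] = {}
        for lab, roles in self.role_map.items():
            roles = tuple(roles)
            for r in roles:
                if r not in ROLES:
                    raise AtlasSchemaError(f"unknown ROI role {r!r}")
            clean[int(lab)] = roles
        self.role_map = clean
        present = set(np.unique(self.labels).tolist())
        for lab in present:
            roles = self.role_map.get(int(lab), ())
            if not roles:
                raise AtlasSchemaError(f"label {lab} present in map but carries no role")
        if not self.mask("cerebellar_gray").any():
            raise AtlasSchemaError("cerebellar_gray region is empty")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def labels_for(self, role: str) -> Tuple[int, ...]:
        if role not in ROLES:
            raise AtlasSchemaError(f"unknown ROI role {role!r}")
        return tuple(lab for lab, roles in sorted(self.role_map.items()) if role in roles)

    def mask(self, role: str) -> np.ndarray:
        """Boolean voxel mask of the (possibly composite) ROI with this role."""
        labs = self.labels_for(role)
        if not labs:
            return np.zeros(self.labels.shape, dtype=bool)
        return np.isin(self.labels, labs)

    def save(self, label_path: str | Path, role_path: str | Path,
             affine: Optional[np.ndarray] = None) -> None:
        """Write the label map as NIfTI and the role table as TSV.

        The role table has one row per label with a semicolon-joined role list,
        so it round-trips through :func:`petnorm.quantify.load_atlas`.
        """
        aff = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), str(label_path))
        with open(role_path, "w") as fh:
            fh.write("label\troles\n")
            for lab, roles in sorted(self.role_map.items()):
                fh.write(f"{lab}\t{';'.join(roles)}\n")


@dataclass
class PhantomSubject:
    """One synthetic subject: native-space images plus ground truth.

    ``true_field`` is the template->native pull field that exactly normalizes
    the native images back to template space.  ``true_suvr`` is computed from
    the painted template-space uptake before warping and noise, with the
    cerebellar gray mean as denominator (hence its own SUVR is 1 by
    construction).  Volumes are ``None`` for scores-only cohorts.
    """

    subject_id: str
    stage: str
    true_suvr: Dict[str, float]
    pet_native: Optional[Volume3D] = None
    mr_native: Optional[Volume3D] = None
    true_field: Optional[DeformationField] = None

    def save(self, directory: str | Path) -> None:
        """Write NIfTI volumes and a JSON sidecar with truth and stage."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        if self.pet_native is not None:
            self.pet_native.save(d / f"{self.subject_id}_pet.nii.gz")
        if self.mr_native is not None:
            self.mr_native.save(d / f"{self.subject_id}_mr.nii.gz")
        if self.true_field is not None:
            self.true_field.save(d / f"{self.subject_id}_truefield.nii.gz")
        sidecar = {"subject_id": self.subject_id, "stage": self.stage,
                   "true_suvr": self.true_suvr}
        (d / f"{self.subject_id}.json").write_text(json.dumps(sidecar, indent=1))


@dataclass
class CohortRecord:
    """One visit of one subject: dates and cognitive scores.

    ``cdr_global`` follows the clinical 0/0.5/1/2/3 scale; MMSE and MoCA are
    0-30 (30 best).  The four memory probabilities are latent recall
    probabilities from a wordlist paradigm, consumed as given; nondurable
    recall is bounded by 0.5.
    """

    subject_id: str
    visit: int
    scan_date: int
    exam_date: int
    cdr_global: float
    mmse: float
    moca: float
    immediate_recall_1: float
    delayed_recall_1: float
    recall_nondurable: float
    recall_durable: float

    def __post_init__(self) -> None:
        if self.cdr_global not in (0.0, 0.5, 1.0, 2.0, 3.0):
            raise ValueError(f"cdr_global must be one of 0/0.5/1/2/3, got {self.cdr_global}")
        for name, hi in (("mmse", 30.0), ("moca", 30.0), ("immediate_recall_1", 1.0),
                         ("delayed_recall_1", 1.0), ("recall_nondurable", 0.5),
                         ("recall_durable", 1.0)):
            v = getattr(self, name)
            if not (0.0 <= v <= hi):
                raise ValueError(f"{name}={v} outside [0, {hi}]")


def require_congruent(*shapes: Tuple[int, ...]) -> None:
    """Raise :class:`ShapeError` unless all grid shapes match."""
    first = shapes[0]
    for s in shapes[1:]:
        if tuple(s) != tuple(first):
            raise ShapeError(f"grids are not congruent: {shapes}")
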