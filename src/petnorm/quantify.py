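"""Regional SUVR quantification in template space.

SUVR for an ROI is the mean PET activity over all voxels whose label carries
the ROI role, divided by the mean over the cerebellar-gray voxels.  Composite
ROIs (the Braak-stage and metatemporal unions) pool voxels across their
member labels — voxel-weighted, not an average of per-label means — so a
large member contributes in proportion to its size.  No partial-volume
correction is applied.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .volumes import (AtlasSchemaError, QUANT_ROLES, ROIAtlas, ShapeError,
                      Volume3D)

#: Fixed column schema of SUVR tables (CSV round-trippable).
SUVR_COLUMNS = ("subject_id", "scan_id", "pipeline", "roi_role", "suvr")


class QuantificationError(RuntimeError):
    """Reference region unusable (empty or non-positive mean)."""


def compute_suvr(pet_template_space: Volume3D | np.ndarray, atlas: ROIAtlas,
                 roi_roles: Sequence[str] = QUANT_ROLES, *,
                 subject_id: str = "subject", scan_id: str = "scan",
                 pipeline: str = "mrfree") -> pd.DataFrame:
    """Per-ROI SUVR table for one template-space PET volume.

    An empty ROI yields a missing (NaN) SUVR with a warning; an empty or
    non-positive cerebellar-gray reference raises
    :class:`QuantificationError`.
    """
    pet = pet_template_space.data if isinstance(pet_template_space, Volume3D) \
        else np.asarray(pet_template_space, dtype=np.float64)
    if pet.shape != atlas.shape:
        raise ShapeError(f"PET grid {pet.shape} != atlas grid {atlas.shape}")
    ref_mask = atlas.mask("cerebellar_gray")
    if not ref_mask.any():
        raise QuantificationError("cerebellar gray reference region is empty")
    ref = float(pet[ref_mask].mean())
    if ref <= 0:
        raise QuantificationError(f"cerebellar gray mean must be positive, got {ref}")
    rows = []
    for role in roi_roles:
        mask = atlas.mask(role)
        if not mask.any():
            warnings.warn(f"ROI role {role!r} has no voxels; SUVR set to NaN")
            value = float("nan")
        else:
            value = float(pet[mask].mean()) / ref
        rows.append({"subject_id": subject_id, "scan_id": scan_id,
                     "pipeline": pipeline, "roi_role": role, "suvr": value})
    return pd.DataFrame(rows, columns=list(SUVR_COLUMNS))


def suvr_wide(table: pd.DataFrame, pipeline: Optional[str] = None) -> pd.DataFrame:
    """Pivot a long SUVR table to one row per scan, one column per ROI role."""
    t = table if pipeline is None else table[table["pipeline"] == pipeline]
    return t.pivot_table(index=["subject_id", "scan_id"], columns="roi_role",
                         values="suvr", aggfunc="first")


def load_atlas(label_path: str | Path, role_path: str | Path) -> ROIAtlas:
    """Read an atlas from a NIfTI label map plus a delimited role table.

    The role table (TSV or CSV, sniffed from the header line) needs columns
    ``label`` and ``roles``, the latter a semicolon-separated role list.
    Duplicate label rows, unknown role names, or labels present in the image
    but absent from the table are schema errors.  This is also how a real
    MNI-space Braak/Desikan-Killiany parcellation would be supplied.
    """
    import nibabel as nib

    img = nib.load(str(label_path))
    labels = np.rint(np.asanyarray(img.dataobj)).astype(np.int32)
    text = Path(role_path).read_text().strip().splitlines()
    if not text:
        raise AtlasSchemaError("empty role table")
    sep = "\t" if "\t" in text[0] else ","
    header = [h.strip() for h in text[0].split(sep)]
    if "label" not in header or "roles" not in header:
        raise AtlasSchemaError(f"role table must have 'label' and 'roles' columns, got {header}")
    li, ri = header.index("label"), header.index("roles")
    role_map = {}
    for line in text[1:]:
        parts = [p.strip() for p in line.split(sep)]
        lab = int(parts[li])
        if lab in role_map:
            raise AtlasSchemaError(f"duplicate row for label {lab}")
        role_map[lab] = tuple(r for r in parts[ri].split(";") if r)
    present = set(np.unique(labels).tolist())
    missing = present - set(role_map)
    if missing:
        raise AtlasSchemaError(f"labels {sorted(missing)} present in image but not in role table")
    return ROIAtlas(labels, role_map)
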