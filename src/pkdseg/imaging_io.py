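"""NIfTI input/output and case management.

Volumes are kept in stored voxel order — no canonical reorientation and no
resampling, ever; a geometric mismatch between an image and its mask is an
error.  Images are written as 32-bit float, masks as unsigned 8-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import VoxelGrid3D, BinaryMask3D, GeometryError, check_same_geometry

__all__ = ["Case", "read_case", "write_mask", "write_pair", "read_manifest"]

SPACING_RTOL = 1e-4


@dataclass
class Case:
    """One subject: an image volume and (optionally) its reference mask."""

    case_id: str
    image: VoxelGrid3D
    reference_mask: Optional[BinaryMask3D] = None

    def __post_init__(self):
        if self.reference_mask is not None:
            check_same_geometry(
                self.image, self.reference_mask, rtol=SPACING_RTOL,
                context=f" for case '{self.case_id}'",
            )


def _load_volume(path) -> tuple[np.ndarray, tuple, nib.Nifti1Image]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, img


def read_case(image_path, mask_path=None, case_id: Optional[str] = None) -> Case:
    """Read an image (and optional mask) from NIfTI files.

    Spacing comes from the NIfTI header; mask voxels are binarized by
    ``value > 0``.  A shape or spacing mismatch between image and mask
    raises :class:`GeometryError` rather than resampling.
    """
    data, spacing, _ = _load_volume(image_path)
    grid = VoxelGrid3D(data.astype(np.float32), spacing)
    mask = None
    if mask_path is not None:
        mdata, mspacing, _ = _load_volume(mask_path)
        mask = BinaryMask3D((mdata > 0).astype(np.uint8), mspacing)
    if case_id is None:
        case_id = Path(image_path).name.split(".")[0]
    return Case(case_id, grid, mask)


def _affine_from_spacing(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_image(grid: VoxelGrid3D, out_path) -> Path:
    out_path = Path(out_path)
    img = nib.Nifti1Image(
        np.asarray(grid.values, dtype=np.float32), _affine_from_spacing(grid.spacing_mm)
    )
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, str(out_path))
    return out_path


def write_mask(mask: BinaryMask3D, like_case: Case, out_path) -> Path:
    """Write a mask whose header geometry copies the case's image."""
    check_same_geometry(mask, like_case.image, rtol=SPACING_RTOL,
                        context=f" writing mask for '{like_case.case_id}'")
    out_path = Path(out_path)
    src_affine = _affine_from_spacing(like_case.image.spacing_mm)
    img = nib.Nifti1Image(np.asarray(mask.values, dtype=np.uint8), src_affine)
    img.header.set_zooms(like_case.image.spacing_mm)
    nib.save(img, str(out_path))
    return out_path


def write_pair(grid: VoxelGrid3D, mask: BinaryMask3D, image_path, mask_path):
    """Write a matched image/mask pair (used by the phantom generator)."""
    check_same_geometry(grid, mask, context=" in write_pair")
    write_image(grid, image_path)
    img = nib.Nifti1Image(
        np.asarray(mask.values, dtype=np.uint8), _affine_from_spacing(mask.spacing_mm)
    )
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(mask_path))


def read_manifest(manifest_path, with_masks: bool = True) -> list[Case]:
    """Load every case listed in a manifest CSV (case_id, image_path, ...)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"case_id", "image_path"}
    if not required.issubset(table.columns):
        raise ValueError(f"{manifest_path}: manifest needs columns {sorted(required)}")
    base = manifest_path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    cases = []
    for row in table.itertuples(index=False):
        mask_path = getattr(row, "mask_path", None) if with_masks else None
        if isinstance(mask_path, float) and np.isnan(mask_path):
            mask_path = None
        cases.append(
            read_case(_resolve(row.image_path),
                      _resolve(mask_path) if mask_path is not None else None,
                      case_id=str(row.case_id))
        )
    return cases
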