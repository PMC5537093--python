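"""Core in-memory containers: intensity volumes and binary masks.

Volumes are stored in voxel order as (X, Y, Z) arrays with physical voxel
spacing in millimetres.  Nothing in the package ever resamples or reorients
a volume implicitly; geometry mismatches raise :class:`GeometryError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid3D", "BinaryMask3D", "GeometryError"]


class GeometryError(ValueError):
    """Shape or spacing disagreement between volumes that must align."""


def _check_spacing(spacing):
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class VoxelGrid3D:
    """A 3-D grayscale volume (arbitrary MR-like units) with voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (X, Y, Z)
        Intensity values.
    spacing_mm : tuple of float
        Physical voxel size ``(dx, dy, dz)`` in millimetres.
    """

    values: np.ndarray
    spacing_mm: tuple = field(default=(1.5, 1.5, 3.0))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.values.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self):
        return self.values.shape

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz


@dataclass
class BinaryMask3D:
    """A {0,1} segmentation mask geometrically aligned with an image."""

    values: np.ndarray
    spacing_mm: tuple = field(default=(1.5, 1.5, 3.0))

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={values.ndim}")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, found {uniq[:10]}")
        self.values = values.astype(np.uint8)
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self):
        return self.values.shape

    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz


def check_same_geometry(a, b, rtol: float = 1e-4, context: str = ""):
    """Raise :class:`GeometryError` unless shapes match and spacings agree.

    Spacing is compared with relative tolerance ``rtol`` (header round-trip
    through 32-bit NIfTI fields loses precision).
    """
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch{context}: {a.shape} vs {b.shape}")
    sa, sb = np.asarray(a.spacing_mm), np.asarray(b.spacing_mm)
    if not np.allclose(sa, sb, rtol=rtol, atol=0):
        raise GeometryError(f"spacing mismatch{context}: {tuple(sa)} vs {tuple(sb)}")
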