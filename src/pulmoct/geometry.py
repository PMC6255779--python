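"""Volumetric image and mask containers.

Arrays are indexed ``(i, j, k)`` along ``(x, y, z)``; voxel ``(i, j, k)`` is
centred at ``origin + (i, j, k) * spacing`` (0-based indices, millimetres).
Intensities are Hounsfield Units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageVolume", "BinaryMask", "same_grid", "voxel_volume_mm3"]


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3:
        raise ValueError("spacing must have three components")
    if any(v <= 0 for v in s):
        raise ValueError(f"spacing components must be positive, got {s}")
    return s


def _as_origin(origin) -> tuple[float, float, float]:
    o = tuple(float(v) for v in origin)
    if len(o) != 3:
        raise ValueError("origin must have three components")
    return o


@dataclass
class ImageVolume:
    """A 3-D scalar field in HU with anisotropic voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities in HU. Must be finite.
    spacing : (3,) float
        Voxel size (mm) along x, y, z.
    origin : (3,) float
        Physical position (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (no NaN/Inf)")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical field of view (mm) per axis, counting whole voxel cells."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Index of the voxel whose centre is nearest ``point_mm``, clipped."""
        idx = []
        for ax in range(3):
            i = int(round((point_mm[ax] - self.origin[ax]) / self.spacing[ax]))
            idx.append(min(max(i, 0), self.shape[ax] - 1))
        return tuple(idx)

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        return replace(self, values=values)


@dataclass
class BinaryMask:
    """A 3-D boolean field sharing :class:`ImageVolume` geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if self.values.dtype != bool:
            if not np.isin(self.values, (0, 1)).all():
                raise ValueError("mask values must be boolean or 0/1")
            self.values = self.values.astype(bool)
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    shape = ImageVolume.shape
    voxel_centers = ImageVolume.voxel_centers
    extent_mm = ImageVolume.extent_mm
    index_of = ImageVolume.index_of

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return replace(self, values=np.asarray(values, dtype=bool))


def voxel_volume_mm3(obj) -> float:
    sx, sy, sz = obj.spacing
    return sx * sy * sz


def same_grid(a, b, *, atol: float = 1e-6) -> bool:
    """True if two volumes/masks share shape, spacing and origin (mm tol)."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )
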