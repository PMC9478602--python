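"""Voxel-grid containers: image volumes, dose grids and binary masks.

All grids live in the LPS patient frame (x = patient left, y = posterior,
z = superior).  Array axis order is (x, y, z); voxel indices are 0-based and
the world position of a voxel *center* is ``origin + index * spacing`` (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ValidationError

__all__ = ["ImageVolume", "DoseGrid", "StructureMask", "require_same_grid"]


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing and origin.

    Parameters
    ----------
    values
        Scalar array of shape (nx, ny, nz).  CT volumes hold Hounsfield
        units; dose grids hold cGy.
    spacing
        Voxel size in mm along (x, y, z); all components positive.
    origin
        World position (mm, LPS) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame: str = "LPS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError("values: expected a 3D array")
        if any(s < 1 for s in self.values.shape):
            raise ValidationError("values: every shape component must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing: all components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for (n, 3) index rows."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points; inverse of index_to_world."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (x, y, z) of voxel centers."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        return np.ix_(*axes)  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | StructureMask", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class DoseGrid(ImageVolume):
    """An :class:`ImageVolume` whose values are absorbed dose in cGy (>= 0)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("values: dose must be non-negative everywhere")


@dataclass
class StructureMask:
    """A binary volume aligned to a grid (body, CTV, PTV, OAR, bolus...)."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""
    frame: str = field(default="LPS", repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError("mask: expected a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing: all components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_mm3

    def count(self) -> int:
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def like(self, mask: np.ndarray, name: str = "") -> "StructureMask":
        """A new mask on this grid."""
        return StructureMask(mask, self.spacing, self.origin, name or self.name)

    def same_grid(self, other, tol: float = 1e-6) -> bool:
        return ImageVolume.same_grid(self, other, tol)  # type: ignore[arg-type]

    index_to_world = ImageVolume.index_to_world
    world_to_index = ImageVolume.world_to_index
    coordinate_grids = ImageVolume.coordinate_grids


def require_same_grid(a, b, what: str = "volumes") -> None:
    """Raise :class:`AlignmentError` unless a and b share shape/spacing/origin."""
    if not (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=1e-6)
        and np.allclose(a.origin, b.origin, atol=1e-6)
    ):
        raise AlignmentError(
            f"{what} are not on the same grid: "
            f"{a.shape}/{a.spacing}/{a.origin} vs {b.shape}/{b.spacing}/{b.origin}"
        )
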