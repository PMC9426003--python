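"""Shared voxel-lattice containers.

All volumes in the package live on a common rectilinear lattice with axis
order ``(z, y, x)`` (slice, anterior-posterior, left-right), spacing in
millimetres and 0-based integer indexing.  Lengths exposed to users
(distances, margins, EUL) are in centimetres; dose is in gray.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GridGeometry",
    "StructureMask",
    "DoseGrid",
    "DistanceMap",
    "GeometryMismatchError",
    "EmptyStructureError",
]

MM_PER_CM = 10.0


class GeometryMismatchError(ValueError):
    """Two volumes do not share the same voxel lattice."""


class EmptyStructureError(ValueError):
    """An operation requires a structure with at least one voxel."""


@dataclass(frozen=True)
class GridGeometry:
    """A rectilinear voxel lattice.

    Parameters
    ----------
    shape:
        Number of voxels along ``(z, y, x)``; every entry >= 1.
    spacing_mm:
        Voxel pitch in millimetres along ``(z, y, x)``; every entry > 0.
    origin_mm:
        Physical position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (3.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(s) for s in self.origin_mm)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("shape, spacing_mm and origin_mm must be triples")
        if any(s < 1 for s in shape):
            raise ValueError(f"every shape entry must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"every spacing entry must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing_mm)) / MM_PER_CM**3

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-centre coordinate vectors along z, y, x (mm)."""
        return tuple(
            self.origin_mm[ax] + self.spacing_mm[ax] * np.arange(self.shape[ax])
            for ax in range(3)
        )

    def is_close(self, other: "GridGeometry", tol_mm: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol_mm)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol_mm)
        )


def _require_same_geometry(a, b) -> None:
    if not a.geometry.is_close(b.geometry):
        raise GeometryMismatchError(
            f"geometry mismatch: {a.geometry} vs {b.geometry}"
        )


@dataclass
class StructureMask:
    """Binary occupancy of one structure (organ, target, assistant) on a grid."""

    geometry: GridGeometry
    voxels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        if voxels.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {voxels.shape} does not match grid {self.geometry.shape}"
            )
        self.voxels = voxels.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.geometry.voxel_volume_cm3

    def union(self, other: "StructureMask", label: str = "") -> "StructureMask":
        _require_same_geometry(self, other)
        return StructureMask(self.geometry, self.voxels | other.voxels, label)

    def intersection(self, other: "StructureMask", label: str = "") -> "StructureMask":
        _require_same_geometry(self, other)
        return StructureMask(self.geometry, self.voxels & other.voxels, label)

    def difference(self, other: "StructureMask", label: str = "") -> "StructureMask":
        _require_same_geometry(self, other)
        return StructureMask(self.geometry, self.voxels & ~other.voxels, label)

    def relabel(self, label: str) -> "StructureMask":
        return replace(self, label=label)


@dataclass
class DoseGrid:
    """Per-voxel absorbed dose in Gy on a shared lattice."""

    geometry: GridGeometry
    values_gy: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values_gy, dtype=float)
        if values.shape != self.geometry.shape:
            raise ValueError(
                f"dose shape {values.shape} does not match grid {self.geometry.shape}"
            )
        if not np.isfinite(values).all():
            raise ValueError("dose grid contains non-finite values")
        if (values < 0).any():
            raise ValueError("dose grid contains negative values")
        self.values_gy = values

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.geometry, self.values_gy * float(factor))

    def in_structure(self, mask: StructureMask) -> np.ndarray:
        """Doses of the voxels occupied by ``mask`` (1-D array, Gy)."""
        _require_same_geometry(self, mask)
        if mask.is_empty:
            raise EmptyStructureError(f"structure {mask.label!r} is empty")
        return self.values_gy[mask.voxels]


@dataclass
class DistanceMap:
    """Per-voxel shortest centre-to-centre distance to a source structure, cm.

    Zero exactly on voxels inside the source; the anisotropic voxel spacing
    is respected everywhere else.
    """

    geometry: GridGeometry
    values_cm: np.ndarray
    source_label: str = "PTV"

    def __post_init__(self) -> None:
        values = np.asarray(self.values_cm, dtype=float)
        if values.shape != self.geometry.shape:
            raise ValueError(
                f"distance-map shape {values.shape} does not match grid "
                f"{self.geometry.shape}"
            )
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("distance map must be finite and non-negative")
        self.values_cm = values

    def in_structure(self, mask: StructureMask) -> np.ndarray:
        """Distances of the voxels occupied by ``mask`` (1-D array, cm)."""
        _require_same_geometry(self, mask)
        if mask.is_empty:
            raise EmptyStructureError(f"structure {mask.label!r} is empty")
        return self.values_cm[mask.voxels]
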