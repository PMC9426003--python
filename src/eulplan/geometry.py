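"""Voxel-grid geometry: distance maps, the EUL metric and assistant structures.

The equivalent uniform length (EUL) summarises how far an organ at risk sits
from the planning target volume (PTV).  Every organ voxel ``i`` is assigned
``L_i``, its shortest Euclidean distance to the PTV (zero inside the PTV),
and the EUL of order ``a`` is the power mean ``(mean(L_i^a))^(1/a)``.  With
``a = 1`` this is the arithmetic mean distance; it plays the same role for
geometry that gEUD plays for dose, and is the regressor of the
knowledge-based EUD prediction models in :mod:`eulplan.models`.

The module also provides the morphological building blocks used to derive
the six assistant structures (AS1-AS6) that shape the dose fall-off around
the PTV during optimization: isotropic expansion, half-open ring shells and
the 40%-isodose preliminary assistant structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._power_mean import power_mean
from .grid import (
    MM_PER_CM,
    DistanceMap,
    DoseGrid,
    EmptyStructureError,
    GeometryMismatchError,
    StructureMask,
)

__all__ = [
    "distance_map",
    "compute_eul",
    "dilate",
    "ring",
    "preliminary_as",
    "generate_assistant_structures",
    "ASSet",
]


def distance_map(ptv: StructureMask) -> DistanceMap:
    """Shortest centre-to-centre distance from every voxel to the PTV, in cm.

    Computed with an anisotropic Euclidean distance transform; voxels inside
    the PTV are at distance zero.
    """
    if ptv.is_empty:
        raise EmptyStructureError(
            f"cannot build a distance map from empty source {ptv.label!r}"
        )
    dist_mm = ndimage.distance_transform_edt(
        ~ptv.voxels, sampling=ptv.geometry.spacing_mm
    )
    return DistanceMap(ptv.geometry, dist_mm / MM_PER_CM, source_label=ptv.label)


def compute_eul(dmap: DistanceMap, oar: StructureMask, a: float = 1.0) -> float:
    """Equivalent uniform length of an organ, cm.

    ``EUL = (mean over organ voxels of L_i^a)^(1/a)`` where ``L_i`` is the
    shortest distance from the PTV to voxel ``i``.  Organ voxels inside the
    PTV contribute ``L_i = 0`` (they are not excluded from the mean), so
    ``a < 0`` requires the organ and PTV to be disjoint.
    """
    distances = dmap.in_structure(oar)
    return power_mean(distances, a)


def _distance_mm_from(mask: StructureMask) -> np.ndarray:
    return ndimage.distance_transform_edt(
        ~mask.voxels, sampling=mask.geometry.spacing_mm
    )


def dilate(mask: StructureMask, margin_cm: float, label: str = "") -> StructureMask:
    """Isotropic expansion: all voxels within ``margin_cm`` of the structure.

    A voxel belongs to the result iff its centre-to-centre distance to the
    nearest structure voxel is <= ``margin_cm``; margin 0 is the identity.
    """
    if margin_cm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_cm}")
    if mask.is_empty:
        raise EmptyStructureError(f"cannot dilate empty structure {mask.label!r}")
    if margin_cm == 0:
        return StructureMask(mask.geometry, mask.voxels.copy(), label or mask.label)
    dist_mm = _distance_mm_from(mask)
    return StructureMask(
        mask.geometry, dist_mm <= margin_cm * MM_PER_CM, label or mask.label
    )


def ring(
    ptv: StructureMask, inner_cm: float, outer_cm: float, label: str = ""
) -> StructureMask:
    """Half-open shell around a structure: ``inner_cm < distance <= outer_cm``.

    Inner-exclusive / outer-inclusive, so stepped rings tile without overlap
    and any ring with ``inner_cm >= 0`` is disjoint from the source.
    """
    if inner_cm < 0:
        raise ValueError(f"inner margin must be >= 0, got {inner_cm}")
    if inner_cm >= outer_cm:
        raise ValueError(
            f"ring requires inner < outer, got inner={inner_cm}, outer={outer_cm}"
        )
    if ptv.is_empty:
        raise EmptyStructureError(f"cannot ring empty structure {ptv.label!r}")
    dist_mm = _distance_mm_from(ptv)
    shell = (dist_mm > inner_cm * MM_PER_CM) & (dist_mm <= outer_cm * MM_PER_CM)
    return StructureMask(ptv.geometry, shell, label)


def preliminary_as(
    dose: DoseGrid,
    body: StructureMask,
    rx_gy: float,
    fraction: float = 0.4,
) -> StructureMask:
    """Preliminary assistant structure: body voxels at or above an isodose.

    The threshold is ``fraction`` of the prescription (default the 40%
    isodose of a simple parallel-opposed setup-beam dose).
    """
    if rx_gy <= 0:
        raise ValueError(f"prescription must be > 0 Gy, got {rx_gy}")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if not dose.geometry.is_close(body.geometry):
        raise GeometryMismatchError("dose and body are on different grids")
    hot = dose.values_gy >= fraction * rx_gy
    return StructureMask(dose.geometry, hot & body.voxels, "preliminary_AS")


@dataclass
class ASSet:
    """The six assistant structures plus the preliminary structure they refine.

    AS1..AS6 are pairwise disjoint and none intersects the PTV expanded by
    0.5 cm; together they partition the dose-shaping region into shells of
    increasing distance from the target.
    """

    as1: StructureMask
    as2: StructureMask
    as3: StructureMask
    as4: StructureMask
    as5: StructureMask
    as6: StructureMask
    preliminary: StructureMask

    def __iter__(self):
        return iter((self.as1, self.as2, self.as3, self.as4, self.as5, self.as6))

    def as_dict(self) -> dict[str, StructureMask]:
        return {f"AS{i}": m for i, m in enumerate(self, start=1)}

    def validate(self, ptv: StructureMask) -> None:
        """Raise if disjointness or PTV-avoidance is violated."""
        overlap_count = np.zeros(self.as1.geometry.shape, dtype=np.int8)
        for m in self:
            overlap_count += m.voxels
        if (overlap_count > 1).any():
            raise ValueError("assistant structures overlap")
        expanded = dilate(ptv, 0.5)
        for name, m in self.as_dict().items():
            if (m.voxels & expanded.voxels).any():
                raise ValueError(f"{name} intersects the 0.5 cm-expanded PTV")


# (inner, outer) margins in cm of the five ring shells used by AS1..AS5:
# two 0.5 cm steps from 0.5 to 1.5 cm, then three 1 cm steps to 4.5 cm.
_AS_SHELLS_CM = ((0.5, 1.0), (1.0, 1.5), (1.5, 2.5), (2.5, 3.5), (3.5, 4.5))


def generate_assistant_structures(
    ptv: StructureMask, prelim: StructureMask
) -> ASSet:
    """Derive assistant structures AS1-AS6 from the PTV and the preliminary AS.

    AS1 and AS2 are the overlaps of the preliminary structure with 0.5 cm
    rings out to 1.5 cm; AS3-AS5 continue with 1 cm rings out to 4.5 cm.
    AS4 additionally receives the part of the outermost (3.5-4.5 cm) ring
    that lies outside the preliminary structure, and AS6 is the remainder of
    the preliminary structure beyond the 0.5 cm PTV expansion.
    """
    if not ptv.geometry.is_close(prelim.geometry):
        raise GeometryMismatchError("PTV and preliminary AS are on different grids")
    if ptv.is_empty:
        raise EmptyStructureError("PTV is empty")

    dist_mm = _distance_mm_from(ptv)

    def shell(inner_cm: float, outer_cm: float) -> np.ndarray:
        return (dist_mm > inner_cm * MM_PER_CM) & (dist_mm <= outer_cm * MM_PER_CM)

    shells = [shell(*bounds) for bounds in _AS_SHELLS_CM]
    p = prelim.voxels
    as_voxels = [s & p for s in shells]
    # AS4's extra part: the outermost shell outside the preliminary AS.
    as_voxels[3] = as_voxels[3] | (shells[4] & ~p)
    expanded_ptv = dist_mm <= 0.5 * MM_PER_CM  # includes the PTV itself
    as6 = p & ~expanded_ptv
    for v in as_voxels:
        as6 &= ~v

    geom = ptv.geometry
    masks = [
        StructureMask(geom, v, f"AS{i}") for i, v in enumerate(as_voxels, start=1)
    ]
    result = ASSet(*masks, StructureMask(geom, as6, "AS6"), preliminary=prelim)
    return result
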