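"""Volume file I/O (NRRD / NIfTI) and per-case manifests.

Volumes are read and written through SimpleITK so spacing and origin travel
in the file header; arrays are exposed in this package's ``(z, y, x)`` axis
order.  File headers keep the imaging convention (millimetres); all
user-facing lengths elsewhere are centimetres.  A case manifest is a small
JSON file mapping structure labels to volume files plus the dose file and
prescription metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .grid import DoseGrid, GeometryMismatchError, GridGeometry, StructureMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "CaseManifest",
    "load_case",
]

logger = logging.getLogger(__name__)

_SUPPORTED_SUFFIXES = (".nrrd", ".nii", ".nii.gz")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported volume format {path.name!r}; expected one of "
            f"{_SUPPORTED_SUFFIXES}"
        )


def read_volume(path: str | Path) -> tuple[GridGeometry, np.ndarray]:
    """Read an NRRD or NIfTI volume as ``(geometry, (z, y, x) array)``."""
    path = Path(path)
    _check_suffix(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {img.GetDimension()}-D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path}: only axis-aligned (identity-direction) volumes are supported"
        )
    values = sitk.GetArrayFromImage(img)  # (z, y, x)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: volume contains NaN or infinite voxels")
    geometry = GridGeometry(
        shape=values.shape,
        spacing_mm=img.GetSpacing()[::-1],
        origin_mm=img.GetOrigin()[::-1],
    )
    return geometry, values


def write_volume(
    path: str | Path, geometry: GridGeometry, values: np.ndarray
) -> None:
    """Write a ``(z, y, x)`` array with its lattice geometry to NRRD/NIfTI.

    Masks should be passed as integer arrays (bit-exact round-trip); doses
    are written as float64 (lossless round-trip).
    """
    path = Path(path)
    _check_suffix(path)
    values = np.asarray(values)
    if values.shape != geometry.shape:
        raise ValueError(
            f"array shape {values.shape} does not match grid {geometry.shape}"
        )
    if values.dtype == bool:
        values = values.astype(np.uint8)
    img = sitk.GetImageFromArray(values)
    img.SetSpacing(tuple(geometry.spacing_mm[::-1]))
    img.SetOrigin(tuple(geometry.origin_mm[::-1]))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path, label: str = "") -> StructureMask:
    geometry, values = read_volume(path)
    unique = np.unique(values)
    if not np.isin(unique, (0, 1)).all():
        raise ValueError(f"{path}: mask voxels must be 0/1, found {unique[:5]}")
    return StructureMask(geometry, values.astype(bool), label)


def write_mask(path: str | Path, mask: StructureMask) -> None:
    write_volume(path, mask.geometry, mask.voxels.astype(np.uint8))


def read_dose(path: str | Path) -> DoseGrid:
    geometry, values = read_volume(path)
    return DoseGrid(geometry, values.astype(float))


def write_dose(path: str | Path, dose: DoseGrid) -> None:
    write_volume(path, dose.geometry, dose.values_gy.astype(np.float64))


@dataclass
class CaseManifest:
    """Files and prescription metadata of one case.

    Paths inside the manifest are resolved relative to the manifest file.
    """

    case_id: str
    volumes: dict[str, str]  # label -> volume path
    dose: str | None = None
    prescription_gy: float = 59.4
    fractions: int = 33
    root: Path = field(default_factory=Path)

    @classmethod
    def load(cls, path: str | Path) -> "CaseManifest":
        path = Path(path)
        payload = json.loads(path.read_text())
        for key in ("case_id", "volumes"):
            if key not in payload:
                raise ValueError(f"{path}: manifest missing field {key!r}")
        return cls(
            case_id=str(payload["case_id"]),
            volumes={str(k): str(v) for k, v in payload["volumes"].items()},
            dose=payload.get("dose"),
            prescription_gy=float(payload.get("prescription_gy", 59.4)),
            fractions=int(payload.get("fractions", 33)),
            root=path.parent,
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "case_id": self.case_id,
            "prescription_gy": self.prescription_gy,
            "fractions": self.fractions,
            "volumes": self.volumes,
        }
        if self.dose is not None:
            payload["dose"] = self.dose
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_case(
    manifest: CaseManifest | str | Path,
) -> tuple[dict[str, StructureMask], DoseGrid | None, CaseManifest]:
    """Load all volumes of a case and verify they share one lattice."""
    if not isinstance(manifest, CaseManifest):
        manifest = CaseManifest.load(manifest)
    masks: dict[str, StructureMask] = {}
    reference: tuple[str, GridGeometry] | None = None

    def check(name: str, geometry: GridGeometry) -> None:
        nonlocal reference
        if reference is None:
            reference = (name, geometry)
        elif not reference[1].is_close(geometry):
            raise GeometryMismatchError(
                f"case {manifest.case_id}: {name!r} and {reference[0]!r} are on "
                "different voxel lattices"
            )

    for label, rel in manifest.volumes.items():
        mask = read_mask(manifest.root / rel, label=label)
        check(rel, mask.geometry)
        masks[label] = mask
    dose = None
    if manifest.dose is not None:
        dose = read_dose(manifest.root / manifest.dose)
        check(manifest.dose, dose.geometry)
    return masks, dose, manifest
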