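"""Dose metrics on voxel grids: gEUD, DVH curves and plan-quality indices.

The generalized equivalent uniform dose is the power mean of the per-voxel
doses of an organ, ``gEUD = (mean(D_i^a))^(1/a)``; ``a = 1`` gives the mean
dose, large ``a`` weights hot spots and large negative ``a`` cold spots.
All volume metrics (Vx, D95, HI, CI) are computed by exact voxel counting
rather than interpolation of a binned DVH.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._power_mean import power_mean
from .grid import DoseGrid, EmptyStructureError, StructureMask

__all__ = [
    "compute_geud",
    "compute_dvh",
    "v_at_dose",
    "d_at_volume",
    "homogeneity_index",
    "conformity_index",
    "normalize_plan",
    "plan_metrics",
    "DVHCurve",
    "PlanMetrics",
]

logger = logging.getLogger(__name__)

PTV_LABEL = "PTV"
#: OAR Vx thresholds reported for pelvic plans, Gy.
OAR_V_LEVELS_GY = (20.0, 30.0, 40.0, 50.0, 60.0)


def compute_geud(dose: DoseGrid, organ: StructureMask, a: float = 1.0) -> float:
    """Generalized equivalent uniform dose of an organ, Gy."""
    return power_mean(dose.in_structure(organ), a)


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one organ.

    ``cum_volume_pct[k]`` is the percentage of organ volume receiving at
    least ``dose_edges_gy[k]``; the curve starts at 100% for a nonempty
    organ and reaches 0% at an edge above the organ maximum.  The sorted
    per-voxel doses are retained so point queries can count voxels exactly.
    """

    dose_edges_gy: np.ndarray
    cum_volume_pct: np.ndarray
    doses_sorted_gy: np.ndarray = field(repr=False)
    organ: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges_gy, float)
        vol = np.asarray(self.cum_volume_pct, float)
        if edges.ndim != 1 or edges.shape != vol.shape:
            raise ValueError("edges and volumes must be 1-D arrays of equal length")
        if (np.diff(edges) <= 0).any() or edges[0] != 0:
            raise ValueError("dose edges must be ascending and start at 0")
        if (np.diff(vol) > 1e-12).any():
            raise ValueError("cumulative volume must be non-increasing")
        self.dose_edges_gy = edges
        self.cum_volume_pct = vol
        self.doses_sorted_gy = np.asarray(self.doses_sorted_gy, float)


def compute_dvh(
    dose: DoseGrid, organ: StructureMask, bin_gy: float = 0.1, label: str | None = None
) -> DVHCurve:
    """Cumulative DVH of ``organ`` with the given dose-bin width."""
    if bin_gy <= 0:
        raise ValueError(f"bin width must be > 0 Gy, got {bin_gy}")
    doses = np.sort(dose.in_structure(organ))
    n = doses.size
    d_max = doses[-1]
    n_edges = int(math.floor(d_max / bin_gy)) + 2  # last edge strictly > max
    edges = bin_gy * np.arange(n_edges)
    counts = n - np.searchsorted(doses, edges, side="left")
    return DVHCurve(
        dose_edges_gy=edges,
        cum_volume_pct=100.0 * counts / n,
        doses_sorted_gy=doses,
        organ=label if label is not None else organ.label,
    )


def v_at_dose(dvh: DVHCurve, d_gy: float) -> float:
    """Percent of organ volume receiving at least ``d_gy`` (exact count)."""
    doses = dvh.doses_sorted_gy
    n = doses.size
    return 100.0 * (n - np.searchsorted(doses, d_gy, side="left")) / n


def d_at_volume(dvh: DVHCurve, v_pct: float) -> float:
    """Largest dose received by at least ``v_pct`` percent of the volume, Gy.

    ``d_at_volume(dvh, 95)`` is D95; ``v_pct = 0`` returns the maximum dose.
    """
    if not 0 <= v_pct <= 100:
        raise ValueError(f"volume percentage must be in [0, 100], got {v_pct}")
    doses = dvh.doses_sorted_gy
    n = doses.size
    if v_pct == 0:
        return float(doses[-1])
    k = math.ceil(v_pct / 100.0 * n)  # need >= k voxels at or above the answer
    return float(doses[n - k])


def _dvh_of(dose: DoseGrid, organ: StructureMask) -> DVHCurve:
    return compute_dvh(dose, organ)


def homogeneity_index(dose: DoseGrid, ptv: StructureMask) -> float:
    """PTV dose homogeneity, ``HI = (D2% - D98%) / D50%`` (0 = uniform)."""
    dvh = _dvh_of(dose, ptv)
    d50 = d_at_volume(dvh, 50)
    if d50 == 0:
        raise ValueError("median PTV dose is zero; HI undefined")
    return (d_at_volume(dvh, 2) - d_at_volume(dvh, 98)) / d50


def conformity_index(dose: DoseGrid, ptv: StructureMask, rx_gy: float) -> float:
    """Paddick conformity index, ``CI = TV_rx^2 / (TV * V_rx)`` in [0, 1].

    ``TV`` is the PTV volume, ``V_rx`` the total volume at or above the
    prescription isodose and ``TV_rx`` their overlap; 1 means the
    prescription isodose exactly covers exactly the PTV.  Returns 0 when no
    voxel reaches the prescription.
    """
    if rx_gy <= 0:
        raise ValueError(f"prescription must be > 0 Gy, got {rx_gy}")
    if ptv.is_empty:
        raise EmptyStructureError("PTV is empty")
    hot = dose.values_gy >= rx_gy
    v_rx = int(hot.sum())
    if v_rx == 0:
        return 0.0
    tv = ptv.n_voxels
    tv_rx = int((hot & ptv.voxels).sum())
    return tv_rx**2 / (tv * v_rx)


def normalize_plan(dose: DoseGrid, ptv: StructureMask, rx_gy: float) -> DoseGrid:
    """Rescale the plan so that 95% of the PTV receives the prescription.

    Returns the dose multiplied by ``rx_gy / D95%(PTV)``; a plan already at
    coverage is returned unchanged (scale factor 1).
    """
    if rx_gy <= 0:
        raise ValueError(f"prescription must be > 0 Gy, got {rx_gy}")
    d95 = d_at_volume(_dvh_of(dose, ptv), 95)
    if d95 <= 0:
        raise ValueError("D95 of the PTV is zero; plan cannot be normalized")
    return dose.scaled(rx_gy / d95)


@dataclass
class PlanMetrics:
    """Plan-quality summary: PTV coverage indices and per-OAR Vx/Dmean."""

    ptv: dict[str, float]  # V95 (%), HI, CI
    organs: dict[str, dict[str, float]]  # per organ: V20..V60 (%), Dmean (Gy)
    rx_gy: float

    def to_frame(self, plan_id: str = "") -> pd.DataFrame:
        """Long-format table with one row per (plan, organ, metric)."""
        rows = [
            {"plan": plan_id, "organ": PTV_LABEL, "metric": k, "value": v}
            for k, v in self.ptv.items()
        ]
        for organ, metrics in self.organs.items():
            rows += [
                {"plan": plan_id, "organ": organ, "metric": k, "value": v}
                for k, v in metrics.items()
            ]
        return pd.DataFrame(rows)


def plan_metrics(
    dose: DoseGrid,
    masks: Mapping[str, StructureMask],
    rx_gy: float,
) -> PlanMetrics:
    """Evaluate a plan against its structure set.

    The PTV entry reports V95 (percent of PTV at or above the prescription,
    per the protocol's coverage requirement), HI and CI; every other
    structure gets V20-V60 and the mean dose.  Empty structures are skipped
    with a warning.
    """
    if PTV_LABEL not in masks:
        raise KeyError(f"structure set must contain {PTV_LABEL!r}")
    ptv = masks[PTV_LABEL]
    ptv_dvh = _dvh_of(dose, ptv)
    ptv_metrics = {
        "V95": v_at_dose(ptv_dvh, rx_gy),
        "HI": homogeneity_index(dose, ptv),
        "CI": conformity_index(dose, ptv, rx_gy),
    }
    organs: dict[str, dict[str, float]] = {}
    for label, mask in masks.items():
        if label == PTV_LABEL:
            continue
        if mask.is_empty:
            logger.warning("skipping empty structure %r in plan metrics", label)
            continue
        dvh = _dvh_of(dose, mask)
        entry = {f"V{int(d)}": v_at_dose(dvh, d) for d in OAR_V_LEVELS_GY}
        entry["Dmean"] = float(dose.in_structure(mask).mean())
        organs[label] = entry
    return PlanMetrics(ptv=ptv_metrics, organs=organs, rx_gy=rx_gy)
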