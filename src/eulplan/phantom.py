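"""Synthetic pelvic phantoms with simulated dose and known ground truth.

The generator emulates the anatomy of a pelvic IMRT cohort — a central
target volume with a bladder anterior, a rectum posterior and two femoral
heads lateral, all inside an elliptical body — on a 4 mm calculation grid.
Organ-to-target gaps are the controllable geometry: widening a gap moves
the organ away from the PTV and increases its EUL.

Dose is simulated, not transported: the prescription is delivered uniformly
inside the PTV and falls off exponentially with distance outside it,
``D(v) = rx * exp(-k * L(v))``, with independent fall-off rates for the
anterior and posterior half-spaces.  Each rate is solved by bisection so
that the corresponding organ's gEUD matches a requested target exactly
(within 1e-3 Gy) — gEUD is strictly decreasing in the rate, so the root is
unique.  This makes every pipeline stage (EUL extraction, model fitting,
assistant structures, plan metrics) runnable with known ground truth and no
external data; it makes no claim of dosimetric realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from ._power_mean import power_mean
from .dosimetry import compute_geud
from .geometry import distance_map
from .grid import (
    MM_PER_CM,
    DistanceMap,
    DoseGrid,
    EmptyStructureError,
    GridGeometry,
    StructureMask,
)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SyntheticCase",
    "build_phantom",
    "simulate_conformal_dose",
    "simulate_ap_pa_dose",
    "generate_cohort",
    "AchievabilityError",
    "DEFAULT_TRUTH_MODELS",
]

logger = logging.getLogger(__name__)

#: Default prescription: 59.4 Gy in 33 fractions.
DEFAULT_RX_GY = 59.4

#: Truth coefficients (intercept Gy, slope Gy/cm) of the published
#: bladder/rectum EUD-EUL lines, used as cohort ground truth.
DEFAULT_TRUTH_MODELS: dict[str, tuple[float, float]] = {
    "bladder": (45.37, -5.78),
    "rectum": (44.23, -5.38),
}


class AchievabilityError(ValueError):
    """A requested organ gEUD target cannot be met by the fall-off model."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic pelvic case.

    All semi-axes, centre offsets and gaps are in cm, ordered ``(z, y, x)``;
    +y is posterior.  Gaps are surface-to-surface separations between the
    PTV and the organ along the anterior (bladder) or posterior (rectum)
    axis; a negative gap pushes the organ into the PTV by that depth.
    """

    grid: GridGeometry = GridGeometry(
        shape=(48, 64, 64), spacing_mm=(4.0, 4.0, 4.0)
    )
    body_semiaxes_cm: tuple[float, float, float] = (8.5, 10.0, 11.0)
    ptv_semiaxes_cm: tuple[float, float, float] = (4.0, 3.0, 4.5)
    bladder_semiaxes_cm: tuple[float, float, float] = (3.0, 2.0, 3.0)
    rectum_semiaxes_cm: tuple[float, float, float] = (4.5, 1.5, 1.5)
    femoral_head_radius_cm: float = 2.2
    femoral_head_offset_cm: tuple[float, float] = (1.0, 8.5)  # (y, |x|) from centre
    anterior_gap_cm: float = 1.0
    posterior_gap_cm: float = 0.5
    #: relative semi-axis jitter drawn per organ from the seed (0 = rigid)
    shape_jitter: float = 0.1

    def with_gaps(self, anterior_cm: float, posterior_cm: float) -> "PhantomSpec":
        return replace(
            self, anterior_gap_cm=anterior_cm, posterior_gap_cm=posterior_cm
        )


def _ellipsoid(
    grid: GridGeometry,
    center_cm: tuple[float, float, float],
    semiaxes_cm: tuple[float, float, float],
) -> np.ndarray:
    """Voxel centres inside an axis-aligned ellipsoid (coordinates in cm)."""
    zz, yy, xx = (c / MM_PER_CM for c in grid.coords_mm())
    terms = [
        ((v - c) / s) ** 2
        for v, c, s in zip((zz, yy, xx), center_cm, semiaxes_cm)
    ]
    # small tolerance keeps voxel centres lying exactly on the surface
    # (the snapped near-surface cap) inside despite float rounding
    return (
        terms[0][:, None, None] + terms[1][None, :, None] + terms[2][None, None, :]
    ) <= 1.0 + 1e-9


def _grid_center_cm(grid: GridGeometry) -> tuple[float, float, float]:
    return tuple(
        (grid.origin_mm[ax] + grid.spacing_mm[ax] * (grid.shape[ax] - 1) / 2)
        / MM_PER_CM
        for ax in range(3)
    )


def _snap_cm(value_cm: float, spacing_mm: float, origin_mm: float) -> float:
    """Nearest voxel-centre coordinate (cm) along one axis."""
    step = spacing_mm / MM_PER_CM
    org = origin_mm / MM_PER_CM
    return org + step * round((value_cm - org) / step)


def build_phantom(
    spec: PhantomSpec = PhantomSpec(), seed: int = 0
) -> dict[str, StructureMask]:
    """Voxelize one phantom; deterministic given ``(spec, seed)``.

    The seed drives a small per-organ jitter of the bladder and rectum
    semi-axes so cohort organs vary in size as well as position.  The PTV
    and body never depend on the seed or the gaps, which lets callers cache
    the PTV distance map across a cohort.  Organ gaps are realized on the
    lattice to within half a voxel: the organ centre is placed so that its
    near surface sits at the requested distance from the outermost PTV
    voxel centre, snapped to the voxel grid.
    """
    grid = spec.grid
    # snap the anatomy centre onto a voxel centre so ellipsoid caps align
    # with the lattice and gaps are realized to within half a voxel
    cz, cy, cx = (
        _snap_cm(c, grid.spacing_mm[ax], grid.origin_mm[ax])
        for ax, c in enumerate(_grid_center_cm(grid))
    )
    rng = np.random.default_rng(seed)
    # Draw jitters in a fixed order, independent of the gap values.
    j_bladder = 1.0 + spec.shape_jitter * rng.uniform(-1, 1, size=3)
    j_rectum = 1.0 + spec.shape_jitter * rng.uniform(-1, 1, size=3)

    body = _ellipsoid(grid, (cz, cy, cx), spec.body_semiaxes_cm)
    ptv = _ellipsoid(grid, (cz, cy, cx), spec.ptv_semiaxes_cm)
    if not ptv.any():
        raise EmptyStructureError("phantom spec produces an empty PTV")

    # Outermost PTV voxel-centre y on the central axis, both directions.
    iz = int(np.abs(grid.coords_mm()[0] / MM_PER_CM - cz).argmin())
    ix = int(np.abs(grid.coords_mm()[2] / MM_PER_CM - cx).argmin())
    ptv_line = np.flatnonzero(ptv[iz, :, ix])
    y_coords_cm = grid.coords_mm()[1] / MM_PER_CM
    y_ant_edge = y_coords_cm[ptv_line[0]]   # most anterior PTV centre
    y_post_edge = y_coords_cm[ptv_line[-1]]  # most posterior PTV centre

    def place(gap_cm, semiaxes, anterior: bool):
        sy = semiaxes[1]
        if anterior:
            target = y_ant_edge - gap_cm  # desired near-surface y
            snapped = _snap_cm(target, grid.spacing_mm[1], grid.origin_mm[1])
            center_y = snapped - sy
        else:
            target = y_post_edge + gap_cm
            snapped = _snap_cm(target, grid.spacing_mm[1], grid.origin_mm[1])
            center_y = snapped + sy
        return center_y

    bl_axes = tuple(np.asarray(spec.bladder_semiaxes_cm) * j_bladder)
    re_axes = tuple(np.asarray(spec.rectum_semiaxes_cm) * j_rectum)
    bladder = _ellipsoid(
        grid, (cz, place(spec.anterior_gap_cm, bl_axes, True), cx), bl_axes
    )
    rectum = _ellipsoid(
        grid, (cz, place(spec.posterior_gap_cm, re_axes, False), cx), re_axes
    )
    fy, fx = spec.femoral_head_offset_cm
    r = spec.femoral_head_radius_cm
    fem_l = _ellipsoid(grid, (cz, cy + fy, cx - fx), (r, r, r))
    fem_r = _ellipsoid(grid, (cz, cy + fy, cx + fx), (r, r, r))

    masks = {
        "body": body,
        "PTV": ptv,
        "bladder": bladder,
        "rectum": rectum,
        "femoral_head_L": fem_l,
        "femoral_head_R": fem_r,
    }
    for label, vox in masks.items():
        if label == "body":
            continue
        if not vox.any():
            raise ValueError(f"phantom spec produces an empty {label}")
        if (vox & ~body).any():
            raise ValueError(f"phantom spec places {label} outside the body")
    return {
        label: StructureMask(grid, vox, label) for label, vox in masks.items()
    }


# --- dose simulation ------------------------------------------------------


def _halfspace_split(
    masks: dict[str, StructureMask]
) -> tuple[np.ndarray, np.ndarray]:
    """Anterior/posterior half-space masks split at the PTV centroid's
    coronal plane."""
    ptv = masks["PTV"]
    y_idx = np.nonzero(ptv.voxels)[1]
    y_centroid = y_idx.mean()
    yy = np.arange(ptv.geometry.shape[1])
    anterior = yy < y_centroid
    ant3d = np.broadcast_to(
        anterior[None, :, None], ptv.geometry.shape
    )
    return ant3d, ~ant3d


def _organ_geud_closed_form(
    rx_gy: float, l_cm: np.ndarray, k: float, a: float
) -> float:
    """gEUD of ``rx * exp(-k L)`` over one organ (PTV voxels get rx)."""
    dose = np.where(l_cm > 0, rx_gy * np.exp(-k * l_cm), rx_gy)
    return power_mean(dose, a)


def simulate_conformal_dose(
    masks: dict[str, StructureMask],
    rx_gy: float,
    eud_targets: dict[str, float],
    a: float = 1.0,
    seed: int | None = None,
    dmap: DistanceMap | None = None,
    k_max_per_cm: float = 8.0,
    tol_gy: float = 1e-4,
) -> DoseGrid:
    """Simulated plan dose meeting per-organ gEUD targets exactly.

    The dose is the prescription inside the PTV and
    ``rx * exp(-k_h * L(v))`` outside, where ``L`` is the distance to the
    PTV (cm) and ``k_h`` (1/cm) is the fall-off rate of the half-space
    (anterior or posterior of the PTV centroid) containing voxel ``v``.
    Each targeted organ is assigned the half-space holding its centroid and
    that half-space's rate is solved by bisection so the organ's gEUD
    matches its target; organs straddling the plane are handled by a short
    fixed-point iteration over the two rates.

    The model is deterministic; ``seed`` is accepted for interface symmetry
    with the other simulators and ignored.

    Raises
    ------
    AchievabilityError
        If a target lies outside the organ's achievable gEUD range
        ``(gEUD at k_max, gEUD at k=0)``, or two targeted organs share a
        half-space.
    """
    del seed
    if "PTV" not in masks:
        raise KeyError("structure set must contain 'PTV'")
    ptv = masks["PTV"]
    if dmap is None:
        dmap = distance_map(ptv)
    ant3d, post3d = _halfspace_split(masks)

    # Assign each targeted organ to a half-space by centroid.
    assignment: dict[str, str] = {}
    for organ in eud_targets:
        vox = masks[organ].voxels
        y_org = np.nonzero(vox)[1].mean()
        y_ptv = np.nonzero(ptv.voxels)[1].mean()
        side = "anterior" if y_org < y_ptv else "posterior"
        if side in assignment.values():
            raise AchievabilityError(
                "two targeted organs share a half-space; independent fall-off "
                "rates cannot meet both targets"
            )
        assignment[organ] = side

    organ_l = {o: dmap.in_structure(masks[o]) for o in eud_targets}
    organ_half = {
        o: (ant3d if assignment[o] == "anterior" else post3d)[masks[o].voxels]
        for o in eud_targets
    }

    # Feasibility per organ, ignoring cross-half coupling (exact when the
    # organ lies wholly in its half-space, which the phantom guarantees).
    for organ, target in eud_targets.items():
        lo = _organ_geud_closed_form(rx_gy, organ_l[organ], k_max_per_cm, a)
        hi = _organ_geud_closed_form(rx_gy, organ_l[organ], 0.0, a)
        if not lo <= target <= hi:
            raise AchievabilityError(
                f"{organ}: target {target:.2f} Gy outside achievable range "
                f"[{lo:.2f}, {hi:.2f}] Gy"
            )

    rates = {"anterior": 1.0, "posterior": 1.0}

    def organ_geud(organ: str) -> float:
        l = organ_l[organ]
        in_own = organ_half[organ]
        k_own = rates[assignment[organ]]
        other = "posterior" if assignment[organ] == "anterior" else "anterior"
        k_other = rates[other]
        k_vec = np.where(in_own, k_own, k_other)
        dose = np.where(l > 0, rx_gy * np.exp(-k_vec * l), rx_gy)
        return power_mean(dose, a)

    for _ in range(6):
        for organ, target in eud_targets.items():
            side = assignment[organ]

            def f(k: float) -> float:
                rates[side] = k
                return organ_geud(organ) - target

            if abs(f(0.0)) <= tol_gy:
                rates[side] = 0.0
                continue
            if f(0.0) < 0 or f(k_max_per_cm) > 0:
                raise AchievabilityError(
                    f"{organ}: target {target:.2f} Gy not bracketed by fall-off "
                    f"rates [0, {k_max_per_cm}] 1/cm"
                )
            rates[side] = float(
                optimize.brentq(f, 0.0, k_max_per_cm, xtol=1e-10, rtol=1e-14)
            )
        if all(
            abs(organ_geud(o) - t) <= tol_gy for o, t in eud_targets.items()
        ):
            break
    else:
        raise AchievabilityError("fall-off rates did not converge to targets")

    l_all = dmap.values_cm
    k_field = np.where(ant3d, rates["anterior"], rates["posterior"])
    dose = np.where(
        ptv.voxels, rx_gy, rx_gy * np.exp(-k_field * l_all)
    )
    return DoseGrid(ptv.geometry, dose)


def simulate_ap_pa_dose(
    masks: dict[str, StructureMask],
    rx_gy: float = DEFAULT_RX_GY,
    margin_cm: float = 0.5,
    falloff_per_cm: float = 1.5,
) -> DoseGrid:
    """Deterministic parallel-opposed (0° and 180°) setup-beam dose.

    The beams travel along the anterior-posterior axis, so the full
    prescription fills the corridor of voxels whose (z, x) projection falls
    within the PTV's projection dilated by ``margin_cm``; outside the
    corridor the dose decays as ``exp(-falloff * lateral distance)``.  Its
    40% isodose is the preliminary assistant structure of the AS workflow.
    """
    if "PTV" not in masks or "body" not in masks:
        raise KeyError("structure set must contain 'PTV' and 'body'")
    ptv = masks["PTV"]
    if ptv.is_empty:
        raise EmptyStructureError("PTV is empty")
    grid = ptv.geometry
    proj = ptv.voxels.any(axis=1)  # (z, x) beam's-eye-view projection
    samp = (grid.spacing_mm[0], grid.spacing_mm[2])
    dist2d_mm = ndimage.distance_transform_edt(~proj, sampling=samp)
    corridor2d = dist2d_mm <= margin_cm * MM_PER_CM
    lateral_cm = np.where(corridor2d, 0.0, dist2d_mm / MM_PER_CM - margin_cm)
    dose2d = rx_gy * np.exp(-falloff_per_cm * lateral_cm)
    dose = np.broadcast_to(dose2d[:, None, :], grid.shape).copy()
    return DoseGrid(grid, dose)


# --- cohort generation ----------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated plan library.

    Defaults mirror the modelled cohort: 60 cases, truth EUD-EUL lines
    equal to the published bladder/rectum coefficients, 1.5 Gy Gaussian
    noise around the line, ``a = 1`` and a 59.4 Gy prescription on a 4 mm
    grid.  Gap ranges (cm) are sampled uniformly per case.
    """

    n_cases: int = 60
    gap_ranges_cm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"bladder": (0.2, 1.8), "rectum": (0.2, 1.8)}
    )
    truth_models: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_MODELS)
    )
    noise_sd_gy: float = 1.5
    a: float = 1.0
    rx_gy: float = DEFAULT_RX_GY
    phantom: PhantomSpec = PhantomSpec()
    seed: int = 0
    #: safety margin kept inside the achievable gEUD range when clipping
    clip_margin_gy: float = 0.1

    def __post_init__(self) -> None:
        if self.n_cases < 3:
            raise ValueError(f"a cohort needs n_cases >= 3, got {self.n_cases}")
        if self.noise_sd_gy < 0:
            raise ValueError("noise_sd_gy must be >= 0")
        for organ, (lo, hi) in self.gap_ranges_cm.items():
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid gap range for {organ}: ({lo}, {hi})")


@dataclass
class OrganTruth:
    """Recorded ground truth for one organ of one case."""

    gap_cm: float
    eul_cm: float
    target_eud_gy: float
    achieved_eud_gy: float
    clipped: bool


@dataclass
class SyntheticCase:
    """One phantom case: masks, simulated dose and recorded ground truth."""

    case_id: str
    masks: dict[str, StructureMask]
    dose: DoseGrid | None
    truth: dict[str, OrganTruth]
    rx_gy: float


def generate_cohort(
    spec: CohortSpec = CohortSpec(), include_dose: bool = True
) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Simulate a plan library with known EUD-EUL ground truth.

    Per case: gaps are sampled uniformly from the spec ranges, the phantom
    is built, EULs are measured, each organ's target gEUD is drawn as
    ``intercept + slope * EUL + N(0, noise_sd)`` (clipped into the
    achievable range, with the clip recorded), and — unless
    ``include_dose=False``, which skips the dose grids for geometry-only
    studies — the dose is simulated to meet the targets and the achieved
    gEUD is re-measured from the grid.  Fully reproducible from the spec
    seed; a failing case is logged and skipped, and the cohort fails if
    more than 10% of cases abort.

    Returns the cases plus a truth table with one row per (case, organ):
    ``case_id, organ, gap_cm, eul_cm, target_eud_gy, achieved_eud_gy,
    clipped``.
    """
    rng = np.random.default_rng(spec.seed)
    organs = sorted(spec.truth_models)
    for organ in organs:
        if organ not in spec.gap_ranges_cm:
            raise ValueError(f"no gap range for modelled organ {organ!r}")

    # PTV and body are gap- and seed-independent: cache their distance map.
    ref_masks = build_phantom(spec.phantom, seed=0)
    dmap_cache = distance_map(ref_masks["PTV"])

    cases: list[SyntheticCase] = []
    rows: list[dict] = []
    failures = 0
    for i in range(spec.n_cases):
        case_id = f"case{i:03d}"
        gaps = {
            o: float(rng.uniform(*spec.gap_ranges_cm[o]))
            for o in organs
        }
        noise = {o: float(rng.normal(0.0, spec.noise_sd_gy)) for o in organs}
        case_seed = int(rng.integers(0, 2**31 - 1))
        try:
            case = _one_case(
                spec, case_id, gaps, noise, case_seed, dmap_cache, include_dose
            )
        except (ValueError, KeyError) as exc:
            failures += 1
            logger.warning("case %s aborted: %s", case_id, exc)
            continue
        cases.append(case)
        for organ in organs:
            t = case.truth[organ]
            rows.append(
                {
                    "case_id": case_id,
                    "organ": organ,
                    "gap_cm": t.gap_cm,
                    "eul_cm": t.eul_cm,
                    "target_eud_gy": t.target_eud_gy,
                    "achieved_eud_gy": t.achieved_eud_gy,
                    "clipped": t.clipped,
                }
            )
    if failures > 0.1 * spec.n_cases:
        raise RuntimeError(
            f"cohort generation failed: {failures}/{spec.n_cases} cases aborted"
        )
    return cases, pd.DataFrame(rows)


def _one_case(
    spec: CohortSpec,
    case_id: str,
    gaps: dict[str, float],
    noise: dict[str, float],
    case_seed: int,
    dmap: DistanceMap,
    include_dose: bool,
) -> SyntheticCase:
    phantom = spec.phantom.with_gaps(
        anterior_cm=gaps.get("bladder", spec.phantom.anterior_gap_cm),
        posterior_cm=gaps.get("rectum", spec.phantom.posterior_gap_cm),
    )
    masks = build_phantom(phantom, seed=case_seed)

    truth: dict[str, OrganTruth] = {}
    targets: dict[str, float] = {}
    for organ, (b0, b1) in spec.truth_models.items():
        l = dmap.in_structure(masks[organ])
        eul = power_mean(l, spec.a)
        target = b0 + b1 * eul + noise[organ]
        lo = _organ_geud_closed_form(spec.rx_gy, l, 8.0, spec.a)
        hi = _organ_geud_closed_form(spec.rx_gy, l, 0.0, spec.a)
        clipped = False
        lo_c, hi_c = lo + spec.clip_margin_gy, hi - spec.clip_margin_gy
        if not lo_c <= target <= hi_c:
            target = float(np.clip(target, lo_c, hi_c))
            clipped = True
            logger.info("case %s %s: target clipped to %.2f Gy", case_id, organ, target)
        targets[organ] = target
        truth[organ] = OrganTruth(
            gap_cm=gaps[organ],
            eul_cm=eul,
            target_eud_gy=target,
            achieved_eud_gy=target,  # refined below when dose is simulated
            clipped=clipped,
        )

    dose = None
    if include_dose:
        dose = simulate_conformal_dose(
            masks, spec.rx_gy, targets, a=spec.a, dmap=dmap
        )
        for organ in targets:
            truth[organ].achieved_eud_gy = compute_geud(
                dose, masks[organ], spec.a
            )
    return SyntheticCase(
        case_id=case_id, masks=masks, dose=dose, truth=truth, rx_gy=spec.rx_gy
    )
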