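"""Synthetic prostate phantom geometry families.

The study geometry is a TG-119-like prostate arrangement built from analytic
surrogates: the PTV is an ellipsoid centred at the origin, the rectum is a
cylinder running superior-inferior just posterior to the PTV, and the bladder
is an ellipsoid anterior-superior to the PTV.  The printed structure volumes
and overlap volumes act as calibration targets; sizes are solved on the
voxel grid by bisection so every target is met within a stated tolerance on
any reasonable spacing.

Two case families are provided:

* ``generate_simulation1_cases`` - 6 cases: two PTV sizes (162.7 / 188.0 cc)
  crossed with three rectum overlap volumes (3.3 / 5.3 / 7.7 cc), with the
  rectum volume (49.9 cc), bladder volume (165.0 cc) and bladder overlap
  (13.2 cc) held fixed.  Because COPP = ROV/RV ignores the PTV, the two
  PTV-size arms are indistinguishable by COPP at each overlap level; POPP
  separates them by the factor 188.0/162.7.
* ``generate_simulation2_cases`` - 81 cases: a full factorial of nine rectum
  configurations (AP/LR expansion 4/5/6 mm x posterior shift 10/12/14 mm)
  and nine bladder configurations (uniform expansion 7/10/12 mm x anterior
  shift 5/8/11 mm) around a fixed 162.7 cc PTV.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Callable, Sequence, Union

import numpy as np

from .grid_geometry import (
    Cylinder,
    Ellipsoid,
    Primitive,
    StructureMask,
    VoxelGrid,
    expand_mask,
    make_grid,
    overlap_volume,
    rasterize_primitive,
    shift_mask,
)

__all__ = [
    "GeometryCase",
    "BasePhantomSpec",
    "UnachievableTargetError",
    "default_grid",
    "build_base_phantom",
    "build_structure_from_recipe",
    "build_case_from_provenance",
    "solve_shift_for_overlap",
    "generate_simulation1_cases",
    "generate_simulation2_cases",
]


class UnachievableTargetError(ValueError):
    """A requested overlap or volume target cannot be reached."""


# --- printed calibration targets (cc / mm) ---------------------------------

PTV_CC = 162.7
PTV_LARGE_CC = 188.0
RECTUM_CC_SIM1 = 49.9
BLADDER_CC_SIM1 = 165.0
ROV_TARGETS_CC = (3.3, 5.3, 7.7)
BOV_SIM1_CC = 13.2

RECTUM_EXPANSIONS_MM = (4.0, 5.0, 6.0)          # AP + LR, symmetric
RECTUM_POSTERIOR_SHIFTS_MM = (10.0, 12.0, 14.0)
RECTUM_CC_SIM2 = (42.5, 50.0, 58.2)
BLADDER_EXPANSIONS_MM = (7.0, 10.0, 12.0)       # uniform
BLADDER_ANTERIOR_SHIFTS_MM = (5.0, 8.0, 11.0)
BLADDER_CC_SIM2 = (124.2, 165.0, 197.0)

OVERLAP_TOLERANCE_CC = 0.15
VOLUME_TOLERANCE = 0.05  # relative, for expanded-structure targets


@dataclasses.dataclass(frozen=True)
class BasePhantomSpec:
    """Analytic surrogate dimensions of the base phantom (mm).

    Defaults are calibrated so the base arrangement reproduces the study's
    printed volumes: PTV ~162.7 cc, rectum ~50 cc (raw cylinder + 5 mm AP/LR
    margin), bladder ~165 cc (raw ellipsoid + 10 mm margin).  The rectum raw
    radius and length are chosen so the three AP/LR expansions reproduce
    42.5/50.0/58.2 cc; the bladder raw semiaxes likewise reproduce
    124.2/165.0/197.0 cc under uniform expansion.
    """

    ptv_semiaxes_ratio: tuple[float, float, float] = (1.2, 1.2, 1.0)
    rectum_radius_mm: float = 7.81
    rectum_half_length_mm: float = 48.5
    rectum_center_mm: tuple[float, float, float] = (0.0, -26.0, 0.0)
    bladder_semiaxes_mm: tuple[float, float, float] = (26.0, 24.0, 22.0)
    bladder_center_mm: tuple[float, float, float] = (0.0, 35.0, 26.0)


DEFAULT_SPEC = BasePhantomSpec()


@dataclasses.dataclass
class GeometryCase:
    """One PTV / rectum / bladder configuration with provenance.

    Stored volumes are in cc and always recomputable from the masks:
    ``rov_cc == overlap_volume(rectum, ptv)`` etc.
    """

    case_id: str
    ptv: StructureMask
    rectum: StructureMask
    bladder: StructureMask
    ptv_cc: float
    rv_cc: float
    bv_cc: float
    rov_cc: float
    bov_cc: float
    provenance: dict

    @classmethod
    def from_structures(
        cls,
        case_id: str,
        ptv: StructureMask,
        rectum: StructureMask,
        bladder: StructureMask,
        provenance: dict,
    ) -> "GeometryCase":
        case = cls(
            case_id=case_id,
            ptv=ptv,
            rectum=rectum,
            bladder=bladder,
            ptv_cc=ptv.volume_cc,
            rv_cc=rectum.volume_cc,
            bv_cc=bladder.volume_cc,
            rov_cc=overlap_volume(rectum, ptv),
            bov_cc=overlap_volume(bladder, ptv),
            provenance=provenance,
        )
        case.validate()
        return case

    def validate(self) -> None:
        if overlap_volume(self.rectum, self.bladder) > 0:
            raise ValueError(f"case {self.case_id}: rectum and bladder overlap")
        for name, stored, mask in (
            ("ptv_cc", self.ptv_cc, self.ptv),
            ("rv_cc", self.rv_cc, self.rectum),
            ("bv_cc", self.bv_cc, self.bladder),
        ):
            if abs(stored - mask.volume_cc) > 1e-9:
                raise ValueError(f"case {self.case_id}: stored {name} inconsistent")

    @property
    def grid(self) -> VoxelGrid:
        return self.ptv.grid


def default_grid(spacing_mm: float = 2.0) -> VoxelGrid:
    """Grid covering the full phantom family with margin to spare.

    2 mm isotropic is the default working resolution (a typical dose-grid
    spacing); pass 1.0 for convergence checks.
    """
    return make_grid((90.0, 180.0, 130.0), spacing_mm)


# ---------------------------------------------------------------------------
# calibration solvers
# ---------------------------------------------------------------------------

def _bisect_monotone(
    build: Callable[[float], StructureMask],
    measure: Callable[[StructureMask], float],
    lo: float,
    hi: float,
    target: float,
    tol: float,
    what: str,
    xtol: float = 1e-3,
) -> tuple[float, StructureMask, float]:
    """Bisection on a scalar parameter for a monotone non-decreasing measure.

    Voxelized measures are step functions, so after the bracket collapses the
    endpoint whose achieved value is closest to the target is returned.
    """
    m_lo, m_hi = build(lo), build(hi)
    f_lo, f_hi = measure(m_lo), measure(m_hi)
    if not (min(f_lo, f_hi) - tol <= target <= max(f_lo, f_hi) + tol):
        raise UnachievableTargetError(
            f"{what}: target {target:.3f} outside achievable range "
            f"[{min(f_lo, f_hi):.3f}, {max(f_lo, f_hi):.3f}]"
        )
    if f_lo > f_hi:  # orient so measure increases with the parameter
        lo, hi, f_lo, f_hi, m_lo, m_hi = hi, lo, f_hi, f_lo, m_hi, m_lo
    while abs(hi - lo) > xtol:
        mid = 0.5 * (lo + hi)
        m_mid = build(mid)
        f_mid = measure(m_mid)
        if f_mid < target:
            lo, f_lo, m_lo = mid, f_mid, m_mid
        else:
            hi, f_hi, m_hi = mid, f_mid, m_mid
    if abs(f_lo - target) <= abs(f_hi - target):
        best = (lo, m_lo, f_lo)
    else:
        best = (hi, m_hi, f_hi)
    if abs(best[2] - target) > tol:
        raise UnachievableTargetError(
            f"{what}: closest achievable value {best[2]:.3f} misses target "
            f"{target:.3f} by more than {tol:.3f}"
        )
    return best


def _solve_scaled_ellipsoid(
    grid: VoxelGrid,
    center: Sequence[float],
    semiaxes: Sequence[float],
    target_cc: float,
    scale_axes: tuple[int, ...] = (0, 1, 2),
    label: str = "",
    tol_cc: float = 0.2,
) -> tuple[StructureMask, tuple[float, float, float]]:
    """Scale selected semiaxes of an ellipsoid so its voxel volume hits a target."""
    base = np.asarray(semiaxes, dtype=float)
    result_axes = {}

    def build(scale: float) -> StructureMask:
        ax = base.copy()
        ax[list(scale_axes)] *= scale
        result_axes["ax"] = tuple(ax)
        return rasterize_primitive(grid, Ellipsoid(tuple(center), tuple(ax)), label)

    _, mask, _ = _bisect_monotone(
        build, lambda m: m.volume_cc, 0.5, 1.6, target_cc, tol_cc,
        f"ellipsoid volume ({label or 'unnamed'})",
    )
    return mask, result_axes["ax"]


def solve_shift_for_overlap(
    moving: Union[StructureMask, Primitive],
    fixed: StructureMask,
    target_cc: float,
    axis: str = "y",
    tolerance: float = OVERLAP_TOLERANCE_CC,
    bracket_mm: tuple[float, float] = (-60.0, 60.0),
) -> tuple[float, StructureMask, float]:
    """Find the axis offset at which ``moving`` overlaps ``fixed`` by ``target_cc``.

    ``moving`` may be a :class:`StructureMask` (offsets snap to whole voxels;
    the closest achievable overlap is returned, which on a coarse grid may be
    limited by voxel-layer quantization) or an analytic primitive (the centre
    is moved continuously and re-rasterized, giving sub-voxel resolution of
    the achieved overlap).  Overlap must be monotone in the offset across the
    bracket.  Returns ``(offset_mm, shifted_mask, achieved_cc)``.
    """
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    if isinstance(moving, StructureMask):
        moving_cc = moving.volume_cc
    else:
        moving_cc = rasterize_primitive(fixed.grid, moving).volume_cc
    if not (0.0 <= target_cc <= min(moving_cc, fixed.volume_cc) + tolerance):
        raise UnachievableTargetError(
            f"overlap target {target_cc:.2f} cc exceeds the attainable range "
            f"(moving {moving_cc:.2f} cc, fixed {fixed.volume_cc:.2f} cc)"
        )

    if isinstance(moving, StructureMask):
        step = moving.grid.spacing_mm[ax]

        def build(offset: float) -> StructureMask:
            vec = [0.0, 0.0, 0.0]
            vec[ax] = round(offset / step) * step
            return shift_mask(moving, vec)

        xtol = 0.51 * step
    else:

        def build(offset: float) -> StructureMask:
            vec = [0.0, 0.0, 0.0]
            vec[ax] = offset
            return rasterize_primitive(fixed.grid, moving.shifted(vec))

        xtol = 1e-3

    offset, mask, achieved = _bisect_monotone(
        build,
        lambda m: overlap_volume(m, fixed),
        bracket_mm[0],
        bracket_mm[1],
        target_cc,
        tolerance,
        f"overlap with {fixed.label or 'fixed'}",
        xtol=xtol,
    )
    if isinstance(moving, StructureMask):
        offset = round(offset / step) * step
    return offset, mask, achieved


# ---------------------------------------------------------------------------
# structure recipes (provenance -> mask, bitwise reproducible)
# ---------------------------------------------------------------------------

def build_structure_from_recipe(grid: VoxelGrid, recipe: dict) -> StructureMask:
    """Rebuild a structure mask from its provenance recipe.

    A recipe records the analytic primitive (post any solved positioning),
    an optional margin applied analytically before rasterization
    (``analytic_expand_mm``: exact radial growth of the cylinder, offset
    ellipsoid approximated by growing each semiaxis), an optional mask-level
    margin expansion (``expand_mm``), and an optional whole-voxel shift.
    Rebuilding on the same grid is bitwise deterministic.  The generators
    use the analytic margin because dilating a voxelized thin structure
    under-reaches the analytic offset surface by up to one voxel, which on a
    2 mm grid breaks the printed volume targets.
    """
    kind = recipe["kind"]
    grow = float(recipe.get("analytic_expand_mm", 0.0))
    if kind == "ellipsoid":
        semiaxes = tuple(s + grow for s in recipe["semiaxes"])
        prim: Primitive = Ellipsoid(tuple(recipe["center"]), semiaxes)
    elif kind == "cylinder":
        # radial (in-plane) growth only: AP/LR expansion of an SI cylinder
        prim = Cylinder(
            tuple(recipe["center"]),
            recipe["radius"] + grow,
            recipe["half_length"],
            recipe.get("axis", "z"),
        )
    else:
        raise ValueError(f"unknown recipe kind {kind!r}")
    mask = rasterize_primitive(grid, prim, recipe.get("label", ""))
    margins = recipe.get("expand_mm")
    if margins is not None and np.any(np.asarray(margins) > 0):
        mask = expand_mask(mask, margins)
    shift = recipe.get("shift_mm")
    if shift is not None and np.any(np.asarray(shift) != 0):
        mask = shift_mask(mask, shift)
    return mask


def build_case_from_provenance(grid: VoxelGrid, provenance: dict) -> GeometryCase:
    """Regenerate a full case from its provenance record."""
    return GeometryCase.from_structures(
        provenance["case_id"],
        build_structure_from_recipe(grid, provenance["ptv"]),
        build_structure_from_recipe(grid, provenance["rectum"]),
        build_structure_from_recipe(grid, provenance["bladder"]),
        provenance,
    )


# ---------------------------------------------------------------------------
# base phantom and case families
# ---------------------------------------------------------------------------

def _solve_ptv(
    grid: VoxelGrid, spec: BasePhantomSpec, target_cc: float, fixed_si_mm: float | None = None
) -> tuple[StructureMask, tuple[float, float, float]]:
    """PTV ellipsoid scaled to a volume target.

    The base PTV is scaled isotropically.  For the large-PTV arm the SI
    semiaxis is held at the base value and only the axial (LR/AP) semiaxes
    grow, mimicking a laterally larger target with the same cranio-caudal
    extent.
    """
    if fixed_si_mm is None:
        nominal = tuple(30.0 * r for r in spec.ptv_semiaxes_ratio)
        return _solve_scaled_ellipsoid(grid, (0, 0, 0), nominal, target_cc, (0, 1, 2), "PTV")
    base = (spec.ptv_semiaxes_ratio[0], spec.ptv_semiaxes_ratio[1], 1.0)
    semiaxes = (base[0] * fixed_si_mm, base[1] * fixed_si_mm, fixed_si_mm)
    return _solve_scaled_ellipsoid(grid, (0, 0, 0), semiaxes, target_cc, (0, 1), "PTV")


def build_base_phantom(
    grid: VoxelGrid | None = None, spec: BasePhantomSpec = DEFAULT_SPEC
) -> GeometryCase:
    """The calibrated base arrangement: PTV ~162.7 cc, RV ~50 cc, BV ~165 cc.

    The rectum is the raw cylinder with the middle (5 mm AP/LR) margin, the
    bladder the raw ellipsoid with the middle (10 mm uniform) margin, both at
    their unshifted positions; overlaps with the PTV are strictly positive by
    construction.
    """
    if grid is None:
        grid = default_grid()
    ptv, ptv_axes = _solve_ptv(grid, spec, PTV_CC)
    ptv.label = "PTV"
    rectum_recipe = {
        "kind": "cylinder",
        "center": spec.rectum_center_mm,
        "radius": spec.rectum_radius_mm,
        "half_length": spec.rectum_half_length_mm,
        "axis": "z",
        "analytic_expand_mm": 5.0,
        "label": "Rectum",
    }
    bladder_recipe = {
        "kind": "ellipsoid",
        "center": spec.bladder_center_mm,
        "semiaxes": spec.bladder_semiaxes_mm,
        "analytic_expand_mm": 10.0,
        "label": "Bladder",
    }
    provenance = {
        "case_id": "base",
        "family": "base",
        "ptv": {"kind": "ellipsoid", "center": (0, 0, 0), "semiaxes": ptv_axes, "label": "PTV"},
        "rectum": rectum_recipe,
        "bladder": bladder_recipe,
    }
    return GeometryCase.from_structures(
        "base",
        ptv,
        build_structure_from_recipe(grid, rectum_recipe),
        build_structure_from_recipe(grid, bladder_recipe),
        provenance,
    )


def generate_simulation1_cases(
    grid: VoxelGrid | None = None, seed: int = 0
) -> list[GeometryCase]:
    """Six cases: {162.7, 188.0 cc PTV} x {3.3, 5.3, 7.7 cc rectum overlap}.

    The rectum (49.9 cc) and bladder (165.0 cc) volumes are fixed; the three
    rectum overlap levels are reached by solving the rectum AP position, and
    the bladder overlap is pinned at 13.2 cc by solving the bladder AP shift
    for each PTV size.  Generation is fully deterministic; ``seed`` is
    reserved for optional surface jitter, which is off by default.
    """
    del seed  # deterministic by default
    if grid is None:
        grid = default_grid()
    spec = DEFAULT_SPEC

    # PTV arms: base size scaled isotropically; large arm grows LR/AP only.
    ptv_small, ax_small = _solve_ptv(grid, spec, PTV_CC)
    ptv_large, ax_large = _solve_ptv(grid, spec, PTV_LARGE_CC, fixed_si_mm=ax_small[2])
    ptv_small.label = ptv_large.label = "PTV"

    # Fixed-volume rectum: solve the cylinder radius for 49.9 cc.
    def build_rectum(radius: float) -> StructureMask:
        return rasterize_primitive(
            grid,
            Cylinder(spec.rectum_center_mm, radius, spec.rectum_half_length_mm),
            "Rectum",
        )

    rectum_radius, _, _ = _bisect_monotone(
        build_rectum, lambda m: m.volume_cc, 10.0, 16.0, RECTUM_CC_SIM1, 0.3,
        "rectum volume",
    )

    # Fixed-volume bladder: scale the base ellipsoid to 165.0 cc.
    _, bladder_axes = _solve_scaled_ellipsoid(
        grid, spec.bladder_center_mm, spec.bladder_semiaxes_mm, BLADDER_CC_SIM1,
        label="Bladder",
    )

    cases = []
    for ptv, ptv_axes, ptv_target in (
        (ptv_small, ax_small, PTV_CC),
        (ptv_large, ax_large, PTV_LARGE_CC),
    ):
        # Pin the bladder overlap by shifting the bladder in AP.
        bladder_prim = Ellipsoid(spec.bladder_center_mm, tuple(bladder_axes))
        b_off, bladder, bov = solve_shift_for_overlap(
            bladder_prim, ptv, BOV_SIM1_CC, axis="y", bracket_mm=(-25.0, 40.0)
        )
        bladder.label = "Bladder"
        for rov_target in ROV_TARGETS_CC:
            rect_prim = Cylinder(
                spec.rectum_center_mm, rectum_radius, spec.rectum_half_length_mm
            )
            r_off, rectum, rov = solve_shift_for_overlap(
                rect_prim, ptv, rov_target, axis="y", bracket_mm=(-25.0, 25.0)
            )
            rectum.label = "Rectum"
            case_id = f"S1_PTV{ptv_target:.0f}_ROV{rov_target:.1f}"
            rc = np.asarray(spec.rectum_center_mm) + [0, r_off, 0]
            bc = np.asarray(spec.bladder_center_mm) + [0, b_off, 0]
            provenance = {
                "case_id": case_id,
                "family": "simulation1",
                "ptv_target_cc": ptv_target,
                "rov_target_cc": rov_target,
                "bov_target_cc": BOV_SIM1_CC,
                "rv_target_cc": RECTUM_CC_SIM1,
                "bv_target_cc": BLADDER_CC_SIM1,
                "ptv": {
                    "kind": "ellipsoid", "center": (0, 0, 0),
                    "semiaxes": tuple(ptv_axes), "label": "PTV",
                },
                "rectum": {
                    "kind": "cylinder", "center": tuple(rc), "radius": rectum_radius,
                    "half_length": spec.rectum_half_length_mm, "axis": "z",
                    "label": "Rectum",
                },
                "bladder": {
                    "kind": "ellipsoid", "center": tuple(bc),
                    "semiaxes": tuple(bladder_axes), "label": "Bladder",
                },
            }
            cases.append(
                GeometryCase.from_structures(case_id, ptv, rectum, bladder, provenance)
            )
    return cases


def generate_simulation2_cases(
    grid: VoxelGrid | None = None, seed: int = 0
) -> list[GeometryCase]:
    """81 cases: 9 rectum x 9 bladder configurations around a fixed PTV.

    Rectum: the raw cylinder is expanded by 4/5/6 mm in AP and LR (reaching
    ~42.5/50.0/58.2 cc) and shifted 10/12/14 mm posteriorly.  Bladder: the
    raw ellipsoid is expanded uniformly by 7/10/12 mm (~124.2/165.0/197.0 cc)
    and shifted 5/8/11 mm anteriorly.  Shifts are applied to the primitive
    centre before rasterization (expansion and translation commute), which
    keeps sub-voxel shift levels distinct on a 2 mm grid.  Deterministic;
    ``seed`` is reserved for optional surface jitter (off by default).
    """
    del seed
    if grid is None:
        grid = default_grid()
    spec = DEFAULT_SPEC

    ptv, ptv_axes = _solve_ptv(grid, spec, PTV_CC)
    ptv.label = "PTV"
    ptv_recipe = {
        "kind": "ellipsoid", "center": (0, 0, 0), "semiaxes": tuple(ptv_axes),
        "label": "PTV",
    }

    rectum_configs = []
    for e, s in itertools.product(RECTUM_EXPANSIONS_MM, RECTUM_POSTERIOR_SHIFTS_MM):
        center = (
            spec.rectum_center_mm[0],
            spec.rectum_center_mm[1] - s,  # posterior = -y
            spec.rectum_center_mm[2],
        )
        recipe = {
            "kind": "cylinder", "center": center, "radius": spec.rectum_radius_mm,
            "half_length": spec.rectum_half_length_mm, "axis": "z",
            "analytic_expand_mm": e, "label": "Rectum",
        }
        mask = build_structure_from_recipe(grid, recipe)
        target = RECTUM_CC_SIM2[RECTUM_EXPANSIONS_MM.index(e)]
        if abs(mask.volume_cc - target) > VOLUME_TOLERANCE * target:
            raise UnachievableTargetError(
                f"rectum expansion {e} mm: volume {mask.volume_cc:.1f} cc "
                f"misses target {target} cc by more than {VOLUME_TOLERANCE:.0%}"
            )
        rectum_configs.append((e, s, recipe, mask))

    bladder_configs = []
    for e, s in itertools.product(BLADDER_EXPANSIONS_MM, BLADDER_ANTERIOR_SHIFTS_MM):
        center = (
            spec.bladder_center_mm[0],
            spec.bladder_center_mm[1] + s,  # anterior = +y
            spec.bladder_center_mm[2],
        )
        recipe = {
            "kind": "ellipsoid", "center": center,
            "semiaxes": spec.bladder_semiaxes_mm,
            "analytic_expand_mm": e, "label": "Bladder",
        }
        mask = build_structure_from_recipe(grid, recipe)
        target = BLADDER_CC_SIM2[BLADDER_EXPANSIONS_MM.index(e)]
        if abs(mask.volume_cc - target) > VOLUME_TOLERANCE * target:
            raise UnachievableTargetError(
                f"bladder expansion {e} mm: volume {mask.volume_cc:.1f} cc "
                f"misses target {target} cc by more than {VOLUME_TOLERANCE:.0%}"
            )
        bladder_configs.append((e, s, recipe, mask))

    cases = []
    for (re_, rs, r_recipe, rectum), (be, bs, b_recipe, bladder) in itertools.product(
        rectum_configs, bladder_configs
    ):
        case_id = f"S2_R{re_:.0f}e{rs:.0f}s_B{be:.0f}e{bs:.0f}s"
        provenance = {
            "case_id": case_id,
            "family": "simulation2",
            "rectum_expansion_mm": re_,
            "rectum_posterior_shift_mm": rs,
            "bladder_expansion_mm": be,
            "bladder_anterior_shift_mm": bs,
            "ptv": ptv_recipe,
            "rectum": r_recipe,
            "bladder": b_recipe,
        }
        cases.append(
            GeometryCase.from_structures(case_id, ptv, rectum, bladder, provenance)
        )
    return cases
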