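"""Scalar plan metrics: DVH queries, conformity, homogeneity, COPP/POPP.

Dose-volume conventions
-----------------------
* ``V_xGy`` is the percentage of a structure's volume receiving at least
  ``x`` Gy.  Threshold comparisons use the closed bound (``>=``) throughout;
  "receiving the prescription dose" and "receiving more than the
  prescription dose" are harmonized to ``>= Rx`` (switchable via the
  ``inclusive`` flag where it could matter).
* ``D_p`` is the minimum dose covering ``p`` % of the structure, computed
  from exact voxel-dose order statistics rather than interpolated histogram
  bins, so the homogeneity index does not depend on a bin width.

Predictive parameters
---------------------
For an OAR with volume ``V_OAR`` overlapping a target of volume ``V_PTV``
by ``V_OV``:

* conventional overlap parameter  ``COPP = V_OV / V_OAR``
* proposed overlap parameter      ``POPP = COPP * (V_PTV / V_OAR)``

COPP is blind to target size: two cases with equal overlap ratio but
different PTVs score identically.  POPP rescales by the PTV-to-OAR volume
ratio on the grounds that the achievable OAR sparing worsens as the target
grows relative to the OAR.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .dose_engine import DoseGrid
from .grid_geometry import GridMismatchError, StructureMask, overlap_volume

__all__ = [
    "DVHCurve",
    "PlanQualityMetrics",
    "OverlapFeatures",
    "cumulative_dvh",
    "volume_at_dose",
    "volume_at_dose_direct",
    "dose_at_volume",
    "mean_dose",
    "conformity_number",
    "homogeneity_index",
    "plan_quality",
    "overlap_features",
]


def _structure_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if dose.grid != mask.grid:
        raise GridMismatchError("dose and mask must share a grid")
    if mask.is_empty:
        raise ValueError(f"structure {mask.label or '(unnamed)'} is empty")
    return dose.dose[mask.occupancy]


@dataclasses.dataclass
class DVHCurve:
    """Cumulative relative DVH of one structure.

    ``cum_rel_volume[i]`` is the fraction of the structure receiving at
    least ``dose_edges[i]``; the exact voxel doses are retained so
    percentile queries bypass the display binning.
    """

    label: str
    dose_edges: np.ndarray
    cum_rel_volume: np.ndarray
    voxel_doses: np.ndarray  # sorted ascending

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.dose_edges) > 0)
        assert np.all(np.diff(self.cum_rel_volume) <= 1e-12)


def cumulative_dvh(dose: DoseGrid, mask: StructureMask, bin_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH over the mask's voxels with display bin width ``bin_gy``."""
    if bin_gy <= 0:
        raise ValueError("bin_gy must be positive")
    doses = np.sort(_structure_doses(dose, mask))
    top = doses[-1] + bin_gy
    edges = np.arange(0.0, top + bin_gy, bin_gy)
    # fraction with dose >= edge (closed bound)
    frac = 1.0 - np.searchsorted(doses, edges, side="left") / doses.size
    return DVHCurve(mask.label, edges, frac, doses)


def volume_at_dose(dvh: DVHCurve, threshold_gy: float, relative: bool = True) -> float:
    """V_xGy from a DVH: percent of the structure receiving >= ``threshold_gy``."""
    if threshold_gy < 0:
        raise ValueError("threshold must be non-negative")
    n = dvh.voxel_doses.size
    frac = 1.0 - np.searchsorted(dvh.voxel_doses, threshold_gy, side="left") / n
    return 100.0 * frac if relative else frac


def volume_at_dose_direct(
    dose: DoseGrid, mask: StructureMask, threshold_gy: float, inclusive: bool = True
) -> float:
    """V_xGy in percent straight from dose + mask (no DVH object)."""
    doses = _structure_doses(dose, mask)
    hit = doses >= threshold_gy if inclusive else doses > threshold_gy
    return 100.0 * float(np.count_nonzero(hit)) / doses.size


def dose_at_volume(dvh: DVHCurve, percent: float) -> float:
    """D_p: the minimum dose covering ``percent`` % of the structure.

    Exact order statistic: with n voxel doses sorted descending, D_p is the
    ceil(p/100 * n)-th highest dose, the smallest d with V(d) >= p.
    """
    if not (0 < percent <= 100):
        raise ValueError("percent must be in (0, 100]")
    doses = dvh.voxel_doses
    n = doses.size
    k = int(np.ceil(percent / 100.0 * n))
    return float(doses[n - k])


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Arithmetic mean voxel dose within the structure, Gy."""
    return float(_structure_doses(dose, mask).mean())


@dataclasses.dataclass
class PlanQualityMetrics:
    """Conformity and homogeneity of one plan.

    ``cn = (TV_PIV / TV) * (TV_PIV / PIV)`` with TV the target volume, PIV
    the prescription-isodose volume and TV_PIV their intersection;
    ``hi = (D2 - D98) / D50`` over the target.
    """

    cn: float
    tv_cc: float
    piv_cc: float
    tv_piv_cc: float
    hi: float | None = None
    d2_gy: float | None = None
    d50_gy: float | None = None
    d98_gy: float | None = None


def conformity_number(
    dose: DoseGrid, ptv: StructureMask, rx_gy: float, inclusive: bool = True
) -> PlanQualityMetrics:
    """Conformity number and its component volumes.

    ``PIV = 0`` (no voxel reaches the prescription) is reported as CN = 0
    with a warning rather than an error.
    """
    if rx_gy <= 0:
        raise ValueError("rx_gy must be positive")
    if ptv.is_empty:
        raise ValueError("PTV is empty")
    if dose.grid != ptv.grid:
        raise GridMismatchError("dose and PTV must share a grid")
    vox_cc = ptv.grid.voxel_volume_cc
    hot = dose.dose >= rx_gy if inclusive else dose.dose > rx_gy
    tv = ptv.volume_cc
    piv = float(np.count_nonzero(hot)) * vox_cc
    tv_piv = float(np.count_nonzero(hot & ptv.occupancy)) * vox_cc
    if piv == 0.0:
        warnings.warn("no voxel reaches the prescription dose; CN defined as 0",
                      stacklevel=2)
        cn = 0.0
    else:
        cn = (tv_piv / tv) * (tv_piv / piv)
    return PlanQualityMetrics(cn=cn, tv_cc=tv, piv_cc=piv, tv_piv_cc=tv_piv)


def homogeneity_index(dose: DoseGrid, ptv: StructureMask) -> float:
    """HI = (D2 - D98) / D50 within the PTV; 0 for a perfectly flat dose."""
    dvh = cumulative_dvh(dose, ptv)
    d50 = dose_at_volume(dvh, 50.0)
    if d50 <= 0:
        raise ValueError("D50 is zero; homogeneity index undefined")
    return (dose_at_volume(dvh, 2.0) - dose_at_volume(dvh, 98.0)) / d50


def plan_quality(dose: DoseGrid, ptv: StructureMask, rx_gy: float) -> PlanQualityMetrics:
    """CN, HI and the underlying component volumes / percentile doses."""
    pq = conformity_number(dose, ptv, rx_gy)
    dvh = cumulative_dvh(dose, ptv)
    pq.d2_gy = dose_at_volume(dvh, 2.0)
    pq.d50_gy = dose_at_volume(dvh, 50.0)
    pq.d98_gy = dose_at_volume(dvh, 98.0)
    pq.hi = (pq.d2_gy - pq.d98_gy) / pq.d50_gy if pq.d50_gy > 0 else np.nan
    return pq


@dataclasses.dataclass(frozen=True)
class OverlapFeatures:
    """Overlap geometry of one OAR against the PTV, with COPP and POPP."""

    v_ov_cc: float
    v_oar_cc: float
    v_ptv_cc: float

    @property
    def copp(self) -> float:
        return self.v_ov_cc / self.v_oar_cc

    @property
    def popp(self) -> float:
        return self.copp * self.v_ptv_cc / self.v_oar_cc

    @classmethod
    def from_volumes(cls, v_ov_cc: float, v_oar_cc: float, v_ptv_cc: float) -> "OverlapFeatures":
        """Build directly from known volumes (e.g. published structure sets)."""
        if v_oar_cc <= 0:
            raise ValueError("OAR volume must be positive")
        if not (0 <= v_ov_cc <= min(v_oar_cc, v_ptv_cc) + 1e-9):
            raise ValueError("overlap volume must satisfy 0 <= V_OV <= min(V_OAR, V_PTV)")
        return cls(v_ov_cc, v_oar_cc, v_ptv_cc)


def overlap_features(oar: StructureMask, ptv: StructureMask) -> OverlapFeatures:
    """Measure V_OV, V_OAR, V_PTV from masks and expose COPP / POPP."""
    if oar.grid != ptv.grid:
        raise GridMismatchError("OAR and PTV must share a grid")
    if oar.is_empty:
        raise ValueError("OAR is empty; COPP is undefined (division by zero)")
    return OverlapFeatures(
        v_ov_cc=overlap_volume(oar, ptv),
        v_oar_cc=oar.volume_cc,
        v_ptv_cc=ptv.volume_cc,
    )
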