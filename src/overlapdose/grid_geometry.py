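"""Voxelized structure geometry.

All later stages (phantom construction, dose emulation, DVH metrics) operate
on boolean occupancy masks defined on a shared axis-aligned voxel lattice.
Coordinates follow the patient convention used throughout the package:

* ``+x`` = patient left, ``-x`` = right  (LR axis)
* ``+y`` = anterior,     ``-y`` = posterior  (AP axis)
* ``+z`` = superior,     ``-z`` = inferior  (SI axis)

Distances are millimetres, volumes are reported in cubic centimetres.
Occupancy uses the voxel-centre rule: a voxel belongs to a structure iff its
centre lies inside the analytic surface.  There is no partial-volume
weighting; volume accuracy is limited by the grid spacing (one 2 mm voxel is
0.008 cc).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "Ellipsoid",
    "Cylinder",
    "GridMismatchError",
    "OutOfBoundsError",
    "make_grid",
    "rasterize_primitive",
    "expand_mask",
    "shift_mask",
    "mask_volume",
    "overlap_volume",
]


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


class OutOfBoundsError(ValueError):
    """A geometric operation would push a structure off the grid."""


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned 3D lattice with physical spacing.

    ``origin_mm`` is the physical coordinate of the centre of voxel
    ``(0, 0, 0)``.  Arrays defined on the grid are indexed ``[ix, iy, iz]``.
    """

    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        object.__setattr__(self, "spacing_mm", tuple(float(v) for v in self.spacing_mm))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin_mm) != 3 or len(self.spacing_mm) != 3 or len(self.shape) != 3:
            raise ValueError("VoxelGrid needs 3-vectors for origin, spacing and shape")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be strictly positive, got {self.shape}")

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (mm^3 / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) voxel-centre coordinate arrays."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def empty_mask(self, label: str = "") -> "StructureMask":
        return StructureMask(self, np.zeros(self.shape, dtype=bool), label)


def make_grid(
    extent_mm: Sequence[float], spacing_mm: Union[float, Sequence[float]]
) -> VoxelGrid:
    """Build a grid covering ``extent_mm`` centred on the coordinate origin.

    The shape is ``ceil(extent / spacing)`` per axis, so the realized extent
    is never smaller than requested.
    """
    extent = np.asarray(extent_mm, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.ndim == 0:
        spacing = np.full(3, float(spacing))
    if extent.shape != (3,) or spacing.shape != (3,):
        raise ValueError("extent and spacing must be scalars or 3-vectors")
    if np.any(extent <= 0) or np.any(spacing <= 0):
        raise ValueError("extent and spacing must be strictly positive")
    shape = np.ceil(extent / spacing - 1e-9).astype(int)
    origin = -shape * spacing / 2.0 + spacing / 2.0
    return VoxelGrid(tuple(origin), tuple(spacing), tuple(shape))


@dataclasses.dataclass
class StructureMask:
    """Boolean occupancy of one structure on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    occupancy: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.grid.shape:
            raise GridMismatchError(
                f"occupancy shape {self.occupancy.shape} != grid shape {self.grid.shape}"
            )

    @property
    def volume_cc(self) -> float:
        return float(self.occupancy.sum()) * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())

    def centroid_mm(self) -> np.ndarray:
        """Physical centroid of the occupied voxels."""
        if self.is_empty:
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.occupancy)
        return np.asarray(self.grid.origin_mm) + idx.mean(axis=0) * np.asarray(
            self.grid.spacing_mm
        )

    def copy(self, label: str | None = None) -> "StructureMask":
        return StructureMask(
            self.grid, self.occupancy.copy(), self.label if label is None else label
        )


# ---------------------------------------------------------------------------
# analytic primitives
# ---------------------------------------------------------------------------

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclasses.dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre and (a, b, c) semiaxes in mm."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def shifted(self, offset_mm: Sequence[float]) -> "Ellipsoid":
        c = tuple(np.asarray(self.center, dtype=float) + np.asarray(offset_mm, dtype=float))
        return Ellipsoid(c, self.semiaxes)


@dataclasses.dataclass(frozen=True)
class Cylinder:
    """Finite circular cylinder along a coordinate axis (default SI / z)."""

    center: tuple[float, float, float]
    radius: float
    half_length: float
    axis: str = "z"

    def shifted(self, offset_mm: Sequence[float]) -> "Cylinder":
        c = tuple(np.asarray(self.center, dtype=float) + np.asarray(offset_mm, dtype=float))
        return Cylinder(c, self.radius, self.half_length, self.axis)


Primitive = Union[Ellipsoid, Cylinder]


def rasterize_primitive(grid: VoxelGrid, primitive: Primitive, label: str = "") -> StructureMask:
    """Voxelize an analytic solid with the voxel-centre inclusion rule.

    Degenerate primitives (a zero semiaxis, radius or half-length) rasterize
    to the empty mask.  A primitive entirely outside the grid raises a
    warning but still returns the empty mask.
    """
    x, y, z = grid.coordinate_arrays()
    if isinstance(primitive, Ellipsoid):
        a, b, c = (float(v) for v in primitive.semiaxes)
        if min(a, b, c) < 0:
            raise ValueError("ellipsoid semiaxes must be non-negative")
        if min(a, b, c) == 0:
            occ = np.zeros(grid.shape, dtype=bool)
        else:
            cx, cy, cz = primitive.center
            occ = (
                ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2
            ) <= 1.0
    elif isinstance(primitive, Cylinder):
        if primitive.radius < 0 or primitive.half_length < 0:
            raise ValueError("cylinder radius and half-length must be non-negative")
        if primitive.axis not in _AXIS_INDEX:
            raise ValueError(f"unknown cylinder axis {primitive.axis!r}")
        if primitive.radius == 0 or primitive.half_length == 0:
            occ = np.zeros(grid.shape, dtype=bool)
        else:
            coords = [x, y, z]
            ax = _AXIS_INDEX[primitive.axis]
            radial = [i for i in range(3) if i != ax]
            c = primitive.center
            r2 = sum((coords[i] - c[i]) ** 2 for i in radial)
            occ = (r2 <= primitive.radius**2) & (
                np.abs(coords[ax] - c[ax]) <= primitive.half_length
            )
    else:
        raise ValueError(f"unknown primitive kind: {type(primitive).__name__}")

    if isinstance(primitive, (Ellipsoid, Cylinder)) and not occ.any():
        degenerate = (
            isinstance(primitive, Ellipsoid) and min(primitive.semiaxes) == 0
        ) or (
            isinstance(primitive, Cylinder)
            and (primitive.radius == 0 or primitive.half_length == 0)
        )
        if not degenerate:
            warnings.warn(
                f"primitive {primitive!r} does not intersect the grid; mask is empty",
                stacklevel=2,
            )
    return StructureMask(grid, occ, label)


# ---------------------------------------------------------------------------
# morphological operators
# ---------------------------------------------------------------------------

def _parse_margins(margins_mm) -> np.ndarray:
    """Normalize a margin spec to a (3, 2) array [[-x, +x], [-y, +y], [-z, +z]]."""
    m = np.asarray(margins_mm, dtype=float)
    if m.ndim == 0:
        out = np.full((3, 2), float(m))
    elif m.shape == (3,):
        out = np.repeat(m[:, None], 2, axis=1)
    elif m.shape == (3, 2):
        out = m.copy()
    elif m.shape == (6,):
        out = m.reshape(3, 2)
    else:
        raise ValueError(
            "margins must be a scalar, a per-axis 3-vector, or per-axis (-,+) pairs"
        )
    if not np.all(np.isfinite(out)) or np.any(out < 0):
        raise ValueError(f"margins must be finite and non-negative, got {out.tolist()}")
    return out


def expand_mask(mask: StructureMask, margins_mm, label: str | None = None) -> StructureMask:
    """Anisotropic margin expansion.

    ``margins_mm`` may be a scalar (uniform margin), a per-axis 3-vector
    (symmetric on both senses of each axis, e.g. "AP and LR" expansion =
    ``(m, m, 0)``), or per-axis ``(-,+)`` pairs.  A voxel is added iff its
    centre lies within the margin ellipsoid of some occupied voxel centre,
    i.e. Euclidean distance computed in coordinates scaled so the requested
    per-axis margins map to a unit ball.  Zero-margin axes do not expand.
    The result always contains the input.
    """
    if mask.is_empty:
        raise ValueError("cannot expand an empty mask")
    margins = _parse_margins(margins_mm)
    if np.all(margins == 0):
        return mask.copy(label)
    spacing = np.asarray(mask.grid.spacing_mm)

    symmetric = np.allclose(margins[:, 0], margins[:, 1])
    if symmetric:
        m = margins[:, 0]
        # Distance transform of the background in coordinates scaled by the
        # per-axis margin; occupied-or-within-unit-distance is the expansion.
        # Zero-margin axes get an effectively infinite step cost.
        big = 1e9
        sampling = np.where(m > 0, spacing / np.where(m > 0, m, 1.0), big)
        dist = ndimage.distance_transform_edt(~mask.occupancy, sampling=sampling)
        occ = dist <= 1.0 + 1e-9
    else:
        occ = ndimage.binary_dilation(
            mask.occupancy, structure=_margin_structuring_element(margins, spacing)
        )
    out = StructureMask(mask.grid, occ, mask.label if label is None else label)
    return out


def _margin_structuring_element(margins: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Dilation kernel whose reach is the (possibly asymmetric) margin ellipsoid."""
    half = np.ceil(margins.max(axis=1) / spacing).astype(int)
    offsets = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    r2 = np.zeros_like(offsets[0], dtype=float)
    inside = np.ones_like(offsets[0], dtype=bool)
    for ax in range(3):
        off = offsets[ax]
        m_neg, m_pos = margins[ax]
        m = np.where(off >= 0, m_pos, m_neg)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(m > 0, (off / np.where(m > 0, m, 1.0)) ** 2, np.inf)
        term = np.where(off == 0, 0.0, term)
        bad = (m == 0) & (off != 0)
        inside &= ~bad
        r2 = r2 + np.where(bad, 0.0, np.where(np.isfinite(term), term, 0.0))
    # binary_dilation reflects the structuring element; the kernel grid is
    # symmetric in shape so asymmetric margins land on the intended senses.
    return inside & (r2 <= 1.0 + 1e-9)


def shift_mask(mask: StructureMask, offset_mm: Sequence[float], label: str | None = None) -> StructureMask:
    """Translate a mask by a whole-voxel-snapped offset.

    The offset is rounded to the nearest whole number of voxels per axis, so
    the occupied voxel count (hence volume) is preserved exactly.  If the
    translation would clip any occupied voxel at the grid boundary an
    :class:`OutOfBoundsError` is raised instead of silently truncating.
    """
    offset = np.asarray(offset_mm, dtype=float)
    if offset.shape != (3,) or not np.all(np.isfinite(offset)):
        raise ValueError("offset must be a finite 3-vector")
    spacing = np.asarray(mask.grid.spacing_mm)
    steps = np.rint(offset / spacing).astype(int)
    if np.all(steps == 0):
        return mask.copy(label)
    if mask.is_empty:
        return mask.copy(label)

    idx = np.argwhere(mask.occupancy)
    lo = idx.min(axis=0) + steps
    hi = idx.max(axis=0) + steps
    if np.any(lo < 0) or np.any(hi >= np.asarray(mask.grid.shape)):
        raise OutOfBoundsError(
            f"shift {offset.tolist()} mm ({steps.tolist()} voxels) pushes "
            f"{mask.label or 'mask'} past the grid boundary"
        )
    occ = np.zeros_like(mask.occupancy)
    src = tuple(
        slice(max(0, -s), mask.grid.shape[ax] - max(0, s)) for ax, s in enumerate(steps)
    )
    dst = tuple(
        slice(max(0, s), mask.grid.shape[ax] - max(0, -s)) for ax, s in enumerate(steps)
    )
    occ[dst] = mask.occupancy[src]
    return StructureMask(mask.grid, occ, mask.label if label is None else label)


def mask_volume(mask: StructureMask) -> float:
    """Structure volume in cc (occupied voxels x voxel volume)."""
    return mask.volume_cc


def overlap_volume(a: StructureMask, b: StructureMask) -> float:
    """Volume of the voxelwise intersection of two masks, in cc."""
    if a.grid != b.grid:
        raise GridMismatchError("overlap_volume requires masks on the same grid")
    return float(np.count_nonzero(a.occupancy & b.occupancy)) * a.grid.voxel_volume_cc
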