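"""Dose-grid / CT / structure data model and the geometric primitives.

Conventions
-----------
* Arrays are indexed ``(z, y, x)`` — frame, row, column order.
* ``origin`` is the physical position (mm) of the *center* of voxel
  ``(0, 0, 0)``; ``spacing`` is the per-axis voxel pitch (mm).  Both are
  ``(z, y, x)`` triples, as are all physical points.
* Dose is stored in Gy; CT values in Hounsfield units.
* Only axis-aligned geometries are supported; anything else is rejected
  loudly (QA software should not guess).

File format
-----------
``write_rtdose``/``read_rtdose`` use a plain-array dialect: a ``.npz``
archive with the dose stored as scaled unsigned integers plus a JSON
header carrying ``dose_grid_scaling``, ``origin_mm``, ``spacing_mm`` and
``unit`` — mirroring the RT Dose grid-scaling convention, so round trips
are exact to one scaling quantum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage

__all__ = [
    "DoseGrid",
    "CTVolume",
    "Structure",
    "StructureSet",
    "VoxelMask",
    "GeometryError",
    "DoseFileError",
    "read_rtdose",
    "write_rtdose",
    "rasterize_structure",
    "expand_margin",
    "resample_dose",
    "point_dose",
]

STRUCTURE_ROLES = ("iGTV", "ITV", "PTV", "lung", "spinal_cord", "external", "other")


class GeometryError(ValueError):
    """Raised for unsupported or inconsistent grid geometry."""


class DoseFileError(IOError):
    """Raised when a dose file is malformed (missing scaling, wrong unit...)."""


def _as_triple(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in np.asarray(v).ravel())
    if len(t) != 3:
        raise GeometryError(f"expected a (z, y, x) triple, got {v!r}")
    return t  # type: ignore[return-value]


def geometry_id(origin, spacing, shape) -> str:
    """Opaque identifier for an (origin, spacing, shape) geometry."""
    payload = json.dumps(
        {"o": _as_triple(origin), "s": _as_triple(spacing), "n": [int(n) for n in shape]}
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class _Grid3D:
    values: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    frame_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.origin = _as_triple(self.origin)
        self.spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacings must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")
        if not self.frame_id:
            self.frame_id = geometry_id(self.origin, self.spacing, self.values.shape)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def extent(self) -> list[tuple[float, float]]:
        """Per-axis (low, high) physical bounds of the voxel-center lattice."""
        return [
            (self.origin[a], self.origin[a] + self.spacing[a] * (self.shape[a] - 1))
            for a in range(3)
        ]

    def same_geometry(self, other: "_Grid3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )


@dataclass
class DoseGrid(_Grid3D):
    """Axis-aligned 3-D dose field in Gy.

    ``valid`` marks voxels carrying real data; resampling flags points
    that fell outside the source extent so downstream statistics can
    exclude them.
    """

    valid: np.ndarray | None = None

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("dose values must be >= 0")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise GeometryError("valid mask shape must match values")


@dataclass
class CTVolume(_Grid3D):
    """CT-like scalar volume in HU (typically within [-1024, 3000])."""


@dataclass
class Structure:
    """One named structure: a stack of planar polygons.

    Each contour is ``(z_mm, polygon)`` where ``polygon`` is an
    ``(n, 2)`` array of ``(y, x)`` vertices in mm, n >= 3.  Nested
    contours on one slice carve holes (even-odd rule).
    """

    name: str
    role: str = "other"
    contours: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        if self.role not in STRUCTURE_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {STRUCTURE_ROLES}")
        checked = []
        for z, poly in self.contours:
            poly = np.asarray(poly, dtype=np.float64)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError("each contour polygon needs >= 3 (y, x) vertices")
            checked.append((float(z), poly))
        self.contours = checked


@dataclass
class StructureSet:
    structures: list[Structure] = field(default_factory=list)

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    def get(self, name: str) -> Structure | None:
        try:
            return self[name]
        except KeyError:
            return None

    def names(self) -> list[str]:
        return [s.name for s in self.structures]


@dataclass
class VoxelMask:
    """Boolean occupancy of a structure on a grid geometry."""

    flags: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    frame_id: str = ""

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 3:
            raise GeometryError("mask must be 3-D")
        self.origin = _as_triple(self.origin)
        self.spacing = _as_triple(self.spacing)
        if not self.frame_id:
            self.frame_id = geometry_id(self.origin, self.spacing, self.flags.shape)

    @property
    def shape(self):
        return self.flags.shape

    @property
    def voxel_count(self) -> int:
        return int(self.flags.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def minus(self, other: "VoxelMask") -> "VoxelMask":
        """Set difference (e.g. lung minus iGTV), same geometry required."""
        if self.flags.shape != other.flags.shape:
            raise GeometryError("mask set-difference requires matching geometry")
        return VoxelMask(self.flags & ~other.flags, self.origin, self.spacing, self.frame_id)


# ---------------------------------------------------------------------------
# File I/O (plain-array RT Dose dialect)
# ---------------------------------------------------------------------------

_MAX_STORED = np.uint32(2**32 - 1)


def write_rtdose(grid: DoseGrid, path) -> None:
    """Write a dose grid as scaled integers + JSON header.

    The scaling quantum is ``max_dose / (2**32 - 1)`` so the round-trip
    error is at most one quantum.
    """
    if not isinstance(grid, DoseGrid):
        raise TypeError("write_rtdose expects a DoseGrid")
    vmax = float(grid.values.max()) if grid.values.size else 0.0
    scaling = vmax / float(_MAX_STORED) if vmax > 0 else 1.0
    stored = np.round(grid.values / scaling).astype(np.uint32) if vmax > 0 else np.zeros(
        grid.shape, dtype=np.uint32
    )
    header = {
        "modality": "RTDOSE",
        "unit": "GY",
        "dose_grid_scaling": scaling,
        "origin_mm": list(grid.origin),
        "spacing_mm": list(grid.spacing),
        "frame_id": grid.frame_id,
        "axis_order": "zyx",
    }
    with open(path, "wb") as fh:
        np.savez(fh, stored=stored, header=np.frombuffer(json.dumps(header).encode(), np.uint8))


def read_rtdose(path) -> DoseGrid:
    """Read a dose grid written by :func:`write_rtdose`.

    Raises :class:`DoseFileError` if the scaling tag is absent or the
    dose unit is not Gy, and :class:`GeometryError` for a declared
    non-axis-aligned orientation.
    """
    with np.load(path) as npz:
        if "header" not in npz or "stored" not in npz:
            raise DoseFileError(f"{path}: not a recognized dose file")
        header = json.loads(bytes(npz["header"]).decode())
        stored = npz["stored"]
    if header.get("axis_order", "zyx") != "zyx":
        raise GeometryError(f"{path}: unsupported (non-axis-aligned) orientation")
    if "dose_grid_scaling" not in header:
        raise DoseFileError(f"{path}: dose grid scaling tag is missing")
    unit = header.get("unit", "")
    if unit.upper() != "GY":
        raise DoseFileError(f"{path}: unsupported dose unit {unit!r} (expected Gy)")
    values = np.asarray(stored, dtype=np.float64) * float(header["dose_grid_scaling"])
    return DoseGrid(
        values=values,
        origin=header["origin_mm"],
        spacing=header["spacing_mm"],
        frame_id=header.get("frame_id", ""),
    )


# ---------------------------------------------------------------------------
# Geometry operations
# ---------------------------------------------------------------------------


def rasterize_structure(structure: Structure, geometry: _Grid3D | VoxelMask) -> VoxelMask:
    """Voxelize planar contours onto a grid: a voxel belongs to the mask
    iff its center lies inside the polygon on its slice (even-odd rule,
    so nested contours carve holes).

    A contour plane must coincide with a grid slice within half a slice
    spacing, otherwise :class:`GeometryError` is raised.
    """
    shape = geometry.shape if not isinstance(geometry, VoxelMask) else geometry.flags.shape
    origin, spacing = geometry.origin, geometry.spacing
    flags = np.zeros(shape, dtype=bool)

    if structure.contours:
        ny, nx = shape[1], shape[2]
        yy = origin[1] + spacing[1] * np.arange(ny)
        xx = origin[2] + spacing[2] * np.arange(nx)
        gy, gx = np.meshgrid(yy, xx, indexing="ij")
        centers = np.column_stack([gy.ravel(), gx.ravel()])

        for z, poly in structure.contours:
            k_f = (z - origin[0]) / spacing[0]
            k = int(round(k_f))
            if k < 0 or k >= shape[0] or abs(k_f - k) >= 0.5 - 1e-9:
                raise GeometryError(
                    f"contour plane z={z} mm does not coincide with any grid slice"
                )
            inside = _MplPath(poly).contains_points(centers).reshape(ny, nx)
            flags[k] ^= inside  # even-odd across nested contours

    fid = getattr(geometry, "frame_id", "")
    return VoxelMask(flags, origin, spacing, fid)


def expand_margin(mask: VoxelMask, margin_mm: float) -> VoxelMask:
    """Isotropic (physical-mm) margin expansion of a voxel mask.

    A voxel joins the output iff its center lies within ``margin_mm``
    (Euclidean, anisotropic spacing respected) of any input voxel
    center; the result is always a superset of the input.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0 or not mask.flags.any():
        return VoxelMask(mask.flags.copy(), mask.origin, mask.spacing, mask.frame_id)
    dist = ndimage.distance_transform_edt(~mask.flags, sampling=mask.spacing)
    return VoxelMask(dist <= margin_mm + 1e-9, mask.origin, mask.spacing, mask.frame_id)


def _index_coords(grid: _Grid3D, points_mm: np.ndarray) -> np.ndarray:
    """(n, 3) physical points -> (3, n) fractional index coordinates."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
    return ((pts - np.asarray(grid.origin)) / np.asarray(grid.spacing)).T


def point_dose(grid: DoseGrid, point_mm: Sequence[float]) -> float:
    """Trilinear-interpolated dose (Gy) at a physical point.

    The point must lie inside the voxel-center extent of the grid.
    """
    coords = _index_coords(grid, point_mm)
    upper = np.asarray(grid.shape, dtype=float) - 1
    if np.any(coords.ravel() < -1e-9) or np.any(coords.ravel() > upper + 1e-9):
        raise GeometryError(f"point {tuple(point_mm)} mm lies outside the grid extent")
    val = ndimage.map_coordinates(grid.values, coords, order=1, mode="nearest")
    return float(val[0])


def resample_dose(grid: DoseGrid, target: _Grid3D | VoxelMask) -> DoseGrid:
    """Resample a dose grid onto a target geometry by trilinear
    interpolation.  Target points outside the source voxel-center extent
    are flagged invalid (``valid=False``) and set to 0 Gy.
    """
    shape = target.shape if not isinstance(target, VoxelMask) else target.flags.shape
    t_origin = np.asarray(target.origin)
    t_spacing = np.asarray(target.spacing)

    axes = [
        (t_origin[a] + t_spacing[a] * np.arange(shape[a]) - grid.origin[a]) / grid.spacing[a]
        for a in range(3)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([zz.ravel(), yy.ravel(), xx.ravel()])
    values = ndimage.map_coordinates(grid.values, coords, order=1, mode="nearest").reshape(shape)

    upper = np.asarray(grid.shape) - 1
    valid = np.ones(shape, dtype=bool)
    for a, ax in enumerate(axes):
        ok = (ax >= -1e-9) & (ax <= upper[a] + 1e-9)
        sl = [np.newaxis] * 3
        sl[a] = slice(None)
        valid &= ok[tuple(sl)]
    values = np.where(valid, values, 0.0)
    values[values < 0] = 0.0

    fid = getattr(target, "frame_id", "")
    return DoseGrid(values, tuple(t_origin), tuple(t_spacing), fid, valid=valid)
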