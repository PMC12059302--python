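"""Regular-grid scalar fields for dose and density.

All grids live in a fixed patient frame with axes ordered (x, y, z):
x toward patient-left, y toward patient-posterior, z toward patient-superior
(the DICOM LPS convention), coordinates in mm.  A grid is described by the
position of the *center* of voxel (0, 0, 0), per-axis voxel spacings and
per-axis voxel counts; value arrays are indexed ``values[ix, iy, iz]``.

Treatment dose and imaging dose are typically computed on different grids;
:func:`resample_to` harmonizes them (trilinear interpolation, zero outside
the source support) so that :func:`add` can accumulate them voxelwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "GridGeometry",
    "DoseGrid",
    "DensityGrid",
    "MATERIALS",
    "MATERIAL_CODES",
    "resample_to",
    "add",
    "scale",
]

#: Material classes recognized by :class:`DensityGrid`, in code order.
MATERIALS = ("air", "lung", "soft", "bone")
MATERIAL_CODES = {name: i for i, name in enumerate(MATERIALS)}


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular 3D grid.

    Parameters
    ----------
    origin
        Position (mm) of the center of voxel ``(0, 0, 0)`` in the patient frame.
    spacing
        Per-axis voxel edge lengths (mm); all strictly positive.
    dims
        Per-axis voxel counts; all >= 1.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must each have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be > 0, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1, got {self.dims}")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) voxel-center coordinate arrays."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def points(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array in C index order."""
        x, y, z = np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2), indexing="ij"
        )
        return np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) index coordinates of world points (N, 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer grid box (lo, hi) in mm: voxel-center extent plus half a voxel."""
        o = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        n = np.asarray(self.dims)
        return o - 0.5 * sp, o + (n - 0.5) * sp


def _check_values(geometry: GridGeometry, values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != geometry.dims:
        raise ValueError(
            f"{what} array shape {arr.shape} does not match grid dims {geometry.dims}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite values")
    if np.any(arr < 0):
        raise ValueError(f"{what} contains negative values")
    return arr


@dataclass(frozen=True)
class DoseGrid:
    """Absorbed dose (Gy) on a regular grid; finite, non-negative values."""

    geometry: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_values(self.geometry, self.values, "dose"))

    def max(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class DensityGrid:
    """Mass density relative to water plus a per-voxel material class.

    ``materials`` holds integer codes into :data:`MATERIALS`
    (air=0, lung=1, soft=2, bone=3); the bone class drives the kV
    dose-enhancement factor of the imaging surrogate.
    """

    geometry: GridGeometry
    values: np.ndarray = field(repr=False)
    materials: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", _check_values(self.geometry, self.values, "density")
        )
        mats = np.asarray(self.materials)
        if mats.shape != self.geometry.dims:
            raise ValueError("materials array shape does not match grid dims")
        if mats.min() < 0 or mats.max() >= len(MATERIALS):
            raise ValueError("material codes outside the air/lung/soft/bone set")
        object.__setattr__(self, "materials", mats.astype(np.uint8))

    def material_mask(self, name: str) -> np.ndarray:
        return self.materials == MATERIAL_CODES[name]


def resample_to(src: DoseGrid, target: GridGeometry) -> DoseGrid:
    """Resample a dose grid onto a target geometry.

    Trilinear interpolation at target voxel centers; any target center
    outside the source voxel-center support maps to 0 Gy.  Within the
    support the result is a convex combination of source voxel values.
    """
    if not np.all(np.isfinite(src.values)):  # DoseGrid enforces this, belt+braces
        raise ValueError("source dose contains non-finite values")
    if target == src.geometry:
        return DoseGrid(target, src.values.copy())
    idx = src.geometry.world_to_index(target.points()).T  # (3, N) fractional indices
    vals = map_coordinates(src.values, idx, order=1, mode="nearest")
    # zero outside the voxel-center support
    n = np.asarray(src.geometry.dims, dtype=float)
    inside = np.all(idx >= 0.0, axis=0) & np.all(idx <= (n - 1)[:, None], axis=0)
    vals = np.where(inside, vals, 0.0)
    return DoseGrid(target, vals.reshape(target.dims))


def add(a: DoseGrid, b: DoseGrid) -> DoseGrid:
    """Voxelwise sum of two dose grids sharing one geometry."""
    if a.geometry != b.geometry:
        raise ValueError(
            "cannot add dose grids on different geometries: "
            f"{a.geometry} vs {b.geometry}; resample first"
        )
    return DoseGrid(a.geometry, a.values + b.values)


def scale(a: DoseGrid, k: float) -> DoseGrid:
    """Multiply a dose grid by a non-negative scalar (image counts, mAs ratios)."""
    if k < 0:
        raise ValueError(f"scale factor must be >= 0, got {k}")
    return DoseGrid(a.geometry, a.values * float(k))
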