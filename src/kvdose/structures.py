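"""Anatomical regions: rasterization, margin expansion, volume bookkeeping.

A :class:`Structure` carries either closed planar contours (per-slice
polygons in mm, the form exported by treatment planning systems) or a
boolean voxel mask on a :class:`~kvdose.grids.GridGeometry`, or both.
Planning margins (PTV = tumor + 5 mm, PRV = organ + 5 mm) are isotropic
3D Euclidean expansions computed on the voxel lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.ndimage import distance_transform_edt
from shapely.geometry import Polygon as ShapelyPolygon

from .grids import GridGeometry

__all__ = [
    "Structure",
    "StructureSet",
    "rasterize",
    "expand_margin",
    "volume_cc",
    "DEFAULT_ALIASES",
]

#: ROI-name aliases used when importing third-party structure sets.
DEFAULT_ALIASES = {
    "Lung_L": "Lt Lung",
    "Lung_R": "Rt Lung",
    "LeftLung": "Lt Lung",
    "RightLung": "Rt Lung",
    "SpinalCord_PRV": "Spinal Cord PRV",
    "Cord PRV": "Spinal Cord PRV",
    "Esophagus_PRV": "Esophagus PRV",
    "Trachea_PRV": "Trachea PRV",
    "BronchialTree": "PB Tree",
    "Chestwall": "ChestWall",
    "Chest Wall": "ChestWall",
}


@dataclass
class Structure:
    """A named anatomical region (PTV, OAR or support structure)."""

    name: str
    role: str = "OAR"  # one of {"PTV", "OAR", "support"}
    contours: list[tuple[float, np.ndarray]] | None = None  # (z_mm, (N, 2) xy mm)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.contours is None and self.mask is None:
            raise ValueError(f"structure {self.name!r} has neither contours nor a mask")
        if self.role not in ("PTV", "OAR", "support"):
            raise ValueError(f"unknown role {self.role!r}")

    def get_mask(self, frame: GridGeometry) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != frame.dims:
                raise ValueError(
                    f"mask of {self.name!r} has shape {self.mask.shape}, "
                    f"frame dims are {frame.dims}"
                )
            return self.mask
        return rasterize(self.contours, frame)


@dataclass
class StructureSet:
    """Unique-named structures sharing one grid frame."""

    frame: GridGeometry
    structures: dict[str, Structure] = field(default_factory=dict)

    def add(self, structure: Structure) -> None:
        if structure.name in self.structures:
            raise ValueError(f"duplicate structure name {structure.name!r}")
        self.structures[structure.name] = structure

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def __getitem__(self, name: str) -> Structure:
        return self.structures[name]

    def names(self) -> list[str]:
        return list(self.structures)

    def mask(self, name: str) -> np.ndarray:
        return self.structures[name].get_mask(self.frame)


def rasterize(
    contours: list[tuple[float, np.ndarray]] | None, target: GridGeometry
) -> np.ndarray:
    """Rasterize closed planar polygons to a boolean mask.

    A voxel is inside iff its center is inside the polygon (even-odd rule);
    polygons sharing a slice are combined by XOR, so holes are expressed as
    nested polygons.  Each polygon's plane must lie within half a slice
    spacing of a grid slice.
    """
    mask = np.zeros(target.dims, dtype=bool)
    if not contours:
        return mask
    zs = target.axis_coords(2)
    xc = target.axis_coords(0)
    yc = target.axis_coords(1)
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    for z_mm, poly in contours:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("each contour must be an (N>=3, 2) array of xy mm")
        k = int(np.argmin(np.abs(zs - z_mm)))
        if abs(zs[k] - z_mm) > 0.5 * target.spacing[2] + 1e-9:
            raise ValueError(
                f"contour plane z={z_mm} mm is farther than half a slice from any grid slice"
            )
        ring = poly if np.allclose(poly[0], poly[-1]) else np.vstack([poly, poly[:1]])
        sp = ShapelyPolygon(ring)
        if not sp.is_valid:
            warnings.warn(
                f"self-intersecting contour at z={z_mm} mm; using even-odd fill",
                stacklevel=2,
            )
        inside = MplPath(ring).contains_points(pts).reshape(len(xc), len(yc))
        mask[:, :, k] ^= inside
    return mask


def expand_margin(
    mask: np.ndarray, margin_mm: float, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Isotropic Euclidean expansion of a boolean mask.

    An output voxel is true iff its center lies within ``margin_mm`` of any
    true input voxel center; anisotropic spacing is respected through the
    sampled Euclidean distance transform.  ``margin_mm == 0`` is the identity.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0 mm, got {margin_mm}")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm + 1e-9


def volume_cc(mask: np.ndarray, geometry: GridGeometry) -> float:
    """Volume of a mask in cc (1 cc = 1000 mm^3)."""
    if mask.shape != geometry.dims:
        raise ValueError("mask shape does not match geometry dims")
    return float(np.count_nonzero(mask)) * geometry.voxel_volume_cc
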