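"""DICOM-RT import: RTDOSE grids, RTSTRUCT contours, CT density.

The optional real-data path.  Grids come back in the package's fixed
patient frame (x left, y posterior, z superior — the DICOM LPS axes), so
datasets whose ImageOrientationPatient is the identity orientation map
directly; anything else is rejected rather than silently resampled.
"""

from __future__ import annotations

import numpy as np
import pydicom

from ..grids import DensityGrid, DoseGrid, GridGeometry, MATERIAL_CODES
from ..structures import DEFAULT_ALIASES, Structure, StructureSet

__all__ = ["read_rtdose", "read_rtstruct", "density_from_hu", "HU_DENSITY_TABLE"]

#: Piecewise-linear HU -> relative (to water) mass density calibration points.
HU_DENSITY_TABLE = ((-1000.0, 0.001), (-700.0, 0.25), (0.0, 1.0), (1000.0, 1.6))

#: HU thresholds for the four material classes (air | lung | soft | bone).
HU_MATERIAL_THRESHOLDS = {"air": -900.0, "lung": -300.0, "soft": 250.0}

_IDENTITY_IOP = (1, 0, 0, 0, 1, 0)


def _check_axial(ds) -> None:
    iop = getattr(ds, "ImageOrientationPatient", list(_IDENTITY_IOP))
    if not np.allclose([float(v) for v in iop], _IDENTITY_IOP, atol=1e-4):
        raise ValueError("only identity-orientation (axial LPS) datasets are supported")


def read_rtdose(path) -> DoseGrid:
    """Read an RTDOSE file into a DoseGrid (DoseGridScaling applied)."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ValueError(f"{path} is not an RTDOSE dataset")
    _check_axial(ds)
    scaling = float(ds.DoseGridScaling)
    # pixel_array is (frames=z, rows=y, cols=x); reorder to (x, y, z)
    arr = ds.pixel_array.astype(float) * scaling
    arr = np.transpose(arr, (2, 1, 0))
    ipp = [float(v) for v in ds.ImagePositionPatient]
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise ValueError("non-uniform GridFrameOffsetVector is not supported")
    z_sp = float(dz[0]) if offsets.size > 1 else 1.0
    origin = (ipp[0], ipp[1], ipp[2] + float(offsets[0]))
    geom = GridGeometry(origin, (col_sp, row_sp, abs(z_sp)), arr.shape)
    if z_sp < 0:
        arr = arr[:, :, ::-1]
    return DoseGrid(geom, arr)


def density_from_hu(hu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map HU to relative density and material class via the fixed tables."""
    pts = np.asarray(HU_DENSITY_TABLE)
    dens = np.interp(hu, pts[:, 0], pts[:, 1])
    mats = np.full(hu.shape, MATERIAL_CODES["bone"], dtype=np.uint8)
    mats[hu <= HU_MATERIAL_THRESHOLDS["soft"]] = MATERIAL_CODES["soft"]
    mats[hu <= HU_MATERIAL_THRESHOLDS["lung"]] = MATERIAL_CODES["lung"]
    mats[hu <= HU_MATERIAL_THRESHOLDS["air"]] = MATERIAL_CODES["air"]
    return dens, mats


def read_ct_series(paths) -> DensityGrid:
    """Read an axial CT series (one file per slice) into a DensityGrid."""
    slices = [pydicom.dcmread(p) for p in paths]
    for ds in slices:
        _check_axial(ds)
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.asarray([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zs)
    if len(zs) > 1 and not np.allclose(dz, dz[0], atol=1e-3):
        raise ValueError("non-uniform CT slice spacing is not supported")
    first = slices[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    hu = np.stack(
        [
            ds.pixel_array.astype(float) * float(getattr(ds, "RescaleSlope", 1.0))
            + float(getattr(ds, "RescaleIntercept", 0.0))
            for ds in slices
        ],
        axis=-1,
    )  # (rows=y, cols=x, z)
    hu = np.transpose(hu, (1, 0, 2))  # (x, y, z)
    ipp = [float(v) for v in first.ImagePositionPatient]
    geom = GridGeometry(
        (ipp[0], ipp[1], zs[0]),
        (col_sp, row_sp, float(dz[0]) if len(zs) > 1 else 1.0),
        hu.shape,
    )
    dens, mats = density_from_hu(hu)
    return DensityGrid(geom, dens, mats)


def read_rtstruct(
    path, frame: GridGeometry, aliases: dict[str, str] | None = None
) -> StructureSet:
    """Read RTSTRUCT contours, mapping ROI names through the alias table."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise ValueError(f"{path} is not an RTSTRUCT dataset")
    alias = dict(DEFAULT_ALIASES)
    alias.update(aliases or {})
    names = {
        int(roi.ROINumber): alias.get(str(roi.ROIName), str(roi.ROIName))
        for roi in ds.StructureSetROISequence
    }
    sset = StructureSet(frame=frame)
    for roi in ds.ROIContourSequence:
        name = names[int(roi.ReferencedROINumber)]
        contours = []
        for c in getattr(roi, "ContourSequence", []):
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            contours.append((float(pts[0, 2]), pts[:, :2]))
        if contours:
            role = "PTV" if name.upper().startswith("PTV") else "OAR"
            sset.add(Structure(name, role=role, contours=contours))
    return sset
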