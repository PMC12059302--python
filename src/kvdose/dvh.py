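"""Cumulative DVH construction and dose/volume metrics.

All constraint metrics are computed directly from the sorted voxel doses
inside a structure mask, so that the DVH bin width never limits accuracy;
the binned :class:`CumulativeDVH` exists for export and plotting.

Conventions
-----------
* "Volume receiving a dose higher than D" is evaluated as ``dose >= D`` at
  the voxel level (a measure-zero difference for continuous dose fields
  that keeps the uniform-dose edge case well behaved).  A strict ``>``
  mode is available via ``strict=True``.
* Dmax follows the clinical 0.03 cc convention: voxels are sorted by
  descending dose, volume is accumulated, and the dose is interpolated
  linearly inside the voxel in which the cumulative volume crosses 0.03 cc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid

__all__ = [
    "CumulativeDVH",
    "compute_dvh",
    "dose_at_volume",
    "dose_at_volume_pct",
    "mean_dose",
    "volume_above_cc",
    "volume_above_pct",
    "ptv_v_pct_of_rx",
    "DMAX_VOLUME_CC",
]

#: Clinical "maximum dose" reporting volume (cc).
DMAX_VOLUME_CC = 0.03


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative dose-volume histogram.

    ``volume_cc[i]`` is the structure volume receiving at least
    ``dose_edges[i]``; it is non-increasing, starts at the total structure
    volume (every voxel receives >= 0 Gy) and ends at or above zero.
    """

    dose_edges: np.ndarray
    volume_cc: np.ndarray
    total_volume_cc: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        vols = np.asarray(self.volume_cc, dtype=float)
        if edges.ndim != 1 or edges.shape != vols.shape:
            raise ValueError("dose_edges and volume_cc must be matching 1D arrays")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("dose_edges must be strictly increasing")
        if np.any(np.diff(vols) > 1e-9):
            raise ValueError("cumulative volume must be non-increasing")
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume_cc", vols)

    def to_text(self) -> str:
        """Two-column plain-text export (dose Gy, volume cc)."""
        lines = ["# dose_Gy\tvolume_cc"]
        lines += [f"{d:.4f}\t{v:.6f}" for d, v in zip(self.dose_edges, self.volume_cc)]
        return "\n".join(lines) + "\n"


def _masked_doses(dose: DoseGrid, mask: np.ndarray, structure: str = "") -> np.ndarray:
    if mask.shape != dose.geometry.dims:
        raise ValueError("mask shape does not match dose grid dims")
    vals = dose.values[mask]
    if vals.size == 0:
        raise ValueError(f"empty mask for structure {structure!r}")
    return vals


def compute_dvh(
    dose: DoseGrid, mask: np.ndarray, bin_width: float = 0.01, structure: str = ""
) -> CumulativeDVH:
    """Exact voxel-counting cumulative DVH at edges from 0 to max dose + one bin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = _masked_doses(dose, mask, structure)
    vv = dose.geometry.voxel_volume_cc
    n_bins = int(np.ceil(vals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    # volume receiving >= edge: count via sorted doses
    order = np.sort(vals)
    counts = vals.size - np.searchsorted(order, edges, side="left")
    return CumulativeDVH(edges, counts * vv, total_volume_cc=vals.size * vv)


def _sorted_curve(vals: np.ndarray, voxel_cc: float) -> tuple[np.ndarray, np.ndarray]:
    """(cumulative volume, dose) points of the descending-sorted voxel curve."""
    d = np.sort(vals)[::-1]
    v = voxel_cc * np.arange(1, d.size + 1)
    return v, d


def dose_at_volume(
    dose: DoseGrid, mask: np.ndarray, v_cc: float, structure: str = ""
) -> float:
    """Minimum dose received by the hottest ``v_cc`` of the structure (Gy).

    ``dose_at_volume(..., 0.03)`` is the clinical Dmax.  Linear
    interpolation between the cumulative-volume points of the
    descending-sorted voxel doses; for volumes inside the single hottest
    voxel the hottest voxel dose is returned.
    """
    vals = _masked_doses(dose, mask, structure)
    vv = dose.geometry.voxel_volume_cc
    total = vals.size * vv
    if v_cc <= 0:
        raise ValueError(f"requested volume must be > 0 cc, got {v_cc}")
    if v_cc > total + 1e-12:
        raise ValueError(
            f"requested volume {v_cc} cc exceeds structure volume {total:.6g} cc"
        )
    v, d = _sorted_curve(vals, vv)
    return float(np.interp(min(v_cc, total), v, d))


def dose_at_volume_pct(
    dose: DoseGrid, mask: np.ndarray, p: float, structure: str = ""
) -> float:
    """Dose to the hottest ``p`` percent of the structure (D2% at p=2)."""
    if not (0 < p <= 100):
        raise ValueError(f"percent volume must be in (0, 100], got {p}")
    vals = _masked_doses(dose, mask, structure)
    vv = dose.geometry.voxel_volume_cc
    return dose_at_volume(dose, mask, p / 100.0 * vals.size * vv, structure)


def mean_dose(dose: DoseGrid, mask: np.ndarray, structure: str = "") -> float:
    """Arithmetic mean dose over the masked voxels (Gy)."""
    return float(_masked_doses(dose, mask, structure).mean())


def volume_above_cc(
    dose: DoseGrid, mask: np.ndarray, threshold: float, strict: bool = False
) -> float:
    """Volume (cc) of masked voxels receiving at least ``threshold`` Gy."""
    if threshold < 0:
        raise ValueError("dose threshold must be >= 0")
    if mask.shape != dose.geometry.dims:
        raise ValueError("mask shape does not match dose grid dims")
    vals = dose.values[mask]
    hit = vals > threshold if strict else vals >= threshold
    return float(np.count_nonzero(hit)) * dose.geometry.voxel_volume_cc


def volume_above_pct(
    dose: DoseGrid, mask: np.ndarray, threshold: float,
    strict: bool = False, structure: str = "",
) -> float:
    """Percent of the structure volume receiving at least ``threshold`` Gy."""
    vals = _masked_doses(dose, mask, structure)
    hit = vals > threshold if strict else vals >= threshold
    return 100.0 * np.count_nonzero(hit) / vals.size


def ptv_v_pct_of_rx(
    dose: DoseGrid, ptv_mask: np.ndarray, rx_gy: float, pct_of_rx: float = 90.0,
    strict: bool = False,
) -> float:
    """Percent of the PTV receiving at least ``pct_of_rx`` % of the prescription.

    V90% (the coverage constraint ``PTV V90% > 99%``) is the default.
    """
    if rx_gy <= 0:
        raise ValueError("prescription dose must be > 0 Gy")
    if not (0 < pct_of_rx <= 100):
        raise ValueError("pct_of_rx must be in (0, 100]")
    return volume_above_pct(
        dose, ptv_mask, pct_of_rx / 100.0 * rx_gy, strict=strict, structure="PTV"
    )
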