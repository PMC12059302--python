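"""Native fixture bundle: JSON metadata + HDF5 arrays per patient case.

``<case_id>.json`` holds geometry, prescription, arcs and structure names;
``<case_id>.h5`` holds the float/boolean arrays (axis order x, y, z as
everywhere in the package).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from ..cohort import PatientCase
from ..grids import DensityGrid, DoseGrid, GridGeometry
from ..imaging import VmatArc
from ..protocols import Prescription
from ..structures import Structure, StructureSet

__all__ = ["save_case", "load_case"]


def save_case(case: PatientCase, directory: str | Path) -> Path:
    """Write one case bundle; returns the JSON path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "id": case.id,
        "geometry": {
            "origin": list(case.density.geometry.origin),
            "spacing": list(case.density.geometry.spacing),
            "dims": list(case.density.geometry.dims),
        },
        "prescription": {
            "rx_total": case.prescription.rx_total,
            "n_fractions": case.prescription.n_fractions,
        },
        "arcs": [
            {
                "gantry_start": a.gantry_start,
                "gantry_stop": a.gantry_stop,
                "direction": a.direction,
                "delivery_time_s": a.delivery_time_s,
            }
            for a in case.arcs
        ],
        "tumor_center_mm": list(case.tumor_center_mm),
        "lobe": case.lobe,
        "laterality": case.laterality,
        "structures": {
            name: case.structures[name].role for name in case.structures.names()
        },
    }
    json_path = directory / f"{case.id}.json"
    json_path.write_text(json.dumps(meta, indent=2) + "\n")
    with h5py.File(directory / f"{case.id}.h5", "w") as h5:
        h5.create_dataset("density", data=case.density.values.astype(np.float32),
                          compression="gzip")
        h5.create_dataset("materials", data=case.density.materials,
                          compression="gzip")
        h5.create_dataset("tx_dose", data=case.tx_dose.values.astype(np.float32),
                          compression="gzip")
        grp = h5.create_group("masks")
        for name in case.structures.names():
            grp.create_dataset(name, data=case.structures.mask(name),
                               compression="gzip")
    return json_path


def load_case(json_path: str | Path) -> PatientCase:
    """Read a case bundle written by :func:`save_case`."""
    json_path = Path(json_path)
    meta = json.loads(json_path.read_text())
    g = meta["geometry"]
    geom = GridGeometry(tuple(g["origin"]), tuple(g["spacing"]), tuple(g["dims"]))
    with h5py.File(json_path.with_suffix(".h5"), "r") as h5:
        density = np.asarray(h5["density"], dtype=float)
        materials = np.asarray(h5["materials"])
        tx = np.asarray(h5["tx_dose"], dtype=float)
        sset = StructureSet(frame=geom)
        for name, role in meta["structures"].items():
            sset.add(Structure(name, role=role,
                               mask=np.asarray(h5["masks"][name], dtype=bool)))
    return PatientCase(
        id=meta["id"],
        density=DensityGrid(geom, density, materials),
        structures=sset,
        tx_dose=DoseGrid(geom, tx),
        prescription=Prescription(**meta["prescription"]),
        arcs=[VmatArc(**a) for a in meta["arcs"]],
        tumor_center_mm=tuple(meta["tumor_center_mm"]),
        lobe=meta.get("lobe", ""),
        laterality=meta.get("laterality", ""),
    )
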