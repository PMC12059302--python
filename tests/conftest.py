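from __future__ import annotations

import numpy as np
import pytest

from kvdose import GridGeometry, DoseGrid, PipelineConfig, Prescription, make_phantom

#: Coarse phantom spacing (mm) used by the unit-test fixtures; keeps each
#: generated case below ~70k voxels.
COARSE_SPACING = 5.0


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture()
def unit_geometry() -> GridGeometry:
    """1 mm isotropic 20^3 grid centered near the origin."""
    return GridGeometry(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), dims=(20, 20, 20))


def make_dose(geometry: GridGeometry, values) -> DoseGrid:
    return DoseGrid(geometry, np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def coarse_case():
    """One 48 Gy/4 fr phantom at coarse resolution, near-limit planning."""
    return make_phantom(
        Prescription(48.0, 4), lobe="upper", laterality="left",
        stress=0.9, seed=7, spacing_mm=COARSE_SPACING,
    )


@pytest.fixture(scope="session")
def coarse_cfg() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.data["cohort"]["spacing_mm"] = COARSE_SPACING
    return cfg
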