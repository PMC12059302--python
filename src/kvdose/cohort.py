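"""Seeded synthetic thorax cohort generator.

Real lung-SBRT planning data are institutional; this module fabricates
desk-scale patient cases with the statistical structure the constraint
analysis needs: an elliptic-cylinder thorax with two low-density lungs,
posterior spinal canal and bone, mediastinal organs, skin and chest-wall
shells; a spherical tumor placed by lobe and laterality; and a
PTV-conformal treatment dose with radial exponential falloff whose scale
is tuned so that the most-exposed (binding) OAR constraint sits at a
controlled fraction of its limit:

    binding value = limit x (0.9 + 0.1 x stress),   stress in [0, 1]

so stress 0 leaves >= 10% headroom everywhere and stress 1 parks the
binding constraint exactly at its limit, where a ~1% imaging increment
can flip it from pass to fail.  The default cohort mix is 26 patients at
48 Gy/4 fr, 3 at 60 Gy/8 fr and 1 at 60 Gy/15 fr with the corresponding
upper/middle/lower-lobe and left/right placements.

Everything is a pure function of the recipe seed: the same seed yields
bit-identical cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .grids import DensityGrid, DoseGrid, GridGeometry, MATERIAL_CODES
from .imaging import VmatArc
from .protocols import (
    Prescription,
    evaluate_metric,
    load_protocol,
    protocol_for_fractions,
)
from .structures import Structure, StructureSet, expand_margin

__all__ = ["CohortRecipe", "PatientCase", "make_phantom", "make_cohort"]

#: PTV and PRV planning margin (mm).
PLANNING_MARGIN_MM = 5.0

#: Grid extent (mm) along (x, y, z); dims follow from the recipe spacing.
GRID_EXTENT_MM = (220.0, 180.0, 200.0)

#: Default cohort composition: (rx_total Gy, n_fractions, patient count).
DEFAULT_MIX = ((48.0, 4, 26), (60.0, 8, 3), (60.0, 15, 1))

#: Lobe and laterality composition per prescription, mirroring the cohort mix.
DEFAULT_SITES = {
    (48.0, 4): {"lobes": {"upper": 20, "middle": 3, "lower": 3},
                "lateralities": {"left": 10, "right": 16}},
    (60.0, 8): {"lobes": {"upper": 3}, "lateralities": {"left": 1, "right": 2}},
    (60.0, 15): {"lobes": {"upper": 1}, "lateralities": {"right": 1}},
}

_LOBE_Z_BANDS = {"upper": (25.0, 60.0), "middle": (-15.0, 15.0), "lower": (-60.0, -25.0)}


@dataclass(frozen=True)
class CohortRecipe:
    """Recipe for a reproducible synthetic cohort."""

    n_patients: int = 30
    prescription_mix: tuple[tuple[float, int, int], ...] = DEFAULT_MIX
    stress: float = 0.9
    seed: int = 0
    spacing_mm: float = 2.5

    def __post_init__(self) -> None:
        if sum(c for *_, c in self.prescription_mix) != self.n_patients:
            raise ValueError("prescription_mix counts must sum to n_patients")
        if not (0.0 <= self.stress <= 1.0):
            raise ValueError("stress must be in [0, 1]")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be > 0")


@dataclass
class PatientCase:
    """One synthetic patient: density, structures, treatment dose, plan."""

    id: str
    density: DensityGrid
    structures: StructureSet
    tx_dose: DoseGrid
    prescription: Prescription
    arcs: list[VmatArc]
    tumor_center_mm: tuple[float, float, float]
    lobe: str = ""
    laterality: str = ""

    @property
    def isocenter(self) -> tuple[float, float, float]:
        return self.tumor_center_mm


def _default_geometry(spacing: float) -> GridGeometry:
    dims = tuple(int(round(e / spacing)) for e in GRID_EXTENT_MM)
    origin = tuple(-(d - 1) / 2.0 * spacing for d in dims)
    return GridGeometry(origin, (spacing,) * 3, dims)


def _capsule_mask(x, y, z, p0, p1, radius):
    """Voxels within ``radius`` of the segment p0-p1 (broadcast coordinates)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    denom = float(d @ d)
    t = ((x - p0[0]) * d[0] + (y - p0[1]) * d[1] + (z - p0[2]) * d[2]) / denom
    t = np.clip(t, 0.0, 1.0)
    dx = x - (p0[0] + t * d[0])
    dy = y - (p0[1] + t * d[1])
    dz = z - (p0[2] + t * d[2])
    return dx * dx + dy * dy + dz * dz <= radius * radius


def _snap(geom: GridGeometry, axis: int, value: float) -> float:
    """Nearest voxel-center coordinate along one axis (keeps thin tubular
    organs non-empty at coarse grid spacings)."""
    coords = geom.axis_coords(axis)
    return float(coords[int(np.argmin(np.abs(coords - value)))])


def _build_anatomy(geom: GridGeometry, scale: float):
    """All organ masks for one phantom; returns (masks dict, body-depth array)."""
    x, y, z = geom.coordinate_grids()
    sp = geom.spacing
    s = scale
    # minimum tube radius that always captures the snapped center column
    r_min = 0.7 * max(sp)

    def r_eff(r: float) -> float:
        return max(r, r_min)

    body = (x / (92.0 * s)) ** 2 + (y / (62.0 * s)) ** 2 <= 1.0
    body = np.broadcast_to(body, geom.dims).copy()
    depth = distance_transform_edt(body, sampling=sp)
    # nominal 4 mm shell; at coarse spacing keep at least the one-voxel rind
    skin = body & (depth <= max(4.0, 1.01 * min(sp)))
    thorax_z = np.broadcast_to(np.abs(z) <= 72.0, geom.dims)
    chestwall = body & (depth > 3.0) & (depth <= 18.0) & thorax_z

    lung_params = {"left": +1.0, "right": -1.0}
    lungs = {}
    for side, sign in lung_params.items():
        ell = ((x - sign * 48.0 * s) / (30.0 * s)) ** 2 + ((y + 2.0) / (46.0 * s)) ** 2
        lungs[side] = np.broadcast_to(ell <= 1.0, geom.dims) & thorax_z

    x0 = _snap(geom, 0, 0.0)
    cord_y = _snap(geom, 1, 42.0 * s)
    cord = np.broadcast_to(
        (x - x0) ** 2 + (y - cord_y) ** 2 <= r_eff(5.0) ** 2, geom.dims
    ).copy()
    r2_vert = (x - x0) ** 2 + (y - cord_y) ** 2
    vertebra = np.broadcast_to((r2_vert > 7.0 ** 2) & (r2_vert <= 15.0 ** 2), geom.dims)
    rib_bands = np.broadcast_to((z % 18.0) < 7.0, geom.dims)
    ribs = body & (depth > 4.0) & (depth <= 10.0) & rib_bands & thorax_z
    bone = vertebra | ribs

    trachea_y = _snap(geom, 1, -8.0)
    trachea = np.broadcast_to(
        ((x - x0) ** 2 + (y - trachea_y) ** 2 <= r_eff(7.0) ** 2), geom.dims
    ) & np.broadcast_to(z >= 20.0, geom.dims)
    carina = (x0, trachea_y, 20.0)
    pb_tree = (
        _capsule_mask(x, y, z, carina, (45.0 * s, -2.0, -15.0), r_eff(6.0))
        | _capsule_mask(x, y, z, carina, (-45.0 * s, -2.0, -15.0), r_eff(6.0))
    )
    eso_y = _snap(geom, 1, 14.0 * s)
    esophagus = np.broadcast_to(
        (x - x0) ** 2 + (y - eso_y) ** 2 <= r_eff(4.5) ** 2, geom.dims
    ).copy()
    heart = (
        ((x - 16.0 * s) / (30.0 * s)) ** 2
        + ((y + 2.0) / (26.0 * s)) ** 2
        + ((z + 30.0) / 32.0) ** 2
    ) <= 1.0
    aorta_x = _snap(geom, 0, -4.0 * s)
    aorta_y = _snap(geom, 1, 10.0)
    aorta = _capsule_mask(x, y, z, (aorta_x, aorta_y, -60.0),
                          (aorta_x, aorta_y, 50.0), r_eff(10.0))

    masks = {
        "body": body, "skin": skin, "chestwall": chestwall,
        "lung_left": lungs["left"], "lung_right": lungs["right"],
        "cord": cord, "bone": bone & body, "trachea": trachea & body,
        "pb_tree": pb_tree & body, "esophagus": esophagus & body,
        "heart": heart & body, "aorta": aorta & body,
    }
    return masks, depth


def _place_tumor(
    rng: np.random.Generator,
    geom: GridGeometry,
    masks: dict,
    lobe: str,
    laterality: str,
    radius: float,
) -> tuple[float, float, float]:
    """Pick a tumor center voxel inside the named lung lobe, keeping the
    sphere inside the lung and clear of the mediastinum (so PTV-abutting-OAR
    degeneracies stay rare).  Chooses uniformly among all voxels with full
    clearance; falls back to the best-clearance voxel with a warning."""
    s_sign = +1.0 if laterality == "left" else -1.0
    lung = masks[f"lung_{laterality}"]
    mediastinum = (
        masks["heart"] | masks["aorta"] | masks["trachea"]
        | masks["pb_tree"] | masks["esophagus"]
    )
    # distance (mm) of every voxel to the mediastinum and to non-lung tissue
    sp = geom.spacing
    d_med = distance_transform_edt(~mediastinum, sampling=sp)
    d_lung_edge = distance_transform_edt(lung, sampling=sp)
    clearance = radius + PLANNING_MARGIN_MM + 3.0
    score = np.minimum(d_lung_edge - (radius + 2.0), d_med - clearance)

    z_lo, z_hi = _LOBE_Z_BANDS[lobe]
    x, _, z = geom.coordinate_grids()
    band = np.broadcast_to((z >= z_lo) & (z <= z_hi), geom.dims)
    side = np.broadcast_to(x * s_sign > 0, geom.dims)
    eligible = lung & band & side
    if not eligible.any():
        raise RuntimeError(f"no lung voxel found in {lobe}/{laterality} band")
    good = np.flatnonzero(eligible & (score >= 0.0))
    if good.size:
        flat = int(good[rng.integers(0, good.size)])
    else:
        score_masked = np.where(eligible, score, -np.inf)
        flat = int(np.argmax(score_masked))
        warnings.warn(
            f"tumor in {lobe}/{laterality} placed with reduced clearance "
            f"({score_masked.ravel()[flat]:.1f} mm)",
            stacklevel=2,
        )
    idx = np.unravel_index(flat, geom.dims)
    c = np.asarray(geom.origin) + np.asarray(idx) * np.asarray(geom.spacing)
    return tuple(float(v) for v in c)


def _oar_specs(n_fractions: int):
    name = protocol_for_fractions(n_fractions)
    return [
        sp for sp in load_protocol(name)
        if not sp.report_only and sp.structure_name != "PTV"
    ]


def _tuned_tx_dose(
    geom: GridGeometry,
    ptv: np.ndarray,
    structures: StructureSet,
    rx: Prescription,
    stress: float,
    rng: np.random.Generator,
) -> DoseGrid:
    """PTV-conformal dose with exponential falloff, scale tuned by bisection.

    The dose is the prescription inside the PTV, and outside it the larger
    of a PTV-conformal exponential falloff and a slowly-decaying low-dose
    bath (the entrance/exit dose a VMAT arc spreads over the axial plane,
    ~3% of Rx near the target).  The falloff length is chosen so the
    most-exposed enforceable OAR constraint reaches
    limit x (0.9 + 0.1 x stress); all constraint values are monotone in the
    falloff length, so bisection is exact.  A thin PTV rim is set just below
    90% of Rx (rim fraction grows with stress, with per-patient variation)
    so the coverage constraint sits near its own limit at high stress.
    """
    sp = geom.spacing
    dist_out = distance_transform_edt(~ptv, sampling=sp)
    noise = gaussian_filter(rng.standard_normal(geom.dims), sigma=2.0)
    noise /= max(noise.std(), 1e-12)
    mod = np.clip(1.0 + 0.03 * noise, 0.9, 1.1)
    bath = 0.03 * np.exp(-dist_out / 150.0)

    specs = _oar_specs(rx.n_fractions)
    target = 0.9 + 0.1 * stress

    def field(lam: float) -> np.ndarray:
        vals = rx.rx_total * np.maximum(np.exp(-dist_out / lam), bath) * mod
        vals[ptv] = rx.rx_total
        return vals

    def binding_ratio(lam: float) -> float:
        dose = DoseGrid(geom, field(lam))
        ratios = []
        for spec in specs:
            if spec.structure_name not in structures:
                continue
            v = evaluate_metric(spec, dose, structures, rx)
            ratios.append(v / spec.limit)
        return max(ratios)

    lo, hi = 3.0, 80.0
    g_lo, g_hi = binding_ratio(lo), binding_ratio(hi)
    if g_lo > target:
        warnings.warn(
            f"binding OAR ratio {g_lo:.3f} at minimum falloff exceeds target "
            f"{target:.3f}; using closest achievable", stacklevel=2,
        )
        lam = lo
    elif g_hi < target:
        warnings.warn(
            f"binding OAR ratio {g_hi:.3f} at maximum falloff below target "
            f"{target:.3f}; using closest achievable", stacklevel=2,
        )
        lam = hi
    else:
        for _ in range(40):
            lam = 0.5 * (lo + hi)
            g = binding_ratio(lam)
            if abs(g - target) < 1e-5:
                break
            if g < target:
                lo = lam
            else:
                hi = lam
        lam = 0.5 * (lo + hi)

    vals = field(lam)
    # PTV rim just under the 90%-of-Rx coverage threshold; the rim size
    # varies per patient so coverage scatters around the 99% limit
    rim_frac = float(rng.uniform(0.2, 1.0)) * (0.004 + 0.008 * stress)
    inner = distance_transform_edt(ptv, sampling=sp)
    ptv_idx = np.flatnonzero(ptv.ravel())
    n_rim = int(round(rim_frac * ptv_idx.size))
    if n_rim > 0:
        order = np.argsort(inner.ravel()[ptv_idx], kind="stable")
        rim = ptv_idx[order[:n_rim]]
        flat = vals.ravel()
        flat[rim] = 0.898 * rx.rx_total
        vals = flat.reshape(geom.dims)
    return DoseGrid(geom, vals)


def make_phantom(
    prescription: Prescription,
    lobe: str = "upper",
    laterality: str = "left",
    stress: float = 0.9,
    seed: int = 0,
    spacing_mm: float = 2.5,
    case_id: str | None = None,
) -> PatientCase:
    """Build one synthetic thorax case (deterministic for a fixed seed)."""
    if lobe not in _LOBE_Z_BANDS:
        raise ValueError(f"unknown lobe {lobe!r}")
    if laterality not in ("left", "right"):
        raise ValueError(f"unknown laterality {laterality!r}")
    rng = np.random.default_rng(seed)
    geom = _default_geometry(spacing_mm)
    scale = float(rng.uniform(0.92, 1.18))
    masks, _depth = _build_anatomy(geom, scale)

    tumor_r = float(rng.uniform(8.0, 14.0))
    center = _place_tumor(rng, geom, masks, lobe, laterality, tumor_r)
    x, y, z = geom.coordinate_grids()
    tumor = (
        (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        <= tumor_r ** 2
    )
    tumor = np.broadcast_to(tumor, geom.dims).copy()
    ptv = expand_margin(tumor, PLANNING_MARGIN_MM, geom.spacing)

    mediastinum = (
        masks["heart"] | masks["aorta"] | masks["trachea"]
        | masks["pb_tree"] | masks["esophagus"]
    )
    lung_l = masks["lung_left"] & ~mediastinum & ~tumor
    lung_r = masks["lung_right"] & ~mediastinum & ~tumor

    # density and material maps (air outside body and in the tracheal lumen)
    density = np.full(geom.dims, 0.0012)
    materials = np.full(geom.dims, MATERIAL_CODES["air"], dtype=np.uint8)
    body = masks["body"]
    density[body] = 1.0
    materials[body] = MATERIAL_CODES["soft"]
    lung_tissue = (masks["lung_left"] | masks["lung_right"]) & ~mediastinum & ~tumor
    density[lung_tissue] = 0.25
    materials[lung_tissue] = MATERIAL_CODES["lung"]
    density[masks["bone"]] = 1.6
    materials[masks["bone"]] = MATERIAL_CODES["bone"]
    density[masks["trachea"]] = 0.0012
    materials[masks["trachea"]] = MATERIAL_CODES["air"]
    dens_grid = DensityGrid(geom, density, materials)

    sset = StructureSet(frame=geom)
    margin = PLANNING_MARGIN_MM
    sset.add(Structure("PTV", role="PTV", mask=ptv))
    sset.add(Structure("ITV", role="support", mask=tumor))
    sset.add(Structure("Lt Lung", mask=lung_l))
    sset.add(Structure("Rt Lung", mask=lung_r))
    sset.add(Structure("Trachea", role="support", mask=masks["trachea"]))
    sset.add(Structure("Trachea PRV",
                       mask=expand_margin(masks["trachea"], margin, geom.spacing)))
    sset.add(Structure("Esophagus", role="support", mask=masks["esophagus"]))
    sset.add(Structure("Esophagus PRV",
                       mask=expand_margin(masks["esophagus"], margin, geom.spacing)))
    sset.add(Structure("PB Tree", mask=masks["pb_tree"]))
    sset.add(Structure("Heart", mask=masks["heart"]))
    sset.add(Structure("Aorta", mask=masks["aorta"]))
    sset.add(Structure("Spinal Cord", role="support", mask=masks["cord"]))
    sset.add(Structure("Spinal Cord PRV",
                       mask=expand_margin(masks["cord"], margin, geom.spacing)))
    sset.add(Structure("ChestWall", mask=masks["chestwall"]))
    sset.add(Structure("Skin", mask=masks["skin"]))
    sset.add(Structure("Bone", mask=masks["bone"]))

    tx = _tuned_tx_dose(geom, ptv, sset, prescription, stress, rng)
    arcs = [VmatArc(gantry_start=180.0, gantry_stop=180.0, direction="CW",
                    delivery_time_s=120.0)]
    cid = case_id or f"case-{seed}"
    return PatientCase(
        id=cid, density=dens_grid, structures=sset, tx_dose=tx,
        prescription=prescription, arcs=arcs,
        tumor_center_mm=center, lobe=lobe, laterality=laterality,
    )


def _site_sequence(rng: np.random.Generator, rx_key, count: int):
    sites = DEFAULT_SITES.get(rx_key)
    if sites is None:
        lobes = ["upper"] * count
        lats = ["left" if i % 2 == 0 else "right" for i in range(count)]
    else:
        lobes = [lb for lb, n in sites["lobes"].items() for _ in range(n)]
        lats = [lt for lt, n in sites["lateralities"].items() for _ in range(n)]
        lobes = (lobes * (count // max(len(lobes), 1) + 1))[:count]
        lats = (lats * (count // max(len(lats), 1) + 1))[:count]
    rng.shuffle(lobes)
    rng.shuffle(lats)
    return list(zip(lobes, lats))


def make_cohort(recipe: CohortRecipe) -> list[PatientCase]:
    """Generate the full cohort; per-patient seeds derive from the recipe seed."""
    root = np.random.SeedSequence(recipe.seed)
    site_rng = np.random.default_rng(root.spawn(1)[0])
    children = root.spawn(recipe.n_patients + 1)[1:]
    cases: list[PatientCase] = []
    i = 0
    for rx_total, n_fr, count in recipe.prescription_mix:
        sites = _site_sequence(site_rng, (rx_total, n_fr), count)
        for lobe, lat in sites:
            seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            cases.append(
                make_phantom(
                    Prescription(rx_total, n_fr), lobe=lobe, laterality=lat,
                    stress=recipe.stress, seed=seed,
                    spacing_mm=recipe.spacing_mm,
                    case_id=f"pt{i + 1:02d}-{n_fr}fr",
                )
            )
            i += 1
    return cases
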