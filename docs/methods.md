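# Methods

`kvdose` quantifies how the accumulated dose of stereoscopic/monoscopic
real-time kV tumor monitoring perturbs the DVH-based planning constraints of
lung SBRT. This note records the models, their assumptions, the numerical
choices, and what the synthetic cohort does and does not establish.

## Dose grids and resampling

All fields live on regular grids in a fixed patient frame (x patient-left,
y patient-posterior, z patient-superior; mm; voxel-center convention,
0-based indices). Treatment and imaging dose are usually computed on
different grids; the treatment-dose grid is the canonical accumulation
geometry and the imaging dose is resampled onto it by trilinear
interpolation, with points outside the source support set to 0 Gy (imaging
dose beyond the CT extent is negligible). Interpolated values are convex
combinations of source voxels, so resampling can never manufacture a
hotspot.

## Structures and margins

Regions come as per-slice closed polygons or voxel masks. Rasterization uses
voxel-center inclusion under the even-odd rule (holes are nested polygons
combined by XOR); partial-volume weighting is deliberately not used — it is
below reporting precision at the default grid and voxel-center inclusion is
the standard DVH-engine convention. Planning margins (PTV = tumor + 5 mm,
PRV = organ + 5 mm for trachea, esophagus and spinal cord) are isotropic 3D
Euclidean expansions computed with a sampled distance transform, so
anisotropic spacing is honored. Overlapping structures are evaluated
independently; there is no subtraction hierarchy, because each constraint is
defined per named structure.

## DVH metrics

All constraint metrics are computed from the sorted voxel doses inside the
mask; the binned cumulative DVH (default bin 0.01 Gy) exists only for export
and plotting, so bin width never limits metric accuracy.

* **Dmean** — arithmetic mean over masked voxels.
* **Dmax** — dose to the hottest 0.03 cc: voxels sorted hottest-first,
  cumulative volume accumulated, dose interpolated linearly inside the voxel
  where the running volume crosses 0.03 cc. This is robust to grid
  resolution; the 0.03 cc convention itself does not prescribe an
  interpolation rule, so the linear rule is a package choice.
* **D2%** — same mechanism at 2% of the structure volume.
* **V_D (cc and %)** — volume with dose ≥ D. "Receives a dose higher
  than D" is implemented as ≥ at the voxel level: the difference is
  measure-zero for continuous fields and ≥ keeps the uniform-dose edge case
  (V_D at exactly D) well behaved. A strict `>` mode is available in the
  configuration (`dvh.strict_threshold`).
* **PTV V90%** — percent of the PTV receiving ≥ 90% of the prescription.

Because an imaging dose is non-negative, every one of these metrics is
non-decreasing under dose accumulation. Two structural consequences follow
and are asserted as invariants: an upper-bounded OAR constraint (≤ or <) can
only flip pass→fail when imaging dose is added, and the lower-bounded PTV
coverage constraint (>) can only flip fail→pass.

## Constraint protocols

The three fractionation schemes map to three trial constraint sets
(4 fr → RTOG 0915, 8 fr → LUSTER, 15 fr → SUNSET), shipped as editable YAML
files with the clinical table values verbatim. Constraints are grouped as
C1 (absolute dose, Gy), C2 (absolute volume, cc), C3 (percent volume). Rows
marked N/A in a column are absent from that protocol file. Two bone metrics
(V30 Gy in cc, D2% in Gy) ride along as report-only rows — bone is not a
clinical OAR in these protocols, but kV photoelectric absorption makes bone
dose about 4× soft tissue, so it is worth watching; report-only rows carry
no limit and are excluded from all pass/fail denominators.

Pass/fail is decided on unrounded values (a 98.96 → 99.10 coverage flip is
invisible after rounding); report rendering rounds to 1 decimal (2 for PTV
coverage and for the delta columns). The increments are defined on
constraint values:
`Im/Tx (%) = 100·(value(Tx+Im) − value(Tx))/value(Tx)` with 0/0 := 0 and a
warning+`inf` sentinel when a zero Tx value becomes positive, and
`Im/Rx (%) = 100·(value(Tx+Im) − value(Tx))/Rx` for dose-valued (C1)
constraints only. A constraint whose structure is missing is recorded as
not-evaluated and excluded from cohort denominators rather than counted as a
pass.

## Imaging schedule

Two floor-mounted kV tubes image at a fixed frequency (default 1.67 Hz per
active tube) while the VMAT gantry rotates. A tube's view is blocked while
the gantry head crosses its line of sight, so each arc is partitioned by
gantry angle into stereoscopic pieces (both tubes) and monoscopic pieces
(one tube; none if both are blocked). Gantry motion is assumed uniform in
time over the arc — delivery logs are not modeled — so durations are
proportional to angular extent, and image counts are
`floor(duration × frequency)` per piece. Default blocked ranges are
A: 95–215°, B: 145–265° (a ±60° shadow around posterior-oblique lines of
sight); the exact machine geometry varies by installation, so both ranges
are configuration, stated as assumptions.

## kV dose surrogate

The per-image 3D dose is an analytic primary-beam model:

    D(v) = K_ref · mAs · (d_ref / r)² · exp(−μ_w · t_rad(v)) · f_mat

with `r` the source–voxel distance, `t_rad` the density-weighted
radiological path from the grid entry point to the voxel (midpoint-sampled
ray march, default 96 samples/ray), `μ_w` an effective water attenuation
coefficient for the beam quality, and `f_mat` = `bone_factor` (default 4.0)
for bone voxels, 1 otherwise. Voxels outside the divergent cone
(half-angle default 10°) receive nothing. Scatter, heel effect and detector
response are not modeled: the surrogate is primary-beam-only by design,
which keeps it checkable against the closed form
`exp(−μd)·inverse-square` (the test suite requires ≤1% deviation on the
central axis in water) while preserving the gross features the analysis
needs — posteriorly-weighted deposition for floor tubes under a supine
patient, a surface maximum, and bone enhancement.

The technique (kVp, mAs/image, μ_w) is patient-size-dependent: the lateral
water-equivalent thickness through the isocenter selects one of three rows
(small ≤115 mm: 100 kVp, 1.6 mAs, μ=0.0227 /mm; medium ≤135 mm: 110 kVp,
2.5 mAs, μ=0.0215 /mm; large: 120 kVp, 3.2 mAs, μ=0.0205 /mm). The output
calibration `K_ref` = 2.5·10⁻⁴ Gy/mAs at 1 m was chosen once so that a full
48 Gy/4 fr course with the default single 120 s arc yields a skin D2 of
order 0.5 Gy — an order-of-magnitude anchor to published surface-dose
measurements for this class of system, not a fit (the generated cohorts
produce ≈0.6 Gy).

Imaging dose is ray-marched on a 5 mm grid (the field is smooth at the
centimeter scale) and resampled onto the treatment grid before accumulation.
A course is the sum over fractions, arcs and schedule pieces of
(image count × per-image dose per active tube); identical fractions make the
course exactly linear in fraction count, mAs, and (up to floor rounding)
frequency.

## Synthetic cohort

Real planning data for this problem are institutional, so the pipeline is
exercised on generated thorax phantoms (default grid 2.5 mm isotropic,
220×180×200 mm, ≈5·10⁵ voxels/case): an elliptic-cylinder body (per-patient
size factor 0.92–1.18), two low-density lungs (ρ=0.25), posterior spinal
canal with vertebral column and rib bands (ρ=1.6), trachea with bronchial
bifurcation, esophagus, heart, aorta, a 4 mm skin shell and a 3–18 mm
chest-wall shell. Organ tube centers snap to voxel centers so thin
structures stay non-empty at coarse test resolutions. A spherical tumor
(radius 8–14 mm) is placed in the requested lobe and laterality, keeping
the sphere inside the lung and ≥ (radius+8) mm clear of the mediastinum so
that PTV-abutting-OAR degeneracies stay rare; if no voxel offers full
clearance the best available is used with a warning.

The treatment dose is a geometric surrogate, not an optimized plan: Rx
inside the PTV, and outside it the larger of a PTV-conformal exponential
falloff `Rx·exp(−d/λ)` and a slowly-decaying low-dose bath
`0.03·Rx·exp(−d/150 mm)` standing in for the entrance/exit dose a VMAT arc
spreads across the axial plane, the whole field modulated by ±3% smoothed
noise. The falloff length λ is tuned by bisection (monotone in λ, 40
iterations on λ∈[3, 80] mm) so that the most-exposed enforceable OAR
constraint reaches `limit × (0.9 + 0.1·stress)`:

* `stress = 0` — every OAR constraint passes with ≥10% headroom;
* `stress = 1` — the binding constraint sits at its limit, where a ~1%
  imaging increment flips it pass→fail, the mechanism behind near-limit
  plans in clinical cohorts.

A thin PTV rim (fraction `U(0.2,1)·(0.4% + 0.8%·stress)` of PTV voxels,
dosed at 89.8% of Rx) scatters the coverage constraint around its 99%
limit, so at high stress some patients marginally fail coverage under Tx
and can be rescued by the imaging dose — the only fail→pass direction the
evaluation admits. Cohort composition defaults to 26 patients at
48 Gy/4 fr, 3 at 60 Gy/8 fr, 1 at 60 Gy/15 fr, with the corresponding
upper/middle/lower-lobe and left/right frequencies; per-patient seeds
derive from the recipe seed, so a cohort is bit-reproducible.

What the phantoms do **not** emulate: breathing motion (the ITV is the
tumor itself), realistic VMAT modulation and beam arrangements, anatomical
variability beyond the size factor, CT noise/artifacts, and pretreatment
CBCT dose. Consequently the cohort demonstrates the *mechanics* —
constraint arithmetic, flip directions, posterior weighting, bone
enhancement, schedule bookkeeping — and the scale of Im/Tx and Im/Rx
increments, but per-structure values are not comparable to any specific
clinical cohort. In particular, contralateral and distant OARs here receive
less treatment dose than real plans deliver, which inflates the upper tail
of Im/Tx ratios relative to clinical experience, and the bone-vs-chest-wall
V30 comparison depends on how much rib bone the high-dose shell crosses.

## Numerical choices

* Bisection tolerance on the binding ratio: 10⁻⁵ (≈10⁻⁴ Gy on a 6 Gy
  limit). If the target is unreachable at λ∈[3, 80] mm the closest endpoint
  is used with a warning.
* Dmax interpolation requires v ≤ structure volume; v ≤ one voxel volume
  returns the hottest voxel dose.
* `Im/Tx` with a zero denominator and positive numerator reports `inf` and
  warns; cohort statistics over Im/Tx exclude non-finite values but count
  them in flip/failure tallies.
* Image counts use `floor(duration×frequency + 10⁻⁹)` to keep exact
  multiples stable against float representation (60 s × 1.67 Hz = 100).
* Ray-march entry points come from an exact slab intersection with the
  grid's outer box; homogeneous media therefore reproduce the closed form
  to sampling precision.

## Problem sizes

Unit tests run phantoms at 5–8 mm spacing (≲7·10⁴ voxels); the acceptance
suite and the reproduction script run the full 30-patient cohort at the
default 2.5 mm spacing with imaging ray-marched at 5 mm. A full cohort
generation + imaging + evaluation takes on the order of two minutes on one
CPU.
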