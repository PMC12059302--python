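from __future__ import annotations

import numpy as np
import pytest

from kvdose import DoseGrid, GridGeometry, KvTube, VmatArc
from kvdose.grids import DensityGrid, MATERIAL_CODES
from kvdose.imaging import (
    ImagingTechnique,
    accumulate_course,
    coarsen_density,
    compute_image_dose,
    default_tubes,
    image_counts,
    partition_arc,
    select_technique,
    water_equivalent_lateral_thickness,
)

WATER_TECH = ImagingTechnique(kvp=100, mas_per_image=2.0, mu_water=0.022)


def full_arc(time_s=120.0):
    return VmatArc(gantry_start=0.0, gantry_stop=0.0, direction="CW",
                   delivery_time_s=time_s)


class TestPartitionArc:
    def test_disjoint_blocks_split_80_20_20(self):
        # 360 deg in 120 s; A blocked over 60 deg, B over a disjoint 60 deg:
        # stereo 240/360 -> 80 s, each mono 60/360 -> 20 s
        sched = partition_arc(
            full_arc(), {"A": [(60.0, 120.0)], "B": [(180.0, 240.0)]}
        )
        stereo = sum(iv.duration_s for iv in sched.intervals if iv.mode == "stereo")
        mono_b = sum(iv.duration_s for iv in sched.intervals
                     if iv.mode == "mono" and iv.active_tubes == ("B",))
        mono_a = sum(iv.duration_s for iv in sched.intervals
                     if iv.mode == "mono" and iv.active_tubes == ("A",))
        assert stereo == pytest.approx(80.0)
        assert mono_a == pytest.approx(20.0)
        assert mono_b == pytest.approx(20.0)

    def test_no_blocking_single_stereo_interval(self):
        sched = partition_arc(full_arc(), {"A": [], "B": []})
        assert len(sched.intervals) == 1
        iv = sched.intervals[0]
        assert iv.mode == "stereo" and iv.duration_s == pytest.approx(120.0)

    def test_arc_inside_block_is_all_mono(self):
        arc = VmatArc(100.0, 140.0, "CW", 30.0)
        sched = partition_arc(arc, {"A": [(90.0, 150.0)], "B": []})
        assert all(iv.mode == "mono" and iv.active_tubes == ("B",)
                   for iv in sched.intervals)
        assert sched.total_time_s == pytest.approx(30.0)

    def test_both_blocked_piece_has_no_tubes(self):
        sched = partition_arc(full_arc(), {"A": [(0.0, 360.0)], "B": [(10.0, 20.0)]})
        dark = [iv for iv in sched.intervals if iv.active_tubes == ()]
        assert sum(iv.duration_s for iv in dark) == pytest.approx(120.0 / 36.0)

    def test_durations_partition_random_arcs(self, rng):
        for _ in range(50):
            start = float(rng.uniform(0, 360))
            span = float(rng.uniform(10, 360))
            direction = "CW" if rng.random() < 0.5 else "CCW"
            stop = (start + span) % 360 if direction == "CW" else (start - span) % 360
            t = float(rng.uniform(20, 300))
            arc = VmatArc(start, stop, direction, t)
            blocked = {
                "A": [tuple(sorted(rng.uniform(0, 360, 2)))],
                "B": [tuple(sorted(rng.uniform(0, 360, 2)))],
            }
            sched = partition_arc(arc, blocked)
            assert sched.total_time_s == pytest.approx(t, rel=1e-12)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            partition_arc(full_arc(), {"A": [(10.0, 50.0), (40.0, 80.0)], "B": []})

    def test_ccw_equivalent_to_cw_totals(self):
        blocked = {"A": [(60.0, 120.0)], "B": [(200.0, 260.0)]}
        cw = partition_arc(full_arc(), blocked)
        ccw = partition_arc(VmatArc(0.0, 0.0, "CCW", 120.0), blocked)
        assert cw.stereo_time_s() == pytest.approx(ccw.stereo_time_s())


class TestImageCounts:
    def test_one_minute_stereo_gives_100_per_tube(self):
        sched = partition_arc(VmatArc(0, 180, "CW", 60.0), {"A": [], "B": []},
                              frequency_hz=1.67)
        assert image_counts(sched) == {"A": 100, "B": 100}

    def test_counts_scale_with_duration(self):
        short = partition_arc(VmatArc(0, 180, "CW", 30.0), {"A": [], "B": []})
        long = partition_arc(VmatArc(0, 180, "CW", 60.0), {"A": [], "B": []})
        cs, cl = image_counts(short), image_counts(long)
        for tid in cs:
            assert abs(cl[tid] - 2 * cs[tid]) <= 1  # floor rounding slack


def water_box(nx=20, ny=80, nz=20, sp=2.0, density=1.0):
    geom = GridGeometry(
        origin=(-(nx - 1) / 2 * sp, -(ny - 1) / 2 * sp, -(nz - 1) / 2 * sp),
        spacing=(sp, sp, sp), dims=(nx, ny, nz),
    )
    dens = np.full(geom.dims, density)
    mats = np.full(geom.dims, MATERIAL_CODES["soft"], dtype=np.uint8)
    return DensityGrid(geom, dens, mats)


def posterior_tube(distance=600.0, halfangle=12.0):
    # source on +y, beam along -y through the box
    return KvTube("A", (0.0, distance, 0.0), (0.0, -1.0, 0.0),
                  field_halfangle_deg=halfangle)


class TestKvSurrogate:
    def test_central_axis_depth_dose_closed_form(self):
        density = water_box()
        tube = posterior_tube()
        dose = compute_image_dose(density, tube, WATER_TECH, n_samples=256)
        geom = density.geometry
        ix, iz = geom.dims[0] // 2, geom.dims[2] // 2
        ys = geom.axis_coords(1)
        surface_y = geom.bounding_box()[1][1]
        ssd = 600.0 - surface_y
        # compare dose ratios along the axis with exp(-mu d) x inverse-square
        j_ref = geom.dims[1] - 1  # shallowest central-axis voxel
        d_ref = surface_y - ys[j_ref]
        for j in (60, 40, 20, 0):
            d = surface_y - ys[j]
            expected = (
                np.exp(-WATER_TECH.mu_water * (d - d_ref))
                * ((ssd + d_ref) / (ssd + d)) ** 2
            )
            got = dose.values[ix, j, iz] / dose.values[ix, j_ref, iz]
            assert got == pytest.approx(expected, rel=0.01)

    def test_surface_maximum_along_beam(self):
        density = water_box()
        dose = compute_image_dose(density, posterior_tube(), WATER_TECH)
        geom = density.geometry
        col = dose.values[geom.dims[0] // 2, :, geom.dims[2] // 2]
        assert np.argmax(col) == geom.dims[1] - 1  # entry voxel (closest to source)
        assert np.all(np.diff(col) >= -1e-15)  # monotone toward the source

    def test_linear_in_mas(self):
        density = water_box(nx=10, ny=30, nz=10)
        tube = posterior_tube()
        d1 = compute_image_dose(density, tube, WATER_TECH)
        tech2 = ImagingTechnique(kvp=100, mas_per_image=4.0, mu_water=0.022)
        d2 = compute_image_dose(density, tube, tech2)
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_bone_factor_ratio(self):
        # two voxels mirrored about the central axis, same density, one
        # labeled bone: doses differ by exactly bone_factor
        density = water_box(nx=11, ny=30, nz=11)
        mats = density.materials.copy()
        j, k = 10, 5
        mats[3, j, k] = MATERIAL_CODES["bone"]
        density = DensityGrid(density.geometry, density.values, mats)
        dose = compute_image_dose(density, posterior_tube(), WATER_TECH)
        assert dose.values[3, j, k] / dose.values[7, j, k] == pytest.approx(4.0, rel=1e-9)

    def test_outside_cone_zero(self):
        density = water_box()
        dose = compute_image_dose(density, posterior_tube(halfangle=2.0), WATER_TECH)
        # corner voxel far off-axis receives nothing
        assert dose.values[0, 0, 0] == 0.0
        assert dose.values.max() > 0.0

    def test_axis_missing_grid_rejected(self):
        density = water_box(nx=6, ny=6, nz=6)
        tube = KvTube("A", (0.0, 600.0, 0.0), (0.0, 1.0, 0.0))  # aims away
        with pytest.raises(ValueError, match="does not intersect"):
            compute_image_dose(density, tube, WATER_TECH)


class TestAccumulation:
    def test_single_image_equals_per_image_dose(self):
        density = water_box(nx=10, ny=30, nz=10)
        tube = posterior_tube()
        per = compute_image_dose(density, tube, WATER_TECH)
        arc = VmatArc(0, 3, "CW", 1.0 / 1.67 + 1e-6)  # exactly one image
        course = accumulate_course(density, [arc], (tube,), WATER_TECH, 1,
                                   blocked_ranges={"A": []})
        np.testing.assert_allclose(course.values, per.values, rtol=1e-12)

    def test_fraction_linearity(self):
        density = water_box(nx=10, ny=30, nz=10)
        tubes = default_tubes((0.0, 0.0, 0.0), source_distance_mm=600.0)
        one = accumulate_course(density, [full_arc()], tubes, WATER_TECH, 1)
        four = accumulate_course(density, [full_arc()], tubes, WATER_TECH, 4)
        np.testing.assert_allclose(four.values, 4.0 * one.values, rtol=1e-12)

    def test_stereo_equals_sum_of_monos(self):
        density = water_box(nx=10, ny=30, nz=10)
        tubes = default_tubes((0.0, 0.0, 0.0), source_distance_mm=600.0)
        arc = full_arc()
        stereo = accumulate_course(density, [arc], tubes, WATER_TECH, 1,
                                   blocked_ranges={"A": [], "B": []})
        mono_a = accumulate_course(density, [arc], tubes[:1], WATER_TECH, 1,
                                   blocked_ranges={"A": []})
        mono_b = accumulate_course(density, [arc], tubes[1:], WATER_TECH, 1,
                                   blocked_ranges={"B": []})
        np.testing.assert_allclose(stereo.values, mono_a.values + mono_b.values,
                                   rtol=1e-12)

    def test_posterior_half_hotter_than_anterior(self, coarse_case, coarse_cfg):
        from kvdose.pipeline import course_imaging_dose

        im = course_imaging_dose(coarse_case, coarse_cfg)
        geom = im.geometry
        body = coarse_case.structures.mask("Skin") | ~np.isclose(
            coarse_case.density.values, 0.0012)
        y = geom.axis_coords(1)
        posterior = body & (np.zeros(geom.dims) + y[None, :, None] > 0)
        anterior = body & (np.zeros(geom.dims) + y[None, :, None] < 0)
        assert im.values[posterior].mean() > im.values[anterior].mean()


class TestTechniqueSelection:
    def test_water_equivalent_thickness_homogeneous(self):
        density = water_box(nx=50, ny=20, nz=20, sp=2.0)
        wet = water_equivalent_lateral_thickness(density, (0.0, 0.0, 0.0))
        assert wet == pytest.approx(50 * 2.0, rel=0.03)

    def test_size_classes_monotone_in_mas(self):
        small = water_box(nx=40, ny=20, nz=20, sp=2.0)   # 80 mm WET
        large = water_box(nx=40, ny=20, nz=20, sp=4.0)   # 160 mm WET
        t_small = select_technique(small, (0.0, 0.0, 0.0))
        t_large = select_technique(large, (0.0, 0.0, 0.0))
        assert t_small.mas_per_image < t_large.mas_per_image
        assert t_small.kvp < t_large.kvp

    def test_coarsen_preserves_mean_density(self, coarse_case):
        dens = coarse_case.density
        coarse = coarsen_density(dens, 10.0)
        assert coarse.values.mean() == pytest.approx(dens.values.mean(), rel=0.05)
        assert set(np.unique(coarse.materials)) <= {0, 1, 2, 3}
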