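from __future__ import annotations

import numpy as np
import pytest

from kvdose import (
    DoseGrid,
    GridGeometry,
    compute_dvh,
    dose_at_volume,
    dose_at_volume_pct,
    mean_dose,
    ptv_v_pct_of_rx,
    volume_above_cc,
    volume_above_pct,
)
from oracles import dose_at_volume_bruteforce, mean_bruteforce, volume_above_bruteforce

CM_GEOM = GridGeometry((0, 0, 0), (10.0, 10.0, 10.0), (30, 1, 1))  # 1 cc voxels


def grid_1cc(doses) -> DoseGrid:
    return DoseGrid(CM_GEOM, np.asarray(doses, dtype=float).reshape(30, 1, 1))


class TestCumulativeDVH:
    def test_uniform_structure(self):
        geom = GridGeometry((0, 0, 0), (10, 10, 10), (2, 1, 1))
        dose = DoseGrid(geom, np.full((2, 1, 1), 10.0))
        mask = np.ones((2, 1, 1), dtype=bool)
        dvh = compute_dvh(dose, mask, bin_width=0.5)
        assert dvh.total_volume_cc == pytest.approx(2.0)
        at_or_below = dvh.dose_edges <= 10.0
        assert np.allclose(dvh.volume_cc[at_or_below], 2.0)
        assert np.allclose(dvh.volume_cc[~at_or_below], 0.0)

    def test_two_voxel_structure(self):
        geom = GridGeometry((0, 0, 0), (10, 10, 10), (2, 1, 1))
        dose = DoseGrid(geom, np.array([5.0, 15.0]).reshape(2, 1, 1))
        mask = np.ones((2, 1, 1), dtype=bool)
        dvh = compute_dvh(dose, mask, bin_width=1.0)
        vol = dict(zip(dvh.dose_edges, dvh.volume_cc))
        assert vol[0.0] == pytest.approx(2.0)
        assert vol[5.0] == pytest.approx(2.0)
        assert vol[6.0] == pytest.approx(1.0)
        assert vol[15.0] == pytest.approx(1.0)
        assert vol[16.0] == pytest.approx(0.0)

    def test_matches_counting_oracle(self, rng):
        geom = GridGeometry((0, 0, 0), (10, 10, 10), (10, 10, 10))
        dose = DoseGrid(geom, rng.uniform(0, 30, size=(10, 10, 10)))
        mask = rng.random((10, 10, 10)) > 0.3
        dvh = compute_dvh(dose, mask, bin_width=0.25)
        doses = dose.values[mask]
        for edge, vol in zip(dvh.dose_edges[::7], dvh.volume_cc[::7]):
            assert vol == pytest.approx(volume_above_bruteforce(doses, 1.0, edge))

    def test_empty_mask_names_structure(self):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (2, 2, 2))
        dose = DoseGrid(geom, np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="Heart"):
            compute_dvh(dose, np.zeros((2, 2, 2), dtype=bool), structure="Heart")

    def test_export_roundtrips_numbers(self):
        dose = grid_1cc(np.linspace(0, 29, 30))
        dvh = compute_dvh(dose, np.ones((30, 1, 1), dtype=bool), bin_width=1.0)
        text = dvh.to_text()
        rows = [line.split("\t") for line in text.strip().splitlines()[1:]]
        np.testing.assert_allclose(
            [float(r[1]) for r in rows], dvh.volume_cc, atol=1e-6
        )


class TestDoseAtVolume:
    def test_uniform_any_volume(self):
        dose = grid_1cc([12.0] * 30)
        mask = np.ones((30, 1, 1), dtype=bool)
        for v in (0.03, 1.0, 15.0, 30.0):
            assert dose_at_volume(dose, mask, v) == pytest.approx(12.0)

    def test_dmax_interpolates_inside_crossing_voxel(self):
        # 3 mm voxels (0.027 cc): hottest 20 Gy, next 18 Gy; Dmax(0.03 cc)
        # falls strictly between, matching the sorted-accumulation oracle
        geom = GridGeometry((0, 0, 0), (3, 3, 3), (3, 3, 3))
        vals = np.full(27, 1.0)
        vals[0], vals[1] = 20.0, 18.0
        dose = DoseGrid(geom, vals.reshape(3, 3, 3))
        mask = np.ones((3, 3, 3), dtype=bool)
        got = dose_at_volume(dose, mask, 0.03)
        expected = dose_at_volume_bruteforce(dose.values[mask], 0.027, 0.03)
        assert 18.0 < got < 20.0
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(20.0 + (0.03 - 0.027) / 0.027 * (18.0 - 20.0))

    def test_full_volume_is_minimum_dose(self, rng):
        vals = rng.uniform(1, 9, 30)
        dose = grid_1cc(vals)
        mask = np.ones((30, 1, 1), dtype=bool)
        assert dose_at_volume(dose, mask, 30.0) == pytest.approx(vals.min())

    def test_bad_volumes_rejected(self):
        dose = grid_1cc([1.0] * 30)
        mask = np.ones((30, 1, 1), dtype=bool)
        with pytest.raises(ValueError):
            dose_at_volume(dose, mask, 0.0)
        with pytest.raises(ValueError, match="exceeds"):
            dose_at_volume(dose, mask, 31.0)

    def test_pct_form_and_bounds(self, rng):
        vals = rng.uniform(0, 20, 30)
        dose = grid_1cc(vals)
        mask = np.ones((30, 1, 1), dtype=bool)
        assert dose_at_volume_pct(dose, mask, 100.0) == pytest.approx(vals.min())
        assert dose_at_volume_pct(dose, mask, 50.0) == pytest.approx(
            dose_at_volume_bruteforce(vals, 1.0, 15.0)
        )
        with pytest.raises(ValueError):
            dose_at_volume_pct(dose, mask, 0.0)


class TestSimpleMetrics:
    def test_mean_examples(self, rng):
        mask = np.ones((30, 1, 1), dtype=bool)
        assert mean_dose(grid_1cc([6.0] * 30), mask) == pytest.approx(6.0)
        assert mean_dose(grid_1cc([0.0] * 15 + [12.0] * 15), mask) == pytest.approx(6.0)
        vals = rng.uniform(0, 50, 30)
        assert mean_dose(grid_1cc(vals), mask) == pytest.approx(mean_bruteforce(vals))

    def test_volume_above_uniform(self):
        geom = GridGeometry((0, 0, 0), (10, 10, 10), (4, 1, 1))
        dose = DoseGrid(geom, np.full((4, 1, 1), 10.0))
        mask = np.ones((4, 1, 1), dtype=bool)
        assert volume_above_cc(dose, mask, 5.0) == pytest.approx(4.0)
        assert volume_above_cc(dose, mask, 11.0) == pytest.approx(0.0)
        # threshold exactly at the dose: >= convention counts the volume
        assert volume_above_cc(dose, mask, 10.0) == pytest.approx(4.0)
        assert volume_above_cc(dose, mask, 10.0, strict=True) == pytest.approx(0.0)

    def test_graded_slab_enumeration(self):
        # 30 one-cc slabs with doses 0.5, 1.5, ..., 29.5 Gy; counting voxels
        # with dose >= 15 Gy gives the 15 slabs at 15.5..29.5 Gy
        dose = grid_1cc(np.arange(30) + 0.5)
        mask = np.ones((30, 1, 1), dtype=bool)
        expected = volume_above_bruteforce(dose.values[mask], 1.0, 15.0)
        assert expected == pytest.approx(15.0)
        assert volume_above_cc(dose, mask, 15.0) == pytest.approx(expected)

    def test_volume_above_pct(self, rng):
        vals = rng.uniform(0, 40, 30)
        dose = grid_1cc(vals)
        mask = np.ones((30, 1, 1), dtype=bool)
        assert volume_above_pct(dose, mask, 0.0) == pytest.approx(100.0)
        half = np.sort(vals)[15]
        expected = 100.0 * volume_above_bruteforce(vals, 1.0, half) / 30.0
        assert volume_above_pct(dose, mask, half) == pytest.approx(expected)


class TestPtvCoverage:
    def test_uniform_at_rx(self):
        dose = grid_1cc([48.0] * 30)
        mask = np.ones((30, 1, 1), dtype=bool)
        assert ptv_v_pct_of_rx(dose, mask, 48.0, 90.0) == pytest.approx(100.0)

    def test_fractional_coverage(self):
        # 991 of 1000 voxels at >= 90% of Rx -> V90% = 99.1
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (10, 10, 10))
        vals = np.full(1000, 48.0)
        vals[:9] = 40.0  # below 43.2
        dose = DoseGrid(geom, vals.reshape(10, 10, 10))
        mask = np.ones((10, 10, 10), dtype=bool)
        assert ptv_v_pct_of_rx(dose, mask, 48.0, 90.0) == pytest.approx(99.1)

    def test_all_below_threshold(self):
        dose = grid_1cc([10.0] * 30)
        mask = np.ones((30, 1, 1), dtype=bool)
        assert ptv_v_pct_of_rx(dose, mask, 48.0, 90.0) == pytest.approx(0.0)


class TestInvariants:
    def test_metrics_never_decrease_under_added_dose(self, rng):
        geom = GridGeometry((0, 0, 0), (5, 5, 5), (8, 8, 8))
        for _ in range(5):
            tx = DoseGrid(geom, rng.uniform(0, 40, size=geom.dims))
            im = DoseGrid(geom, rng.uniform(0, 0.5, size=geom.dims))
            total = DoseGrid(geom, tx.values + im.values)
            mask = rng.random(geom.dims) > 0.4
            assert mean_dose(total, mask) >= mean_dose(tx, mask)
            assert dose_at_volume(total, mask, 0.03) >= dose_at_volume(tx, mask, 0.03)
            assert dose_at_volume_pct(total, mask, 2.0) >= dose_at_volume_pct(tx, mask, 2.0)
            assert volume_above_cc(total, mask, 20.0) >= volume_above_cc(tx, mask, 20.0)
            assert volume_above_pct(total, mask, 20.0) >= volume_above_pct(tx, mask, 20.0)

    def test_dose_at_volume_inverse_consistency(self, rng):
        geom = GridGeometry((0, 0, 0), (5, 5, 5), (8, 8, 8))
        dose = DoseGrid(geom, rng.uniform(0, 30, size=geom.dims))
        mask = np.ones(geom.dims, dtype=bool)
        vv = geom.voxel_volume_cc
        for v in (1.0, 5.0, 20.0):
            d = dose_at_volume(dose, mask, v)
            assert volume_above_cc(dose, mask, d) == pytest.approx(v, abs=vv)
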