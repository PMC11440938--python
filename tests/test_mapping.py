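"""Distance maps, per-cell morphology and intensity measurements."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from orgamapper import (Detection, compute_edm, distance_to_membrane,
                        estimate_background, feret_diameter, intensity_profile,
                        measure_cell, measure_detection, radial_statistics)
from orgamapper.mapping import CellRecord

from conftest import disk_mask, make_field


def brute_force_edt(reference: np.ndarray) -> np.ndarray:
    """Nearest-reference-pixel search, the independent EDM oracle."""
    ref = np.column_stack(np.nonzero(reference))
    yy, xx = np.mgrid[0:reference.shape[0], 0:reference.shape[1]]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    d = np.sqrt(((pts[:, None, :] - ref[None, :, :]) ** 2).sum(-1)).min(axis=1)
    return d.reshape(reference.shape)


class TestComputeEDM:
    def test_pixel_adjacent_to_nucleus_is_one_pixel_away(self):
        shape = (30, 30)
        nucleus = disk_mask(shape, (15, 15), 5)
        cell = disk_mask(shape, (15, 15), 12)
        dmap = compute_edm(cell, nucleus, pixel_size=0.5)
        # 4-adjacent to the nucleus boundary: one pixel step = 0.5 um
        assert dmap.at(15 + 6, 15) == pytest.approx(0.5)

    def test_disk_nucleus_distance_is_radial_offset(self):
        shape = (80, 80)
        nucleus = disk_mask(shape, (40, 40), 20)
        cell = disk_mask(shape, (40, 40), 38)
        dmap = compute_edm(cell, nucleus)
        assert dmap.at(40 + 30, 40) == pytest.approx(10.0, abs=0.5)

    def test_nucleus_pixels_are_masked(self):
        shape = (30, 30)
        nucleus = disk_mask(shape, (15, 15), 5)
        cell = disk_mask(shape, (15, 15), 12)
        dmap = compute_edm(cell, nucleus)
        assert np.isnan(dmap.distance_um[15, 15])
        with pytest.raises(ValueError, match="outside"):
            dmap.at(15, 15)

    def test_missing_nucleus_is_an_error(self):
        cell = disk_mask((20, 20), (10, 10), 8)
        with pytest.raises(ValueError, match="no nucleus"):
            compute_edm(cell, np.zeros((20, 20), bool))

    def test_alternative_reference_object(self):
        # any reference mask (e.g. a Golgi blob) obeys the same contract
        shape = (40, 40)
        golgi = disk_mask(shape, (12, 20), 4)
        cell = disk_mask(shape, (20, 20), 18)
        dmap = compute_edm(cell, golgi)
        assert dmap.at(30, 20) == pytest.approx(
            np.hypot(30 - 12, 0) - 4, abs=0.6)

    @given(st.integers(0, 2 ** 31 - 1))
    @hyp_settings(max_examples=25, derandomize=True, deadline=None)
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(10, 50, 2)
        nucleus = np.zeros((h, w), bool)
        cy, cx = rng.integers(2, h - 2), rng.integers(2, w - 2)
        nucleus |= disk_mask((h, w), (cx, cy), int(rng.integers(1, 5)))
        cell = np.ones((h, w), bool)
        dmap = compute_edm(cell, nucleus)
        oracle = brute_force_edt(nucleus)
        valid = dmap.valid
        np.testing.assert_array_equal(dmap.distance_um[valid], oracle[valid])


class TestFeretAndCellRecord:
    def test_square_area_in_square_micrometres(self):
        shape = (120, 120)
        cell = np.zeros(shape, bool)
        cell[10:110, 10:110] = True  # 100 x 100 px
        nucleus = disk_mask(shape, (60, 60), 10)
        field = make_field(shape=shape, organelle=[(np.ones(shape, bool), 37)])
        record = measure_cell(cell, nucleus, field)
        assert record.area_um2 == pytest.approx(10000.0)
        assert record.mean_organelle_intensity == pytest.approx(37.0)

    def test_line_feret_uses_pixel_centers(self):
        mask = np.zeros((5, 105), bool)
        mask[2, 2:103] = True  # 1 x 101 px line
        assert feret_diameter(mask) == pytest.approx(100.0)

    def test_single_pixel_instance_is_degenerate(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(ValueError, match="degenerate|single-pixel"):
            feret_diameter(mask)

    @given(st.integers(0, 2 ** 31 - 1))
    @hyp_settings(max_examples=25, derandomize=True, deadline=None)
    def test_feret_matches_brute_force_max_pairwise_distance(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(8, 40, 2)
        mask = np.zeros((h, w), bool)
        for _ in range(rng.integers(1, 4)):
            cy, cx = rng.integers(1, h - 1), rng.integers(1, w - 1)
            mask |= disk_mask((h, w), (cx, cy), int(rng.integers(1, 6)))
        pts = np.column_stack(np.nonzero(mask)).astype(float)
        if len(pts) < 2:
            return
        brute = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)).max()
        assert feret_diameter(mask) == pytest.approx(brute, abs=1e-9)


class TestMeasureDetection:
    def _setup(self):
        shape = (80, 80)
        nucleus = disk_mask(shape, (40, 40), 10)
        cell = disk_mask(shape, (40, 40), 35)
        field = make_field(shape=shape, organelle=[(disk_mask(shape, (60, 40), 2), 180)],
                           measurement=[(np.ones(shape, bool), 55)])
        dmap = compute_edm(cell, nucleus, field.pixel_size)
        record = measure_cell(cell, nucleus, field)
        return field, dmap, record

    def test_fills_distances_intensities_and_angle(self):
        field, dmap, record = self._setup()
        det = measure_detection(Detection(x=60, y=40, cell_id=1), record, dmap, field)
        assert det.raw_distance_um == pytest.approx(10.0, abs=0.5)
        assert det.normalized_distance == pytest.approx(
            det.raw_distance_um / record.feret_um)
        assert det.organelle_peak == 180.0
        assert det.measurement_peak == 55.0
        assert det.angle_deg == pytest.approx(0.0, abs=1.0)

    def test_normalized_distance_is_raw_over_feret(self):
        field, dmap, _ = self._setup()
        record = CellRecord(cell_id=1, area_um2=1.0, feret_um=50.0,
                            nucleus_com=(40.0, 40.0),
                            mean_organelle_intensity=0.0)
        dmap.distance_um[40, 60] = 5.0  # pin the EDM value: 5 um / 50 um
        det = measure_detection(Detection(x=60, y=40, cell_id=1), record, dmap, field)
        assert det.normalized_distance == pytest.approx(0.1)

    def test_position_outside_cytoplasm_rejected(self):
        field, dmap, record = self._setup()
        with pytest.raises(ValueError, match="outside"):
            measure_detection(Detection(x=2, y=2, cell_id=1), record, dmap, field)


class TestIntensityProfile:
    def _profile(self, organelle_value=80.0, bin_width=2.0):
        shape = (60, 60)
        nucleus = disk_mask(shape, (30, 30), 8)
        cell = disk_mask(shape, (30, 30), 25)
        field = make_field(shape=shape,
                           organelle=[(np.ones(shape, bool), organelle_value)])
        dmap = compute_edm(cell, nucleus, field.pixel_size)
        return intensity_profile(cell, nucleus, dmap, field, bin_width=bin_width), \
            cell, nucleus, field

    def test_uniform_intensity_gives_flat_bins(self):
        profile, *_ = self._profile(organelle_value=80.0)
        np.testing.assert_allclose(profile.bin_mean_organelle, 80.0)

    def test_entry_count_equals_cytoplasm_pixel_count(self):
        profile, cell, nucleus, _ = self._profile()
        assert len(profile.distances_um) == (cell & ~nucleus).sum()

    def test_binned_totals_conserve_integrated_intensity(self):
        profile, *_ = self._profile()
        total = (profile.bin_mean_organelle * profile.bin_pixel_count).sum()
        assert total == pytest.approx(profile.organelle.sum(), rel=1e-9)

    def test_huge_bin_width_collapses_to_single_bin(self):
        profile, cell, nucleus, _ = self._profile(bin_width=1000.0)
        assert len(profile.bin_centers) == 1
        assert profile.bin_pixel_count[0] == (cell & ~nucleus).sum()


class TestBackground:
    def test_constant_image_with_empty_mask(self):
        field = make_field(shape=(30, 30), background=12)
        summary = estimate_background(field, np.zeros((30, 30), bool))
        assert summary.background_mean_organelle == pytest.approx(12.0)

    def test_full_mask_flags_background_absent(self):
        field = make_field(shape=(30, 30))
        summary = estimate_background(field, np.ones((30, 30), bool))
        assert summary.background_mean_organelle is None

    def test_simulated_field_background_recovered(self, baseline_cell, baseline_params):
        from orgamapper import SegmentationSettings, unfiltered_cell_mask
        field, _ = baseline_cell
        raw = unfiltered_cell_mask(field, SegmentationSettings())
        summary = estimate_background(field, raw)
        assert summary.background_mean_organelle == pytest.approx(
            baseline_params.background_level, abs=1.0)


class TestRadialStatistics:
    def test_collinear_detections_have_zero_circular_variance(self):
        dets = [Detection(x=10 + i, y=20, cell_id=1) for i in range(1, 5)]
        angles, cv = radial_statistics(dets, (5.0, 20.0))
        assert cv == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(angles, 0.0, atol=1e-9)

    def test_fourfold_symmetric_detections_have_unit_circular_variance(self):
        dets = [Detection(x=20, y=10, cell_id=1), Detection(x=30, y=20, cell_id=1),
                Detection(x=20, y=30, cell_id=1), Detection(x=10, y=20, cell_id=1)]
        angles, cv = radial_statistics(dets, (20.0, 20.0))
        assert cv == pytest.approx(1.0, abs=1e-12)
        assert ((0 <= angles) & (angles < 360)).all()

    def test_zero_detections_is_an_error(self):
        with pytest.raises(ValueError, match="0 detections"):
            radial_statistics([], (0.0, 0.0))


class TestDistanceToMembrane:
    def test_pixel_adjacent_to_boundary(self):
        cell = np.zeros((20, 20), bool)
        cell[5:15, 5:15] = True
        assert distance_to_membrane(5, 10, cell) == pytest.approx(1.0)

    def test_disk_center_is_one_radius_from_membrane(self):
        cell = disk_mask((60, 60), (30, 30), 20)
        assert distance_to_membrane(30, 30, cell) == pytest.approx(20.0, abs=1.0)

    def test_outside_position_rejected(self):
        cell = disk_mask((20, 20), (10, 10), 5)
        with pytest.raises(ValueError, match="outside"):
            distance_to_membrane(1, 1, cell)

    def test_membrane_plus_nucleus_distance_bounded_by_feret(self, baseline_cell):
        # convex cell: distance to nucleus + distance to membrane cannot
        # exceed the maximum caliper diameter
        from orgamapper import analyze_field, study_settings
        field, truth = baseline_cell
        result = analyze_field(field, study_settings())
        record = result.cell_records[0]
        cell_mask = result.cells.mask(record.cell_id)
        for det in result.detections:
            dtm = distance_to_membrane(det.x, det.y, cell_mask, field.pixel_size)
            assert dtm + det.raw_distance_um <= record.feret_um + 1e-9


class TestTranslationInvariance:
    def test_distances_area_and_dispersion_unchanged_by_shift(self):
        shape = (90, 90)
        nucleus = disk_mask(shape, (30, 30), 8)
        cell = disk_mask(shape, (30, 30), 25)
        field = make_field(shape=shape, organelle=[(np.ones(shape, bool), 64)])
        positions = [(45, 30), (30, 48), (14, 30)]

        def run(dx, dy):
            nuc = np.roll(nucleus, (dy, dx), axis=(0, 1))
            cel = np.roll(cell, (dy, dx), axis=(0, 1))
            dmap = compute_edm(cel, nuc)
            record = measure_cell(cel, nuc, field)
            dets = [measure_detection(Detection(x=x + dx, y=y + dy, cell_id=1),
                                      record, dmap, field)
                    for x, y in positions]
            _, cv = radial_statistics(dets, record.nucleus_com)
            return record.area_um2, record.feret_um, \
                [d.raw_distance_um for d in dets], cv

        base = run(0, 0)
        shifted = run(17, 11)
        assert shifted[0] == base[0]
        assert shifted[1] == base[1]
        np.testing.assert_allclose(shifted[2], base[2])
        assert shifted[3] == pytest.approx(base[3], abs=1e-12)
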