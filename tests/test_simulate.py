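"""Synthetic-cell generator and robustness-study behaviour."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from orgamapper import (SimulationParams, error_factor, generate_cell,
                        measure_positioning, run_robustness_study,
                        sweep_parameter)
from orgamapper.simulate import PlacementError, _apply_value


class TestGenerateCell:
    def test_default_canvas_is_8bit_three_channel_500x300(self, baseline_cell):
        field, truth = baseline_cell
        assert field.channels.shape == (3, 300, 500)
        assert field.channels.dtype == np.uint8
        assert len(truth.centers) == SimulationParams().organelle_count
        assert len(truth.true_distances) == len(truth.centers)
        assert (truth.true_distances >= 0).all()

    def test_zero_organelles_leaves_background_channel(self):
        params = dataclasses.replace(SimulationParams(), organelle_count=0)
        field, truth = generate_cell(params)
        assert len(truth.centers) == 0
        assert np.all(field.organelle == params.background_level)

    def test_ring_placement_distance_matches_placement_radius(self):
        # circular nucleus r=30, organelles on the exact ring at 40 px from
        # its edge: every ground-truth distance is 40 +- 1 px
        params = dataclasses.replace(SimulationParams(), nucleus_radius=30.0,
                                     organelle_placement_radius=40.0,
                                     placement_jitter=0.0)
        _, truth = generate_cell(params)
        assert np.all(np.abs(truth.true_distances - 40.0) <= 1.0)

    def test_deterministic_for_fixed_seed(self, baseline_params):
        f1, t1 = generate_cell(baseline_params)
        f2, t2 = generate_cell(baseline_params)
        np.testing.assert_array_equal(f1.channels, f2.channels)
        np.testing.assert_array_equal(t1.centers, t2.centers)
        f3, _ = generate_cell(dataclasses.replace(baseline_params, seed=1))
        assert not np.array_equal(f1.channels, f3.channels)

    def test_centers_inside_cell_and_outside_nucleus(self, baseline_cell):
        _, truth = baseline_cell
        xi = np.round(truth.centers[:, 0]).astype(int)
        yi = np.round(truth.centers[:, 1]).astype(int)
        assert truth.cell_mask[yi, xi].all()
        assert not truth.nucleus_mask[yi, xi].any()

    def test_infeasible_placement_is_rejected(self):
        params = dataclasses.replace(
            SimulationParams(), cell_half_axes=(60.0, 50.0),
            organelle_placement_radius=100.0)
        with pytest.raises(PlacementError):
            generate_cell(params)

    @pytest.mark.parametrize("overrides", [
        {"organelle_intensity": 300},
        {"nucleus_radius": -3.0},
        {"cell_half_axes": (20.0, 90.0)},  # nucleus (r=30) does not fit
        {"cell_shape": "star"},
    ])
    def test_invalid_parameters_rejected(self, overrides):
        with pytest.raises(ValueError):
            dataclasses.replace(SimulationParams(), **overrides)

    def test_background_gradient_ramps_along_x(self):
        params = dataclasses.replace(SimulationParams(), organelle_count=0,
                                     background_gradient=0.1)
        field, _ = generate_cell(params)
        col_means = field.organelle.astype(float).mean(axis=0)
        assert col_means[-1] > col_means[0]


class TestSweep:
    def test_unknown_parameter_rejected(self, baseline_params):
        with pytest.raises(ValueError, match="unknown simulation parameter"):
            sweep_parameter(baseline_params, "no_such_field", [1, 2])

    def test_sweep_must_include_baseline(self, baseline_params):
        with pytest.raises(ValueError, match="baseline"):
            sweep_parameter(baseline_params, "background_level", [30, 40])

    def test_identity_sweep_reproduces_generate_cell(self, baseline_params, baseline_cell):
        (field, truth), = sweep_parameter(
            baseline_params, "background_level", [baseline_params.background_level])
        np.testing.assert_array_equal(field.channels, baseline_cell[0].channels)
        np.testing.assert_array_equal(truth.centers, baseline_cell[1].centers)

    def test_organelle_radius_sweep_grows_blob_footprint(self, baseline_params):
        results = sweep_parameter(baseline_params, "organelle_radius",
                                  [2.0, 3.0, 5.0])
        footprints = [int((f.organelle > baseline_params.background_level).sum())
                      for f, _ in results]
        assert footprints[0] < footprints[1] < footprints[2]

    def test_cell_scale_sweep_changes_only_cell_size(self, baseline_params):
        results = sweep_parameter(baseline_params, "cell_scale", [1.0, 1.5])
        areas = [int(t.cell_mask.sum()) for _, t in results]
        assert areas[1] > areas[0]
        # nucleus untouched
        assert (results[0][1].nucleus_mask == results[1][1].nucleus_mask).all()


class TestErrorFactor:
    @pytest.mark.parametrize("result, baseline, expected", [
        (3.7, 3.7, 0.0),
        (7.4, 3.7, 1.0),
        (1.85, 3.7, 0.5),
    ])
    def test_fold_change_deviation(self, result, baseline, expected):
        assert error_factor(result, baseline) == pytest.approx(expected)

    def test_zero_baseline_is_undefined(self):
        with pytest.raises(ValueError, match="zero baseline"):
            error_factor(1.0, 0.0)

    @given(st.floats(0.01, 1e3), st.floats(0.01, 1e3))
    @hyp_settings(max_examples=50, derandomize=True)
    def test_nonnegative_and_zero_iff_equal(self, r, r0):
        ef = error_factor(r, r0)
        assert ef >= 0.0
        assert (ef == 0.0) == (r == r0)


class TestPipelineOnSimulatedCells:
    def test_ground_truth_recovery_on_noiseless_cell(self, baseline_cell):
        # full detection+mapping pipeline recovers the organelle count exactly
        # and the mean distance within 1 px of the ground truth
        from orgamapper import analyze_field, study_settings
        field, truth = baseline_cell
        result = analyze_field(field, study_settings())
        assert len(result.detections) == len(truth.centers)
        measured = np.mean([d.raw_distance_um for d in result.detections])
        assert measured == pytest.approx(truth.true_distances.mean(), abs=1.0)

    def test_joint_scaling_preserves_normalized_distance(self, baseline_params):
        k = 1.4
        m0 = measure_positioning(generate_cell(baseline_params)[0])
        mk = measure_positioning(
            generate_cell(_apply_value(baseline_params, "cell_scale", k))[0])
        assert mk["mean_distance_feret_normalized"] == pytest.approx(
            m0["mean_distance_feret_normalized"], rel=0.02)
        assert mk["mean_distance"] / m0["mean_distance"] == pytest.approx(k, rel=0.05)

    def test_background_offset_moves_ratio_not_distance(self, baseline_params):
        m0 = measure_positioning(generate_cell(baseline_params)[0])
        shifted = dataclasses.replace(
            baseline_params, background_level=baseline_params.background_level + 20)
        m1 = measure_positioning(generate_cell(shifted)[0])
        assert m1["mean_distance"] == pytest.approx(m0["mean_distance"], abs=0.2)
        assert m1["intensity_ratio"] != pytest.approx(m0["intensity_ratio"], rel=0.01)


class TestRobustnessStudy:
    def test_baseline_rows_have_zero_error_and_table_shape(self, baseline_params):
        table = run_robustness_study(
            baseline_params, {"background_level": [20, 30]})
        assert set(table.columns) == {"parameter", "value", "method",
                                      "measurement", "error_factor"}
        assert len(table) == 2 * 4  # two values x four methods
        baseline_rows = table[table["value"] == baseline_params.background_level]
        assert (baseline_rows["error_factor"] == 0.0).all()
        assert (table["error_factor"] >= 0.0).all()

    def test_propagates_failures_with_offending_value(self, baseline_params):
        bad = {"organelle_placement_radius": [40.0, 1000.0]}
        with pytest.raises(RuntimeError, match="1000.0"):
            run_robustness_study(baseline_params, bad)
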