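import numpy as np
import pytest

from oracles import brute_longest_run
from synapsepol.actin_kinetics import (
    ActinKinetics,
    RoiSeries,
    actin_ratio_series,
    depletion_interval,
    extract_floating_rois,
    reorganization_interval,
    residence_half_life,
    sensor_fi_ratio,
)
from synapsepol.errors import UnstableConjugateError, ZeroBaselineError
from synapsepol.scene import ImageScene
from synapsepol.scene_synth import ActinProfile, SceneSpec, generate_timelapse


def make_kinetics(ratio_is_cell, ratio_cis_is=None, frame_interval=5.0):
    r = np.asarray(ratio_is_cell, float)
    c = np.asarray(ratio_cis_is, float) if ratio_cis_is is not None else np.ones_like(r)
    return ActinKinetics(
        ratio_is_cell=r, ratio_cis_is=c,
        times_min=np.arange(len(r)) * frame_interval, frame_interval=frame_interval,
    )


def make_series(mean_cell, mean_is, mean_cis, frame_interval=5.0):
    n = len(mean_cell)
    dummy = [np.ones((2, 2), bool)] * n
    return RoiSeries(
        cell_masks=dummy, is_masks=dummy, cis_masks=dummy,
        mean_cell=np.asarray(mean_cell, float),
        mean_is=np.asarray(mean_is, float),
        mean_cis=np.asarray(mean_cis, float),
        times_min=np.arange(n) * frame_interval,
        propagated=np.zeros(n, bool),
    )


class TestFloatingRois:
    def test_static_scene_rois_constant(self, cytosol_seg_config):
        spec = SceneSpec(
            seed=3, n_t=5, shape_yx=(96, 96),
            actin_profile=ActinProfile(burst_start=5, burst_duration=10),
        )
        scene, _ = generate_timelapse(spec)
        series = extract_floating_rois(scene, config=cytosol_seg_config)
        for k in range(1, 5):
            np.testing.assert_array_equal(series.is_masks[k], series.is_masks[0])
            np.testing.assert_array_equal(series.cell_masks[k], series.cell_masks[0])

    def test_nesting_invariant(self, burst_timelapse, cytosol_seg_config):
        scene, _ = burst_timelapse
        series = extract_floating_rois(scene, config=cytosol_seg_config)
        for cell, is_m, cis in zip(series.cell_masks, series.is_masks, series.cis_masks):
            assert not (cis & ~is_m).any()
            assert not (is_m & ~cell).any()

    def test_drifting_cell_tracked(self, cytosol_seg_config):
        spec = SceneSpec(seed=3, n_t=8, shape_yx=(96, 96), drift_px=(0.5, 0.0))
        scene, truth = generate_timelapse(spec)
        series = extract_floating_rois(scene, config=cytosol_seg_config)
        true_c = np.asarray(truth.extras["contact_centroids"])
        for k in range(8):
            got = np.argwhere(series.is_masks[k]).mean(axis=0)
            ref = np.argwhere(series.is_masks[0]).mean(axis=0) + (true_c[k] - true_c[0])
            assert np.linalg.norm(got - ref) < 1.0

    def test_failed_frame_propagated_and_flagged(self, cytosol_seg_config):
        spec = SceneSpec(seed=3, n_t=20, shape_yx=(96, 96))
        scene, _ = generate_timelapse(spec)
        scene.data[7] = 0.0  # kill one frame
        series = extract_floating_rois(scene, config=cytosol_seg_config)
        assert series.propagated[7]
        assert series.propagated.sum() == 1
        np.testing.assert_array_equal(series.cell_masks[7], series.cell_masks[6])

    def test_unstable_conjugate_raises(self, cytosol_seg_config):
        spec = SceneSpec(seed=3, n_t=10, shape_yx=(96, 96))
        scene, _ = generate_timelapse(spec)
        scene.data[5:] = 0.0  # half the frames lost
        with pytest.raises(UnstableConjugateError):
            extract_floating_rois(scene, config=cytosol_seg_config)


class TestRatioSeries:
    def test_uniform_image_unit_ratios(self):
        series = make_series([10, 10, 10], [10, 10, 10], [10, 10, 10])
        kin = actin_ratio_series(series)
        np.testing.assert_allclose(kin.ratio_is_cell, 1.0)
        np.testing.assert_allclose(kin.ratio_cis_is, 1.0)

    def test_doubled_band(self):
        series = make_series([10, 10, 10], [20, 20, 20], [20, 20, 20])
        kin = actin_ratio_series(series)
        np.testing.assert_allclose(kin.ratio_is_cell, 2.0)

    def test_zero_denominator_excluded(self):
        series = make_series([10, 0, 10], [10, 10, 10], [10, 10, 10])
        kin = actin_ratio_series(series)
        assert np.isnan(kin.ratio_is_cell[1])
        assert np.isfinite(kin.ratio_is_cell[[0, 2]]).all()

    def test_noise_free_burst_matches_profile(self, burst_timelapse, cytosol_seg_config):
        scene, truth = burst_timelapse
        series = extract_floating_rois(scene, config=cytosol_seg_config)
        kin = actin_ratio_series(series)
        np.testing.assert_allclose(kin.ratio_is_cell, truth.true_ratio_is_cell, rtol=0.01)
        np.testing.assert_allclose(kin.ratio_cis_is, truth.true_ratio_cis_is, rtol=0.01)


class TestReorganizationInterval:
    def test_worked_example(self):
        kin = make_kinetics([0.9, 1.2, 1.5, 1.3, 0.95])
        dur, peak_t, max_r = reorganization_interval(kin, delta=0.05)
        assert dur == pytest.approx(15.0)
        assert max_r == pytest.approx(1.5)
        assert peak_t == pytest.approx(10.0)
        start, length = brute_longest_run(np.array([0.9, 1.2, 1.5, 1.3, 0.95]) > 1.05)
        assert dur == length * 5.0

    def test_constant_one_zero_duration(self):
        dur, _, _ = reorganization_interval(make_kinetics([1.0] * 5))
        assert dur == 0.0

    def test_all_below_returns_series_max(self):
        dur, _, max_r = reorganization_interval(make_kinetics([0.7, 0.9, 0.8]))
        assert dur == 0.0
        assert max_r == pytest.approx(0.9)

    def test_longest_run_selected(self):
        vals = [1.2, 0.9, 1.2, 1.3, 1.2, 0.9]
        kin = make_kinetics(vals)
        dur, _, _ = reorganization_interval(kin, delta=0.05)
        start, length = brute_longest_run(np.asarray(vals) > 1.05)
        assert dur == length * 5.0 == 15.0

    def test_recovers_generator_duration(self, cytosol_seg_config):
        spec = SceneSpec(
            seed=5, n_t=12, frame_interval=5.0, shape_yx=(96, 96),
            actin_profile=ActinProfile(burst_start=10, burst_duration=30, burst_amplitude=2.0),
        )
        scene, _ = generate_timelapse(spec)
        kin = actin_ratio_series(extract_floating_rois(scene, config=cytosol_seg_config))
        assert abs(kin.reorganization_duration - 30.0) <= 5.0

    def test_scale_invariance(self, burst_timelapse, cytosol_seg_config):
        scene, _ = burst_timelapse
        kin1 = actin_ratio_series(extract_floating_rois(scene, config=cytosol_seg_config))
        scaled = ImageScene(
            data=scene.data * 3.7, channel_roles=scene.channel_roles,
            pixel_size=scene.pixel_size, z_step=scene.z_step,
            frame_interval=scene.frame_interval,
        )
        kin2 = actin_ratio_series(extract_floating_rois(scaled, config=cytosol_seg_config))
        assert kin1.reorganization_duration == kin2.reorganization_duration
        assert kin1.depletion_duration == kin2.depletion_duration


class TestDepletionInterval:
    def test_constant_one_absent(self):
        present, dur = depletion_interval(make_kinetics([1.0] * 4, [1.0] * 4))
        assert not present and dur == 0.0

    def test_worked_example(self):
        kin = make_kinetics([1] * 5, [1.0, 0.7, 0.6, 0.9, 1.05])
        present, dur = depletion_interval(kin, delta=0.05)
        assert present and dur == pytest.approx(15.0)

    def test_recovers_generator_clearance(self, cytosol_seg_config):
        spec = SceneSpec(
            seed=6, n_t=12, frame_interval=5.0, shape_yx=(96, 96),
            actin_profile=ActinProfile(
                burst_start=10, burst_duration=30, burst_amplitude=2.0,
                clearance_ratio=0.5, clearance_start=10, clearance_duration=20,
            ),
        )
        scene, _ = generate_timelapse(spec)
        kin = actin_ratio_series(extract_floating_rois(scene, config=cytosol_seg_config))
        assert abs(kin.depletion_duration - 20.0) <= 5.0


class TestSensorFiRatio:
    def test_constant_series(self):
        times = np.arange(0, 50, 5.0)
        out = sensor_fi_ratio(np.full(10, 7.0), times, baseline_time=30.0)
        np.testing.assert_allclose(out, 1.0)

    def test_doubling_after_baseline(self):
        times = np.arange(0, 50, 5.0)
        fi = np.full(10, 5.0)
        fi[8:] = 10.0
        out = sensor_fi_ratio(fi, times, baseline_time=30.0)
        np.testing.assert_allclose(out[8:], 2.0)

    def test_baseline_frame_index_on_5min_grid(self):
        # t = 30 min on a 5-minute grid is frame index 6
        times = np.arange(0, 60, 5.0)
        fi = np.arange(1.0, 13.0)
        out = sensor_fi_ratio(fi, times, baseline_time=30.0)
        np.testing.assert_allclose(out, fi / fi[6])

    def test_zero_baseline(self):
        times = np.arange(0, 50, 5.0)
        fi = np.zeros(10)
        with pytest.raises(ZeroBaselineError):
            sensor_fi_ratio(fi, times, baseline_time=30.0)


class TestResidenceHalfLife:
    def test_closed_form_exponential(self):
        times = np.arange(0, 120, 0.5)
        fi = 100.0 * np.exp(-np.log(2) / 20.0 * times)
        hl, censored = residence_half_life(fi, times)
        assert not censored
        assert hl == pytest.approx(20.0, abs=1.0)

    def test_flat_after_peak_censored(self):
        fi = np.array([50.0, 100.0, 100.0, 100.0])
        _, censored = residence_half_life(fi, np.arange(4) * 5.0)
        assert censored

    def test_monotone_rising_censored(self):
        fi = np.array([1.0, 2.0, 3.0, 4.0])
        _, censored = residence_half_life(fi, np.arange(4) * 5.0)
        assert censored

    def test_step_to_half_is_one_interval(self):
        # peak 100, immediate drop to the 50% level, then decay to 0
        fi = np.array([100.0, 50.0, 12.0, 1.0, 0.0])
        hl, censored = residence_half_life(fi, np.arange(5) * 5.0)
        assert not censored
        assert hl == pytest.approx(5.0)
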