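"""Compartment curves, Imax normalisation and physiological readouts."""

import math

import numpy as np
import pytest

from vasculens.exceptions import AnalysisError, ConfigError
from vasculens.kinetics import (
    CompartmentCurve,
    compartment_means,
    filling_time,
    leakage_onset,
    lock_duration,
    normalize_to_imax,
    relative_variation,
)
from vasculens.simulate import TracerKinetics, plasma_concentration
from vasculens.stack_io import ImageStack


def curve(times, values, name="intravascular"):
    return CompartmentCurve(name, np.asarray(times, float), np.asarray(values, float))


class TestCompartmentMeans:
    def test_constant_stack(self):
        frames = np.full((3, 6, 6), 42, np.uint16)
        stack = ImageStack(frames, 10.0 * np.arange(3), 1.0)
        c = compartment_means(stack, np.ones((6, 6), bool))
        np.testing.assert_array_equal(c.mean_intensity, [42, 42, 42])

    def test_single_pixel_mask_traces_pixel(self, rng):
        frames = rng.integers(0, 1000, (5, 4, 4)).astype(np.uint16)
        stack = ImageStack(frames, 10.0 * np.arange(5), 1.0)
        mask = np.zeros((4, 4), bool)
        mask[2, 3] = True
        c = compartment_means(stack, mask)
        np.testing.assert_array_equal(c.mean_intensity, frames[:, 2, 3])

    def test_empty_mask_rejected(self):
        frames = np.zeros((2, 4, 4), np.uint16)
        stack = ImageStack(frames, 10.0 * np.arange(2), 1.0)
        with pytest.raises(AnalysisError):
            compartment_means(stack, np.zeros((4, 4), bool))

    def test_simulated_intravascular_curve_tracks_plasma(self, control):
        stack, truth, res = control
        c = res["iv_curve"]
        model = plasma_concentration(c.times, TracerKinetics())
        r = np.corrcoef(c.mean_intensity, model)[0, 1]
        assert r > 0.99


class TestNormalization:
    def test_simple_arithmetic(self):
        n = normalize_to_imax(curve([0, 1, 2], [1, 2, 4]))
        np.testing.assert_allclose(n.normalized, [25, 50, 100])
        assert n.imax == 4

    def test_monotone_curve_peaks_at_end(self):
        n = normalize_to_imax(curve([0, 1, 2, 3], [1, 5, 7, 9]))
        assert n.normalized[-1] == 100.0

    def test_idempotent(self):
        n1 = normalize_to_imax(curve([0, 1], [3, 6]))
        n2 = normalize_to_imax(CompartmentCurve("x", n1.times, n1.normalized))
        np.testing.assert_allclose(n2.normalized, n1.normalized)

    def test_all_zero_rejected(self):
        with pytest.raises(AnalysisError):
            normalize_to_imax(curve([0, 1], [0, 0]))

    def test_simulated_filling_reaches_eighty_percent_at_two_minutes(self, control):
        _, _, res = control
        c = res["iv_curve"]
        i = int(np.argmin(np.abs(c.times - 120.0)))
        assert c.normalized[i] == pytest.approx(80.0, abs=3.0)


class TestRelativeVariation:
    def test_constant_curve_all_zero(self):
        rv = relative_variation(curve([0, 10, 20, 30], [10, 10, 10, 10]), (0, 25))
        np.testing.assert_allclose(rv, 0.0)

    def test_fifty_percent_rise(self):
        rv = relative_variation(curve([0, 10, 20], [10, 10, 15]), (0, 15))
        assert rv[-1] == pytest.approx(0.5)

    def test_zero_baseline_rejected(self):
        with pytest.raises(AnalysisError):
            relative_variation(curve([0, 10], [0, 5]), (0, 5))


class TestFillingTime:
    def test_step_curve(self):
        c = normalize_to_imax(curve([0, 20, 40, 60, 80], [0.01, 0.01, 0.01, 100, 100]))
        assert filling_time(c, 80.0) == 60.0

    def test_fraction_100_is_time_of_maximum(self):
        c = normalize_to_imax(curve([0, 20, 40, 60], [1, 5, 9, 9]))
        assert filling_time(c, 100.0) == 40.0

    def test_never_reached_is_missing(self):
        c = CompartmentCurve("x", np.array([0.0, 10.0]), np.array([1.0, 2.0]),
                             imax=10.0, normalized=np.array([10.0, 20.0]))
        assert math.isnan(filling_time(c, 80.0))

    def test_invalid_fraction_rejected(self):
        c = normalize_to_imax(curve([0, 1], [1, 2]))
        with pytest.raises(ConfigError):
            filling_time(c, 0.0)

    def test_simulated_default_filling_recovered(self, control):
        _, _, res = control
        assert res["readouts"]["filling_time_s"] == pytest.approx(120.0, abs=20.0)


class TestLockDuration:
    def test_no_drop_gives_zero(self):
        t = np.arange(0, 200, 20.0)
        fvd = np.full(t.size, 0.03)
        dur, censored = lock_duration((t, fvd), 0.03, treatment_time=100.0)
        assert dur == 0.0 and not censored

    def test_permanent_lock_is_censored(self):
        t = np.arange(0, 220, 20.0)
        fvd = np.where(t < 100, 0.03, 0.0)
        dur, censored = lock_duration((t, fvd), 0.03, treatment_time=100.0)
        assert censored
        assert dur == pytest.approx(t[-1] - 100.0)

    def test_interpolated_endpoint(self):
        t = np.array([0.0, 100.0, 200.0, 300.0])
        fvd = np.array([0.02, 0.0, 0.0, 0.02])
        dur, censored = lock_duration((t, fvd), 0.02, 100.0, fraction=0.5)
        # crossing at half of the rise between 200 and 300
        assert dur == pytest.approx(150.0)
        assert not censored

    def test_treatment_outside_series_rejected(self):
        t = np.arange(0, 100, 20.0)
        with pytest.raises(AnalysisError):
            lock_duration((t, np.ones(t.size)), 1.0, treatment_time=500.0)

    def test_ep_scene_recovers_truth_onset(self, ep_lock):
        _, truth, res = ep_lock
        # ground-truth complete lock: treatment at 130 s, first re-perfusion 730 s
        assert res["readouts"]["lock_duration_s"] == pytest.approx(600.0, abs=120.0)
        assert not res["readouts"]["lock_censored"]

    def test_ect_scene_is_censored_for_whole_window(self, ect):
        _, _, res = ect
        assert res["readouts"]["lock_censored"]
        assert res["readouts"]["lock_duration_s"] == pytest.approx(3860.0 - 130.0)


class TestLeakageOnset:
    def test_flat_noisy_series_missing(self, rng):
        t = np.arange(0, 600, 20.0)
        rv = rng.normal(0, 0.001, t.size)
        assert math.isnan(leakage_onset(t, rv, (0, 130), 130.0))

    def test_single_frame_spike_filtered(self):
        t = np.arange(0, 400, 20.0)
        rv = np.zeros(t.size)
        rv[12] = 1.0
        assert math.isnan(leakage_onset(t, rv, (0, 130), 130.0, persistence=2))

    def test_persistent_rise_detected_at_first_frame_of_run(self):
        t = np.arange(0, 400, 20.0)
        rv = np.where(t >= 260, 0.5, 0.0)
        assert leakage_onset(t, rv, (0, 130), 130.0) == pytest.approx(130.0)

    def test_baseline_must_precede_treatment(self):
        t = np.arange(0, 400, 20.0)
        with pytest.raises(ConfigError):
            leakage_onset(t, np.zeros(t.size), (0, 200), 130.0)

    def test_ep_leak_scene_recovers_truth_delay(self, ep_leak):
        _, truth, res = ep_leak
        # ground-truth onset 120 s after treatment; one fast-series interval slack
        assert res["readouts"]["leakage_onset_s"] == pytest.approx(120.0, abs=120.0)

    def test_ect_scene_reports_no_leakage(self, ect):
        _, _, res = ect
        assert math.isnan(res["readouts"]["leakage_onset_s"])
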