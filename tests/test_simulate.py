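"""Generator: network geometry, tracer kinetics, rendering, scheduling."""

import math

import numpy as np
import pytest

from vasculens.exceptions import ConfigError
from vasculens.simulate import (
    AcquisitionSchedule,
    NoiseModel,
    PerfusionScenario,
    TracerKinetics,
    VesselNetworkSpec,
    build_network,
    extravascular_concentration,
    plasma_concentration,
    render_frame,
    simulate_stack,
)

TAU_80PCT_AT_2MIN = 120.0 / math.log(5.0)


def straight_segment_spec(length_um=500, diameter_um=20.0, height=60):
    """One straight horizontal vessel whose ROI-clipped length is exact."""
    return VesselNetworkSpec(
        field_height_px=height,
        field_width_px=length_um + 1,
        n_segments=1,
        tortuosity=0.0,
        diameters_um=(diameter_um,),
        calibrate_lw_diameter_um=None,
        tumor_roi=((0, 0), (0, length_um + 1), (height, length_um + 1), (height, 0)),
        seed=0,
    )


class TestBuildNetwork:
    def test_straight_rectangle_geometry(self):
        _, truth = build_network(straight_segment_spec())
        assert truth.lv_um == pytest.approx(500.0)
        assert truth.av_um2 == pytest.approx(10_000.0)
        assert truth.dv_um == pytest.approx(20.0)
        # exact bookkeeping identities
        assert truth.fvd_per_um == truth.lv_um / truth.at_um2
        assert truth.dv_um == truth.av_um2 / truth.lv_um

    def test_same_seed_identical_network(self):
        spec = VesselNetworkSpec(seed=42)
        segs_a, truth_a = build_network(spec)
        segs_b, truth_b = build_network(spec)
        assert truth_a.diameters_um == truth_b.diameters_um
        for a, b in zip(segs_a, segs_b):
            np.testing.assert_array_equal(a.centerline, b.centerline)

    def test_diameter_distribution(self):
        spec = VesselNetworkSpec(
            field_height_px=2000,
            n_segments=60,
            diameter_mean=20.0,
            diameter_sd=4.0,
            calibrate_lw_diameter_um=None,
            seed=7,
        )
        _, truth = build_network(spec)
        se = 4.0 / math.sqrt(60)
        assert abs(np.mean(truth.diameters_um) - 20.0) < 2 * se

    def test_calibration_pins_length_weighted_diameter(self):
        _, truth = build_network(VesselNetworkSpec(seed=3))
        assert truth.dv_um == pytest.approx(20.0)

    @pytest.mark.parametrize("bad", [dict(n_segments=0), dict(field_height_px=-1), dict(diameter_mean=-2.0)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ConfigError):
            build_network(VesselNetworkSpec(**bad))

    def test_roi_outside_field_rejected(self):
        spec = VesselNetworkSpec(tumor_roi=((0, 0), (0, 900), (900, 900), (900, 0)))
        with pytest.raises(ConfigError):
            build_network(spec)


class TestPlasmaCurve:
    def test_zero_at_injection(self):
        assert plasma_concentration(0.0, TracerKinetics()) == 0.0

    def test_plateau(self):
        k = TracerKinetics()
        assert plasma_concentration(1e6, k) == pytest.approx(k.plateau)

    def test_eighty_percent_at_two_minutes(self):
        k = TracerKinetics(tau=TAU_80PCT_AT_2MIN)
        assert plasma_concentration(120.0, k) == pytest.approx(0.8 * k.plateau)

    def test_monotone_nondecreasing(self):
        t = np.linspace(-10, 600, 200)
        c = plasma_concentration(t, TracerKinetics())
        assert np.all(np.diff(c) >= 0)


class TestExtravascularCurve:
    def test_no_leak_without_permeability(self):
        t = np.arange(0, 100, 10.0)
        assert np.all(extravascular_concentration(t, TracerKinetics(k_perm=0.0)) == 0)

    def test_lock_blocks_supply(self):
        t = np.arange(0, 100, 10.0)
        c = extravascular_concentration(
            t, TracerKinetics(k_perm=1e-3), perfusion_gate=np.zeros(t.size, bool)
        )
        assert np.all(c == 0)

    def test_closed_form_for_constant_plasma(self):
        # tau -> 0 makes the plasma level a step to the plateau at t0
        k = TracerKinetics(tau=1e-9, plateau=1000.0, k_perm=2e-3, leakage_onset_delay=20.0)
        t = np.arange(0.0, 101.0, 10.0)
        c = extravascular_concentration(t, k)
        expected = k.k_perm * k.plateau * np.clip(t - 20.0, 0.0, None)
        np.testing.assert_allclose(c, expected)

    def test_monotone_and_rejects_bad_times(self):
        t = np.arange(0, 200, 20.0)
        c = extravascular_concentration(t, TracerKinetics(k_perm=1e-3))
        assert np.all(np.diff(c) >= 0)
        with pytest.raises(ConfigError):
            extravascular_concentration([0.0, 0.0, 10.0], TracerKinetics())


class TestSchedule:
    def test_default_reproduces_protocol(self):
        ts = AcquisitionSchedule.default().timestamps()
        fast1 = np.arange(0, 121, 20.0)
        fast2 = np.arange(140, 261, 20.0)
        slow = np.arange(380, 3861, 120.0)
        np.testing.assert_array_equal(ts, np.concatenate([fast1, fast2, slow]))

    def test_nonmonotone_rejected(self):
        with pytest.raises(ConfigError):
            AcquisitionSchedule(series=((0, 20, 120), (100, 20, 120))).timestamps()


class TestRendering:
    def test_unperfused_noise_free_is_background(self):
        segs, _ = build_network(straight_segment_spec())
        frame = render_frame(
            segs, [False], 5000.0, [0.0], NoiseModel(read_noise_sd=0, photon_scale=0),
            0, pixel_size=1.0, shape=(60, 501),
        )
        assert np.all(frame == 100)

    def test_rendered_width_matches_diameter(self):
        segs, _ = build_network(straight_segment_spec(diameter_um=20.0))
        frame = render_frame(
            segs, [True], 5000.0, [0.0], NoiseModel(read_noise_sd=0, photon_scale=0),
            0, pixel_size=1.0, shape=(60, 501),
        )
        widths = (frame[:, 250] > 100).sum()
        assert abs(widths - 20) <= 1

    def test_cumulative_drift_translates_frame(self):
        segs, _ = build_network(straight_segment_spec())
        noise = NoiseModel(read_noise_sd=0, photon_scale=0, drift_per_frame=(1.0, 0.0))
        f0 = render_frame(segs, [True], 5000.0, [0.0], noise, 0, pixel_size=1.0, shape=(60, 501))
        f5 = render_frame(segs, [True], 5000.0, [0.0], noise, 5, pixel_size=1.0, shape=(60, 501))
        np.testing.assert_array_equal(f5[5:, :], f0[:-5, :])

    def test_subpixel_diameter_warns_and_renders(self):
        from vasculens.simulate import VesselSegment

        segs = [VesselSegment(np.array([[30.0, 0.0], [30.0, 500.0]]), diameter=0.9)]
        with pytest.warns(UserWarning, match="below one pixel"):
            frame = render_frame(
                segs, [True], 5000.0, [0.0], NoiseModel(read_noise_sd=0, photon_scale=0),
                0, pixel_size=1.0, shape=(60, 501),
            )
        assert (frame[:, 250] > 100).sum() >= 1


class TestSimulateStack:
    def test_control_all_perfused_and_deterministic(self):
        spec = VesselNetworkSpec(seed=2)
        stack_a, truth = simulate_stack(spec, seed=5)
        stack_b, _ = simulate_stack(spec, seed=5)
        np.testing.assert_array_equal(stack_a.frames, stack_b.frames)
        assert all(all(row) for row in truth.perfusion)

    def test_ect_without_reperfusion_locks_everything(self):
        spec = VesselNetworkSpec(seed=2)
        scenario = PerfusionScenario.ect(spec.n_segments, perfused_fraction_late=0.0)
        _, truth = simulate_stack(spec, scenario=scenario, seed=5)
        ts = np.asarray(truth.timestamps_s)
        post = ts >= scenario.treatment_time
        perf = np.array(truth.perfusion)
        assert not perf[:, post].any()
        assert perf[:, ~post].all()

    def test_monotone_filling_noise_free(self):
        spec = VesselNetworkSpec(seed=2)
        noise = NoiseModel(read_noise_sd=0, photon_scale=0)
        stack, truth = simulate_stack(spec, noise=noise, seed=0)
        # mean over all frames is dominated by the perfused vessels
        means = stack.frames.reshape(stack.n_frames, -1).mean(axis=1)
        assert np.all(np.diff(means) >= 0)

    def test_extravascular_never_rises_while_locked(self):
        spec = VesselNetworkSpec(seed=2)
        scenario = PerfusionScenario.ect(spec.n_segments, perfused_fraction_late=0.0)
        kin = TracerKinetics(k_perm=1e-3, leakage_onset_delay=0.0)
        noise = NoiseModel(read_noise_sd=0, photon_scale=0)
        stack, truth = simulate_stack(spec, scenario=scenario, kinetics=kin, noise=noise, seed=0)
        ts = np.asarray(truth.timestamps_s)
        # after the lock, no extravascular (non-vessel) pixel may brighten
        locked = np.flatnonzero(ts >= scenario.treatment_time)
        ref = stack.frames[locked[0]]
        for k in locked[1:]:
            assert np.all(stack.frames[k] <= ref)

    def test_scenario_validation(self):
        spec = VesselNetworkSpec(seed=2)
        with pytest.raises(ConfigError):
            simulate_stack(spec, scenario=PerfusionScenario("EP", 130.0, 100.0, ()), seed=0)
        with pytest.raises(ConfigError):
            PerfusionScenario.named("freeze", 4)
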