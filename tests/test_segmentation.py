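"""Vessel masking, manual corrections, compartments, perfusion calls."""

import numpy as np
import pytest
from scipy import ndimage

from vasculens.exceptions import ConfigError, DegenerateInputError, MaskConflictError
from vasculens.segmentation import (
    apply_corrections,
    extravascular_mask,
    perfused_mask_at,
    reference_projection,
    segment_vessels,
)
from vasculens.simulate import (
    NoiseModel,
    PerfusionScenario,
    VesselNetworkSpec,
    _RasterCache,
    build_network,
    simulate_stack,
)
from vasculens.stack_io import ImageStack


class TestReferenceProjection:
    def test_single_frame_window_is_that_frame(self, rng):
        frames = rng.integers(0, 1000, (4, 10, 10)).astype(np.uint16)
        stack = ImageStack(frames, 10.0 * np.arange(4), 1.0)
        np.testing.assert_array_equal(reference_projection(stack, (2, 3)), frames[2])

    def test_union_of_disjoint_vessels_and_max_property(self):
        frames = np.full((2, 10, 10), 100, np.uint16)
        frames[0, 2, :] = 5000
        frames[1, 7, :] = 6000
        stack = ImageStack(frames, np.array([0.0, 10.0]), 1.0)
        proj = reference_projection(stack)
        assert np.all(proj[2, :] == 5000) and np.all(proj[7, :] == 6000)
        assert np.all(proj[None] >= frames)

    def test_empty_window_rejected(self, rng):
        frames = rng.integers(0, 10, (3, 5, 5)).astype(np.uint16)
        stack = ImageStack(frames, 10.0 * np.arange(3), 1.0)
        with pytest.raises(DegenerateInputError):
            reference_projection(stack, (2, 2))


class TestSegmentVessels:
    def test_noise_free_vessel_mask_matches_raster(self):
        spec = VesselNetworkSpec(seed=6)
        noise = NoiseModel(read_noise_sd=0, photon_scale=0)
        stack, _ = simulate_stack(spec, noise=noise, seed=0)
        segs, _ = build_network(spec)
        truth_mask = _RasterCache(segs, stack.frame_shape, spec.pixel_size).union_vessel_mask()
        mask = segment_vessels(reference_projection(stack)).grid
        diff = np.logical_xor(mask, truth_mask).sum()
        assert diff / truth_mask.sum() < 0.05

    def test_constant_reference_rejected(self):
        with pytest.raises(DegenerateInputError):
            segment_vessels(np.full((20, 20), 3.0))

    def test_small_speck_removed(self):
        ref = np.full((30, 30), 10.0)
        ref[4:6, 4] = 5000.0  # 2-px speck
        ref[15:25, 10:20] = 5000.0  # real structure
        mask = segment_vessels(ref, opening_radius_px=0, min_component_px=10).grid
        assert not mask[4:6, 4].any()
        assert mask[16:24, 11:19].all()


class TestCorrections:
    def test_identity_without_corrections(self, rng):
        grid = rng.random((12, 12)) > 0.6
        np.testing.assert_array_equal(apply_corrections(grid).grid, grid)

    def test_add_full_field(self, rng):
        grid = rng.random((8, 8)) > 0.5
        out = apply_corrections(grid, add_mask=np.ones_like(grid))
        assert out.grid.all()

    def test_remove_one_component_lowers_count(self):
        grid = np.zeros((20, 20), bool)
        grid[2:5, 2:5] = True
        grid[10:15, 10:15] = True
        remove = np.zeros_like(grid)
        remove[2:5, 2:5] = True
        out = apply_corrections(grid, remove_mask=remove)
        s = np.ones((3, 3), bool)
        assert ndimage.label(out.grid, s)[1] == ndimage.label(grid, s)[1] - 1

    def test_overlapping_corrections_conflict(self):
        grid = np.zeros((5, 5), bool)
        both = np.ones_like(grid)
        with pytest.raises(MaskConflictError):
            apply_corrections(grid, add_mask=both, remove_mask=both)


class TestCompartmentPartition:
    def test_empty_vessel_mask_gives_full_roi(self, default_roi):
        ev = extravascular_mask(np.zeros_like(default_roi), default_roi)
        np.testing.assert_array_equal(ev.grid, default_roi)

    def test_vessels_covering_roi_leave_nothing(self, default_roi):
        ev = extravascular_mask(np.ones_like(default_roi), default_roi)
        assert not ev.grid.any()

    def test_partition_identity(self, rng, default_roi):
        vessel = rng.random(default_roi.shape) > 0.7
        ev = extravascular_mask(vessel, default_roi).grid
        iv = vessel & default_roi
        assert not (ev & iv).any()
        np.testing.assert_array_equal(ev | iv, default_roi)


class TestPerfusionCalls:
    def test_control_post_filling_equals_vessel_mask(self, control):
        stack, truth, res = control
        vessel = res["vessel_mask"]
        i = int(np.argmin(np.abs(res["aligned"].timestamps - 120)))
        perf = perfused_mask_at(res["aligned"], vessel, i)
        np.testing.assert_array_equal(perf.grid, vessel.grid)

    def test_ect_post_treatment_mask_empty(self, ect):
        stack, truth, res = ect
        ts = res["aligned"].timestamps
        i = int(np.argmin(np.abs(ts - 500)))
        perf = perfused_mask_at(res["aligned"], res["vessel_mask"], i)
        assert not perf.grid.any()

    @pytest.mark.parametrize("k_sd", [2.0, 3.0, 5.0])
    def test_noise_free_calls_match_truth_timeline(self, k_sd):
        spec = VesselNetworkSpec(seed=6)
        scenario = PerfusionScenario.ep(
            spec.n_segments, reperfusion_onset=600.0, stagger=60.0, reperfused_fraction=0.5
        )
        noise = NoiseModel(read_noise_sd=0, photon_scale=0)
        stack, truth = simulate_stack(spec, scenario=scenario, noise=noise, seed=0)
        segs, _ = build_network(spec)
        cache = _RasterCache(segs, stack.frame_shape, spec.pixel_size)
        vessel = segment_vessels(
            reference_projection(stack, (0, int(np.sum(np.array(truth.timestamps_s) < 130.0))))
        )
        perf_truth = np.array(truth.perfusion)
        ts = np.asarray(truth.timestamps_s)
        # tracer must have arrived for perfusion to be observable at all
        for i, t in enumerate(ts):
            if t < 40:
                continue
            called = perfused_mask_at(stack, vessel, i, k_sd=k_sd, background=(100.0, 1.0))
            for s, seg_mask in enumerate(cache.vessel_masks):
                frac = (called.grid & seg_mask).sum() / seg_mask.sum()
                assert (frac > 0.5) == perf_truth[s, i], (t, s)

    def test_perfused_mask_is_subset_of_vessel_mask(self, ep_lock):
        stack, truth, res = ep_lock
        vessel = res["vessel_mask"].grid
        for i in range(0, res["aligned"].n_frames, 7):
            perf = perfused_mask_at(res["aligned"], vessel, i).grid
            assert not (perf & ~vessel).any()

    def test_missing_background_requires_explicit_stats(self, control):
        stack, truth, res = control
        with pytest.raises(ConfigError):
            perfused_mask_at(res["aligned"], res["vessel_mask"], 0, background_frame_index=None)
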